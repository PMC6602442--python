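"""Iterative pool-based conformational search.

The protocol: an initial pool of 48 structures is built from the input by
re-building termini and predicted unreliable regions; each cycle applies
structure operators 10 times to every pool member (480 trials), relaxes
each trial under restraints (a shorter relaxation after loop modelling),
and feeds low-energy trials back into the pool — a trial replaces the
highest-energy pool member within a closeness radius, or the globally
worst member if nothing is close; the radius widens linearly over the five
cycles to push sampling outward. Afterwards all generated structures
(2400 at defaults) are re-scored *without* restraints, the 10 lowest are
taken, given a final full-atom optimization, and returned ranked.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .config import default_config
from .energy import (
    RelaxSchedule,
    RestraintSet,
    build_restraints,
    evaluate_energy,
    relax,
)
from .error_estimation import (
    FragmentLibrary,
    ResidueErrorProfile,
    estimate_profile,
)
from .geometry import compute_backbone_torsions
from .metrics import ca_rmsd
from .operators import (
    OperatorContext,
    apply_random_operator,
    replace_window_torsions,
)
from .sidechain import has_sidechains, repack_sidechains
from .structure_io import ProteinModel, validate_input
from .threading import (
    AlignmentPair,
    PatchLibrary,
    extract_patch_library,
    filter_homologs_by_tmscore,
    optimize_threaded,
    thread_sequence,
)


@dataclass
class RefinementConfig:
    """Search-size parameters plus the full defaults dictionary.

    ``relax_scale`` scales all three relaxation step counts together
    (their 14.4 : 3.0 : 1.2 ratio is preserved); ``rmsf_runs`` and
    ``rmsf_steps`` control the error-estimation ensemble.
    """

    capacity: int = 48
    trials_per_member: int = 10
    cycles: int = 5
    mode: str = "default"                   # default | conservative
    closeness_start: float = 0.5
    closeness_end: float = 2.0
    seed: int = 0
    relax_scale: float = 1.0
    rmsf_runs: int | None = None
    cfg: dict = field(default_factory=default_config)

    def __post_init__(self):
        if min(self.capacity, self.trials_per_member, self.cycles) < 1:
            raise ValueError("capacity, trials_per_member and cycles must be >= 1")
        if self.mode not in ("default", "conservative"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def restraint_form(self) -> str:
        return self.cfg["conservative_form"] if self.mode == "conservative" \
            else self.cfg["restraint_form"]

    def steps(self, which: str) -> int:
        key = {"long": "relax_steps_long", "standard": "relax_steps_standard",
               "short": "relax_steps_short"}[which]
        return max(1, int(round(self.cfg[key] * self.relax_scale)))

    def closeness_at(self, cycle: int) -> float:
        if self.cycles == 1:
            return self.closeness_end
        frac = cycle / (self.cycles - 1)
        return self.closeness_start + (self.closeness_end - self.closeness_start) * frac


@dataclass
class StructurePool:
    """Fixed-capacity set of scored conformations."""

    members: list[tuple[ProteinModel, float]]
    capacity: int
    cycle: int = 0
    closeness_radius: float = 0.5

    def __len__(self):
        return len(self.members)

    def energies(self) -> np.ndarray:
        return np.array([e for _, e in self.members])

    def best(self) -> tuple[ProteinModel, float]:
        k = int(np.argmin(self.energies()))
        return self.members[k]


@dataclass
class RefinementResult:
    """Final ranked models plus the per-cycle log."""

    final_models: list[ProteinModel]
    final_energies: list[float]
    log: list[dict]
    all_scored_count: int
    profile: ResidueErrorProfile | None = None


def _rebuild_region(model, s, e, fraglib, rng):
    """Fragment-assembly rebuild of [s, e] (0-based); None on failure."""
    t = compute_backbone_torsions(model)
    w = e - s + 1
    phi = t.phi[s: e + 1].copy()
    psi = t.psi[s: e + 1].copy()
    frags = [(fp, fs) for fw, fp, fs in fraglib.fragments if fw <= w] if fraglib else []
    if frags:
        fphi, fpsi = frags[int(rng.integers(len(frags)))]
        off = int(rng.integers(w - len(fphi) + 1))
        phi[off: off + len(fphi)] = fphi
        psi[off: off + len(fphi)] = fpsi
    else:
        phi = phi + rng.normal(0, 30.0, w)
        psi = psi + rng.normal(0, 30.0, w)
    if s == 0:
        phi[0] = t.phi[0]
    if e == len(model) - 1:
        psi[-1] = t.psi[-1]
    return replace_window_torsions(model, s, e, phi, psi, rng)


def initialize_pool(
    input_model: ProteinModel,
    profile: ResidueErrorProfile,
    config: RefinementConfig,
    fraglib: FragmentLibrary | None,
    restraints: RestraintSet,
    rng: np.random.Generator,
) -> StructurePool:
    """Build the initial pool by re-building termini and ULR loops.

    Each member uses distinct random draws; on repeated closure failure a
    relaxed copy of the input is kept instead.
    """
    L = len(input_model)
    regions: list[tuple[int, int]] = [(s - 1, e - 1) for s, e in profile.ulrs]
    if config.cfg["rebuild_termini"]:
        tlen = min(config.cfg["terminal_rebuild_len"], max(1, L // 4))
        regions = [(0, tlen - 1), (L - tlen, L - 1)] + regions
    # merge overlaps, keep order
    regions = sorted(set(regions))
    sched = RelaxSchedule(steps=config.steps("short"), mode="minimize")
    members = []
    for k in range(config.capacity):
        work = input_model.copy()
        for s, e in regions:
            for _ in range(10):
                rebuilt = _rebuild_region(work, s, e, fraglib, rng)
                if rebuilt is not None and not rebuilt.chain_gaps():
                    work = rebuilt
                    break
        relaxed = relax(work, restraints, sched, weights=config.cfg["weights"])
        energy = evaluate_energy(relaxed, restraints, config.cfg["weights"]).total_with_restraints
        relaxed.provenance = "trial"
        members.append((relaxed, float(energy)))
    return StructurePool(members, config.capacity,
                         closeness_radius=config.closeness_at(0))


def generate_trials(
    pool: StructurePool,
    context: OperatorContext,
    restraints: RestraintSet,
    config: RefinementConfig,
) -> list[tuple[ProteinModel, str, float]]:
    """One cycle of trials: operators applied 10x to each pool member.

    Returns (relaxed trial, operator tag, restrained energy) triples;
    trials after loop modelling use the short relaxation schedule, all
    others the standard one. No-op operator draws are re-drawn up to five
    times, then the member is passed through relaxation unchanged.
    """
    trials = []
    context.pool = [m for m, _ in pool.members]
    for member, _ in pool.members:
        for _ in range(config.trials_per_member):
            result = None
            for _ in range(5):
                result = apply_random_operator(member, context)
                if not result.noop:
                    break
            which = "short" if result.operator == "loop_modelling" else "standard"
            sched = RelaxSchedule(steps=config.steps(which), mode="minimize")
            relaxed = relax(result.model, restraints, sched, weights=config.cfg["weights"])
            energy = evaluate_energy(relaxed, restraints,
                                     config.cfg["weights"]).total_with_restraints
            trials.append((relaxed, result.operator, float(energy)))
    return trials


def update_pool(
    pool: StructurePool,
    trials: list[tuple[ProteinModel, str, float]],
) -> StructurePool:
    """Feed scored trials into the pool, lowest energy first.

    A trial replaces the highest-energy pool member within the closeness
    radius (CA-RMSD), or the globally worst member if none is close —
    always only if the trial's energy is lower. Pool size is conserved
    and the minimum pool energy never increases.
    """
    order = np.argsort([e for _, _, e in trials])
    for k in order:
        trial, _, energy = trials[k]
        rmsds = np.array([ca_rmsd(trial, m) for m, _ in pool.members])
        close = np.where(rmsds <= pool.closeness_radius)[0]
        if len(close):
            cand = close[int(np.argmax([pool.members[i][1] for i in close]))]
        else:
            cand = int(np.argmax(pool.energies()))
        if energy < pool.members[cand][1]:
            pool.members[cand] = (trial, energy)
    return pool


def select_final_models(
    all_trials: list[tuple[ProteinModel, str, float]],
    config: RefinementConfig,
    n_final: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ProteinModel], list[float]]:
    """Rank every generated structure by restraint-free energy, take the 10
    lowest, and give each a final full-atom optimization (repack + an
    unrestrained minimization), then re-sort."""
    n_final = n_final or config.cfg["final_models"]
    rng = rng or np.random.default_rng(config.seed)
    weights = config.cfg["weights"]
    scores = [
        evaluate_energy(m, None, weights).total_without_restraints
        for m, _, _ in all_trials
    ]
    order = np.argsort(scores)[:n_final]
    if len(all_trials) < n_final:
        import warnings

        warnings.warn(f"only {len(all_trials)} structures available for final selection")
    sched = RelaxSchedule(steps=config.steps("short"), mode="minimize")
    finals = []
    for k in order:
        m = all_trials[int(k)][0].copy()
        if has_sidechains(m):
            m = repack_sidechains(m, rng)
        m = relax(m, None, sched, weights=weights)
        e = evaluate_energy(m, None, weights).total_without_restraints
        m.provenance = "final"
        finals.append((m, float(e)))
    finals.sort(key=lambda t: t[1])
    models = [m for m, _ in finals]
    for rank, m in enumerate(models, start=1):
        m.meta["rank"] = rank
    return models, [e for _, e in finals]


def run_refinement(
    input_model: ProteinModel,
    config: RefinementConfig | None = None,
    pssm: np.ndarray | None = None,
    fraglib: FragmentLibrary | None = None,
    homologs: list[tuple[ProteinModel, AlignmentPair]] | None = None,
    restraint_source: ProteinModel | None = None,
) -> RefinementResult:
    """The full protocol: error estimation, threading, pool search, selection.

    ``restraint_source`` substitutes another structure (e.g. a known
    native, for benchmarking) as the origin of the restraints; by default
    restraints come from the input model itself. Deterministic given
    ``config.seed``.
    """
    config = config or RefinementConfig()
    report = validate_input(input_model)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.violations))

    seeds = np.random.SeedSequence(config.seed).spawn(4 + config.cycles)
    s_err, s_pool, s_final, s_thread = seeds[0], seeds[1], seeds[2], seeds[3]
    cfg = config.cfg

    restraints = build_restraints(
        restraint_source or input_model, form=config.restraint_form, cfg=cfg
    )

    if fraglib is None:
        fraglib = self_fragment_library(input_model, cfg["fragment_window"],
                                        seed=int(s_err.generate_state(1)[0] % 2**31))

    rmsf_sched = RelaxSchedule(
        steps=config.steps("long"), mode="noisy-minimize",
        sidechain_repack_every=max(1, config.steps("long") // 12),
    )
    profile = estimate_profile(
        input_model, restraints, fraglib, pssm=pssm,
        n_runs=config.rmsf_runs or cfg["rmsf_runs"],
        schedule=rmsf_sched, seed=int(s_err.generate_state(1)[0] % 2**31), cfg=cfg,
    )

    patch_library = PatchLibrary(window_bounds=(cfg["patch_window_min"],
                                                cfg["patch_window_max"]))
    if homologs:
        threaded = []
        for hom, aln in homologs:
            if aln.coverage() < cfg["min_coverage"]:
                continue
            threaded.append(thread_sequence(input_model.sequence, hom, aln))
        kept = filter_homologs_by_tmscore(threaded, input_model,
                                          cfg["tm_filter_threshold"])
        optimized = optimize_threaded(kept, cfg,
                                      seed=int(s_thread.generate_state(1)[0] % 2**31))
        patch_library = extract_patch_library(
            optimized, profile.ulrs,
            (cfg["patch_window_min"], cfg["patch_window_max"]),
        )

    rng_pool = np.random.default_rng(s_pool.generate_state(2))
    pool = initialize_pool(input_model, profile, config, fraglib, restraints, rng_pool)

    log: list[dict] = []
    all_trials: list[tuple[ProteinModel, str, float]] = []
    for cycle in range(config.cycles):
        pool.cycle = cycle
        pool.closeness_radius = config.closeness_at(cycle)
        ctx = OperatorContext(
            error_profile=profile,
            patch_library=patch_library,
            fraglib=fraglib,
            pool=[m for m, _ in pool.members],
            rng=np.random.default_rng(seeds[4 + cycle].generate_state(2)),
            cfg=cfg,
        )
        t0 = time.perf_counter()
        trials = generate_trials(pool, ctx, restraints, config)
        all_trials.extend(trials)
        energies_before = pool.energies()
        pool = update_pool(pool, trials)
        tags = [tag for _, tag, _ in trials]
        log.append({
            "cycle": cycle,
            "closeness_radius": pool.closeness_radius,
            "pool_min": float(pool.energies().min()),
            "pool_mean": float(pool.energies().mean()),
            "pool_min_before": float(energies_before.min()),
            "n_trials": len(trials),
            "operator_counts": {n: tags.count(n) for n in sorted(set(tags))},
            "accepted": int(np.sum(pool.energies() != energies_before)),
            "seconds": time.perf_counter() - t0,
        })

    finals, final_energies = select_final_models(
        all_trials, config, rng=np.random.default_rng(s_final.generate_state(2))
    )
    return RefinementResult(
        final_models=finals,
        final_energies=final_energies,
        log=log,
        all_scored_count=len(all_trials),
        profile=profile,
    )


def self_fragment_library(model: ProteinModel, window: int = 7,
                          n_noise: int = 20, seed: int = 0) -> FragmentLibrary:
    """Fragment library from the model's own torsion windows plus noise.

    Used when no external library is supplied: the model's windows give a
    FRAG baseline of zero, the noisy copies provide sampling diversity for
    fragment assembly.
    """
    t = compute_backbone_torsions(model)
    lib = FragmentLibrary(window=window)
    L = len(t)
    rng = np.random.default_rng(seed)
    for s in range(L - window + 1):
        phi = t.phi[s: s + window].copy()
        psi = t.psi[s: s + window].copy()
        phi[~np.isfinite(phi)] = -70.0
        psi[~np.isfinite(psi)] = 140.0
        lib.add(phi, psi)
    base = len(lib.fragments)
    for _ in range(n_noise):
        k = int(rng.integers(base))
        _, phi, psi = lib.fragments[k]
        lib.add(phi + rng.normal(0, 25.0, window), psi + rng.normal(0, 25.0, window))
    return lib
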