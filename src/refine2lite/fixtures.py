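"""Synthetic test structures and refinement cases.

Everything the protocol consumes can be generated here deterministically:
ideal helices and strands, a clash-free antiparallel two-helix bundle,
torsion-space decoys at a target CA-RMSD, synthetic PSSMs with planted
conservation signal, fragment libraries, and complete refinement cases
with native/start/homolog structures. No downloads, no external files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .error_estimation import FragmentLibrary
from .geometry import (
    TorsionSeries,
    compute_backbone_torsions,
    rebuild_backbone_from_torsions,
)
from .metrics import ca_rmsd
from .sidechain import add_cb_atoms, place_cb
from .structure_io import ProteinModel, model_from_backbone
from .threading import AlignmentPair

_ANCHOR = np.array([[0.0, 0.0, 0.0], [1.458, 0.0, 0.0], [2.0, 1.4, 0.0]])

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 120.0

#: turn torsions producing a packed antiparallel bundle (clash-free)
_TURNS = {
    3: [(-60.0, -30.0), (90.0, 0.0), (-90.0, 0.0)],
    4: [(50.0, 45.0), (65.0, 30.0), (-120.0, 140.0), (-80.0, -20.0)],
}


@dataclass
class RefinementCase:
    """A self-contained synthetic refinement benchmark."""

    native: ProteinModel
    start: ProteinModel
    target_start_rmsd: float
    pssm: np.ndarray
    fraglib: FragmentLibrary
    homologs: list[tuple[ProteinModel, AlignmentPair]] = field(default_factory=list)
    loop_range: tuple[int, int] = (0, 0)      # 1-based perturbed-loop range


def _uniform_torsions(n: int, phi: float, psi: float) -> TorsionSeries:
    p = np.full(n, phi)
    s = np.full(n, psi)
    o = np.full(n, 180.0)
    p[0] = np.nan
    s[-1] = np.nan
    o[-1] = np.nan
    return TorsionSeries(p, s, o)


def make_ideal_helix(n: int, sequence: str | None = None) -> ProteinModel:
    """Ideal poly-ALA alpha helix (phi -57, psi -47, omega 180)."""
    if n < 4:
        raise ValueError("helix needs at least 4 residues")
    seq = sequence or "A" * n
    if len(seq) != n:
        raise ValueError("sequence length must equal n")
    m = rebuild_backbone_from_torsions(
        _uniform_torsions(n, HELIX_PHI, HELIX_PSI), _ANCHOR, sequence=seq
    )
    m.provenance = "input"
    return m


def make_ideal_strand(n: int, sequence: str | None = None) -> ProteinModel:
    """Ideal extended strand (phi -120, psi 120)."""
    if n < 3:
        raise ValueError("strand needs at least 3 residues")
    seq = sequence or "A" * n
    m = rebuild_backbone_from_torsions(
        _uniform_torsions(n, STRAND_PHI, STRAND_PSI), _ANCHOR, sequence=seq
    )
    m.provenance = "input"
    return m


def make_two_helix_bundle(
    n_per_helix: int = 14, loop_len: int = 3, sequence: str | None = None
) -> ProteinModel:
    """Two antiparallel helices joined by a turn; clash-free and compact.

    The turn torsions are fixed patterns (loop lengths 3 and 4) chosen so
    the helices pack with inter-helix CA contacts below 12 A.
    """
    if n_per_helix < 6:
        raise ValueError("helices need at least 6 residues each")
    if loop_len not in _TURNS:
        raise ValueError(f"supported loop lengths: {sorted(_TURNS)}")
    n = 2 * n_per_helix + loop_len
    t = _uniform_torsions(n, HELIX_PHI, HELIX_PSI)
    for k, (p, s) in enumerate(_TURNS[loop_len]):
        t.phi[n_per_helix + k] = p
        t.psi[n_per_helix + k] = s
    seq = sequence or "A" * n
    m = rebuild_backbone_from_torsions(t, _ANCHOR, sequence=seq)
    m.provenance = "input"
    return m


def make_alternating_sidechain_model(base: ProteinModel, seed: int = 0) -> ProteinModel:
    """ALA/LEU variant of a backbone model, with CB everywhere and coarse
    CG/CD side chains on the LEU positions (for side-chain tests)."""
    from .config import IDEAL_GEOMETRY
    from .geometry import place_atom

    rng = np.random.default_rng(seed)
    out = base.copy()
    g = IDEAL_GEOMETRY
    for i, res in enumerate(out.residues):
        res.aa = "A" if i % 2 == 0 else "L"
        res.atoms["CB"] = place_cb(res.atoms["N"], res.atoms["CA"], res.atoms["C"])
        if res.aa == "L":
            chi1 = float(rng.choice([-60.0, 60.0, 180.0]))
            chi2 = float(rng.choice([-60.0, 60.0, 180.0]))
            res.atoms["CG"] = place_atom(res.atoms["N"], res.atoms["CA"],
                                         res.atoms["CB"], g["bond_cb_cg"],
                                         g["angle_sidechain"], chi1)
            res.atoms["CD"] = place_atom(res.atoms["CA"], res.atoms["CB"],
                                         res.atoms["CG"], g["bond_cg_cd"],
                                         g["angle_sidechain"], chi2)
    return out


def perturb_structure(
    model: ProteinModel,
    target_rmsd: float,
    seed: int = 0,
    region_weights: np.ndarray | None = None,
) -> ProteinModel:
    """Torsion-space decoy at a target CA-RMSD (within 20%).

    A fixed seeded noise direction on phi/psi is scaled by bisection until
    the rebuilt structure's CA-RMSD to the input lands in
    [0.8, 1.2] x target. ``region_weights`` (per residue) concentrates the
    noise in chosen regions. The chain stays intact by construction.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be >= 0")
    if target_rmsd == 0:
        return model.copy()
    rng = np.random.default_rng(seed)
    t0 = compute_backbone_torsions(model)
    n = len(t0)
    w = np.ones(n) if region_weights is None else np.asarray(region_weights, float)
    dphi = rng.normal(0.0, 1.0, n) * w
    dpsi = rng.normal(0.0, 1.0, n) * w
    anchor = model.backbone_coords()[0, :3]

    def build(scale: float) -> ProteinModel:
        t = t0.copy()
        t.phi = t.phi + scale * dphi
        t.psi = t.psi + scale * dpsi
        return rebuild_backbone_from_torsions(t, anchor, sequence=model.sequence)

    lo, hi = 0.0, 1.0
    # grow until we overshoot the target
    for _ in range(30):
        if ca_rmsd(build(hi), model) >= target_rmsd:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not reach the target RMSD by torsion noise")
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        r = ca_rmsd(build(mid), model)
        if 0.8 * target_rmsd <= r <= 1.2 * target_rmsd:
            out = build(mid)
            out.provenance = "input"
            return out
        if r < target_rmsd:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"bisection failed to bracket RMSD {target_rmsd}")


def make_synthetic_pssm(
    sequence: str, conserved: np.ndarray, seed: int = 0
) -> np.ndarray:
    """(L, 20) PSSM with planted conservation.

    ``conserved`` is a boolean mask; conserved rows score high on every
    component (mean ~ +4), unconserved rows low (mean ~ -1), plus noise —
    so the sign-flipped row mean is low where conservation is high.
    """
    rng = np.random.default_rng(seed)
    L = len(sequence)
    pssm = rng.normal(0.0, 1.0, (L, 20))
    pssm[np.asarray(conserved, bool)] += 4.0
    pssm[~np.asarray(conserved, bool)] -= 1.0
    return pssm


def make_fragment_library(
    native: ProteinModel, window: int = 7, n_noise: int = 30, seed: int = 0
) -> FragmentLibrary:
    """Library of the native's torsion windows plus noisy decoy fragments."""
    from .refinement import self_fragment_library

    return self_fragment_library(native, window=window, n_noise=n_noise, seed=seed)


def make_refinement_case(
    size: int = 40, start_rmsd: float = 2.5, seed: int = 0
) -> RefinementCase:
    """A full synthetic benchmark case.

    The native is a two-helix bundle; the start model concentrates the
    perturbation in the loop and termini (the planted unreliable region)
    with light noise elsewhere. The PSSM marks helix positions conserved.
    Two homolog decoys come with identity alignments: one perturbed
    lightly (passes the TM-score > 0.5 filter), one heavily (fails it).
    """
    if size > 300:
        raise ValueError("size is limited to 300 residues")
    loop_len = 4
    n_per_helix = (size - loop_len) // 2
    native = make_two_helix_bundle(n_per_helix, loop_len)
    L = len(native)
    loop_lo = n_per_helix           # 0-based loop start
    loop_hi = n_per_helix + loop_len - 1
    weights = np.full(L, 0.15)
    weights[loop_lo - 1: loop_hi + 2] = 1.0   # loop + one flank residue
    weights[:2] = 1.0
    weights[-2:] = 1.0
    start = perturb_structure(native, start_rmsd, seed=seed, region_weights=weights)

    conserved = np.ones(L, dtype=bool)
    conserved[loop_lo - 1: loop_hi + 2] = False   # matches the perturbed region
    conserved[:2] = False
    conserved[-2:] = False
    pssm = make_synthetic_pssm(native.sequence, conserved, seed=seed + 1)
    fraglib = make_fragment_library(native, seed=seed + 2)

    good = perturb_structure(native, 0.8, seed=seed + 3)
    good = add_cb_atoms(good)
    bad = perturb_structure(native, 8.0, seed=seed + 4)
    bad = add_cb_atoms(bad)
    homologs = [
        (good, AlignmentPair(native.sequence, native.sequence, "good_homolog")),
        (bad, AlignmentPair(native.sequence, native.sequence, "bad_homolog")),
    ]
    return RefinementCase(
        native=native,
        start=start,
        target_start_rmsd=start_rmsd,
        pssm=pssm,
        fraglib=fraglib,
        homologs=homologs,
        loop_range=(loop_lo + 1, loop_hi + 1),
    )
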