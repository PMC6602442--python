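"""Residue-wise model error estimation and unreliable-local-region detection.

Three per-residue scores feed a linear model of local error:

* RMSF — root-mean-square CA fluctuation over an ensemble of noisy
  restrained relaxations (with side-chain repacking interleaved), after
  iterative superposition onto the ensemble mean;
* FRAG — disagreement between the model's backbone torsions and the best
  matching fragment from a fragment library, in degrees;
* MSA — a conservation signal from a position-specific scoring matrix
  (sign-flipped so that low conservation means high expected error).

Stretches of consecutive residues with predicted error above a threshold
become unreliable local regions (ULRs), the targets of loop rebuilding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULTS
from .energy import RelaxSchedule, RestraintSet, relax
from .geometry import circular_difference, compute_backbone_torsions, kabsch_superpose
from .structure_io import ProteinModel


@dataclass
class ErrorModelCoefficients:
    """Linear model: error = intercept + w_rmsf*RMSF + w_frag*FRAG + w_msa*MSA."""

    intercept: float
    w_rmsf: float
    w_frag: float
    w_msa: float | None = None


@dataclass
class FragmentLibrary:
    """Backbone torsion fragments: (window length, phi[], psi[]) per entry."""

    fragments: list[tuple[int, np.ndarray, np.ndarray]] = field(default_factory=list)
    window: int = 7

    def __len__(self):
        return len(self.fragments)

    def add(self, phi, psi) -> None:
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        if len(phi) != len(psi):
            raise ValueError("fragment phi/psi must have equal length")
        self.fragments.append((len(phi), phi, psi))


@dataclass
class ResidueErrorProfile:
    """Per-residue error scores, the combined prediction, and derived ULRs."""

    rmsf: np.ndarray
    frag: np.ndarray
    msa: np.ndarray | None = None
    predicted_error: np.ndarray | None = None
    ulrs: list[tuple[int, int]] = field(default_factory=list)


def rmsf_score(
    model: ProteinModel,
    restraints: RestraintSet,
    n_runs: int = 24,
    schedule: RelaxSchedule | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Residue-wise CA fluctuation over noisy restrained relaxations.

    Runs ``n_runs`` noisy-minimize relaxations with distinct seeds,
    superposes all end structures onto their iteratively refined CA mean,
    and returns the per-residue root-mean-square deviation from the mean
    structure (Angstrom).
    """
    if n_runs < 2:
        raise ValueError("rmsf_score needs at least 2 runs")
    schedule = schedule or RelaxSchedule(
        steps=DEFAULTS["relax_steps_long"], mode="noisy-minimize",
        sidechain_repack_every=DEFAULTS["sidechain_repack_every"],
    )
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    ensemble = []
    for ss in seeds:
        run_sched = RelaxSchedule(
            steps=schedule.steps, mode="noisy-minimize",
            sidechain_repack_every=schedule.sidechain_repack_every,
            rng_seed=int(ss.generate_state(1)[0] % (2 ** 31)),
        )
        ensemble.append(relax(model, restraints, run_sched).coords("CA"))
    ensemble = np.array(ensemble)          # (R, L, 3)
    mean = ensemble[0].copy()
    for _ in range(5):
        aligned = []
        for ca in ensemble:
            tr, _ = kabsch_superpose(ca, mean)
            aligned.append(tr.apply(ca))
        aligned = np.array(aligned)
        new_mean = aligned.mean(axis=0)
        if np.allclose(new_mean, mean, atol=1e-8):
            mean = new_mean
            break
        mean = new_mean
    dev = aligned - mean[None]
    return np.sqrt(np.mean(np.sum(dev ** 2, axis=-1), axis=0))


def frag_score(model: ProteinModel, library: FragmentLibrary) -> np.ndarray:
    """Mean best-fragment torsion deviation per residue, in degrees.

    For every window position the score is the minimum over library
    fragments of the mean circular absolute phi/psi difference; each
    residue averages the scores of all windows covering it (terminal
    residues simply see fewer windows). Undefined terminal torsions are
    excluded from the means.
    """
    if len(library) == 0:
        raise ValueError("fragment library is empty")
    t = compute_backbone_torsions(model)
    L = len(t)
    w = library.window
    if w > L:
        raise ValueError(f"fragment window {w} exceeds residue count {L}")
    frags = [(fphi, fpsi) for fw, fphi, fpsi in library.fragments if fw == w]
    if not frags:
        raise ValueError(f"library has no fragments of window {w}")
    sums = np.zeros(L)
    counts = np.zeros(L)
    for s in range(L - w + 1):
        mphi = t.phi[s: s + w]
        mpsi = t.psi[s: s + w]
        best = np.inf
        for fphi, fpsi in frags:
            dphi = np.abs(circular_difference(mphi, fphi))
            dpsi = np.abs(circular_difference(mpsi, fpsi))
            diffs = np.concatenate([dphi[np.isfinite(dphi)], dpsi[np.isfinite(dpsi)]])
            if diffs.size:
                best = min(best, float(diffs.mean()))
        if np.isfinite(best):
            sums[s: s + w] += best
            counts[s: s + w] += 1
    counts[counts == 0] = 1
    return sums / counts


def msa_score(
    pssm: np.ndarray,
    sequence: str,
    window: int = 1,
    use_native_component: bool = False,
) -> np.ndarray:
    """Conservation-derived error signal from a PSSM.

    The raw per-residue value is the (sign-flipped) mean of the 20 PSSM
    components of that row — high conservation scores mean low expected
    error — or, with ``use_native_component``, the sign-flipped score of
    the residue's own amino acid. A centered moving average of odd width
    ``window`` smooths the signal (width 1 = no smoothing; termini use
    the available part of the window).
    """
    pssm = np.asarray(pssm, dtype=float)
    if pssm.shape != (len(sequence), 20):
        raise ValueError(
            f"PSSM shape {pssm.shape} does not match sequence length {len(sequence)}"
        )
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if use_native_component:
        order = "ARNDCQEGHILKMFPSTWYV"
        cols = [order.index(aa) for aa in sequence]
        raw = -pssm[np.arange(len(sequence)), cols]
    else:
        raw = -pssm.mean(axis=1)
    if window == 1:
        return raw
    half = window // 2
    out = np.empty_like(raw)
    for i in range(len(raw)):
        lo = max(0, i - half)
        hi = min(len(raw), i + half + 1)
        out[i] = raw[lo:hi].mean()
    return out


def fit_error_model(
    profiles: list[ResidueErrorProfile],
    true_errors: list[np.ndarray],
) -> ErrorModelCoefficients:
    """Ordinary least squares of true per-residue error on the three scores.

    Profiles without an MSA score fit a 3-parameter model. Requires at
    least 4 more observations than parameters; raises on rank deficiency.
    """
    if len(profiles) != len(true_errors):
        raise ValueError("profiles and true_errors must align")
    has_msa = all(p.msa is not None for p in profiles)
    cols = []
    ys = []
    for p, y in zip(profiles, true_errors):
        y = np.asarray(y, dtype=float)
        feats = [np.ones_like(p.rmsf), p.rmsf, p.frag]
        if has_msa:
            feats.append(p.msa)
        cols.append(np.column_stack(feats))
        ys.append(y)
    X = np.vstack(cols)
    y = np.concatenate(ys)
    n_par = X.shape[1]
    if len(y) < n_par + 4:
        raise ValueError(f"need at least {n_par + 4} observations, got {len(y)}")
    if np.linalg.matrix_rank(X) < n_par:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return ErrorModelCoefficients(
        intercept=float(beta[0]),
        w_rmsf=float(beta[1]),
        w_frag=float(beta[2]),
        w_msa=float(beta[3]) if has_msa else None,
    )


def predict_residue_error(
    profile: ResidueErrorProfile, coeffs: ErrorModelCoefficients
) -> np.ndarray:
    """Linear prediction, clamped at zero below; stored on the profile."""
    pred = coeffs.intercept + coeffs.w_rmsf * profile.rmsf + coeffs.w_frag * profile.frag
    if profile.msa is not None and coeffs.w_msa is not None:
        pred = pred + coeffs.w_msa * profile.msa
    pred = np.clip(pred, 0.0, None)
    profile.predicted_error = pred
    return pred


def detect_ulrs(
    predicted_error: np.ndarray,
    threshold: float,
    min_len: int = 3,
    merge_gap: int = 1,
) -> list[tuple[int, int]]:
    """Maximal above-threshold runs as 1-based inclusive (start, end) ranges.

    Runs separated by at most ``merge_gap`` below-threshold residues are
    merged before the ``min_len`` filter is applied.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    vals = np.asarray(predicted_error, dtype=float)
    above = vals > threshold
    runs: list[list[int]] = []
    i = 0
    while i < len(vals):
        if above[i]:
            j = i
            while j + 1 < len(vals) and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [(s + 1, e + 1) for s, e in merged if e - s + 1 >= min_len]


def default_threshold(predicted_error: np.ndarray, k_sd: float | None = None) -> float:
    """Default ULR threshold: mean + k standard deviations of the prediction."""
    if k_sd is None:
        k_sd = DEFAULTS["ulr_threshold_sd"]
    vals = np.asarray(predicted_error, dtype=float)
    return float(vals.mean() + k_sd * vals.std())


def estimate_profile(
    model: ProteinModel,
    restraints: RestraintSet,
    library: FragmentLibrary,
    pssm: np.ndarray | None = None,
    coeffs: ErrorModelCoefficients | None = None,
    n_runs: int | None = None,
    schedule: RelaxSchedule | None = None,
    seed: int = 0,
    cfg: dict | None = None,
) -> ResidueErrorProfile:
    """Full error-estimation pass: scores, prediction, and ULRs."""
    cfg = cfg or DEFAULTS
    if coeffs is None:
        c = cfg["error_coeffs"]
        coeffs = ErrorModelCoefficients(c["intercept"], c["w_rmsf"], c["w_frag"], c["w_msa"])
    profile = ResidueErrorProfile(
        rmsf=rmsf_score(model, restraints, n_runs or cfg["rmsf_runs"], schedule, seed),
        frag=frag_score(model, library),
        msa=msa_score(pssm, model.sequence) if pssm is not None else None,
    )
    pred = predict_residue_error(profile, coeffs)
    thr = default_threshold(pred, cfg["ulr_threshold_sd"])
    profile.ulrs = detect_ulrs(pred, thr, cfg["ulr_min_len"], cfg["ulr_merge_gap"])
    return profile


# ---------------------------------------------------------------------------
# file dialects: PSI-BLAST ASCII PSSM and fragment-library TSV
# ---------------------------------------------------------------------------

PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


def read_pssm(path: str) -> tuple[np.ndarray, str]:
    """Read the PSI-BLAST ASCII PSSM dialect: (L, 20) scores + sequence.

    Rows look like ``  3 K   -1  2 ...`` with at least 20 score columns;
    header/footer lines are skipped.
    """
    rows, seq = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 22:
                continue
            if not parts[0].isdigit() or len(parts[1]) != 1 or not parts[1].isalpha():
                continue
            try:
                scores = [float(v) for v in parts[2:22]]
            except ValueError:
                continue
            rows.append(scores)
            seq.append(parts[1])
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    return np.array(rows), "".join(seq)


def write_pssm(path: str, pssm: np.ndarray, sequence: str) -> None:
    """Write the same ASCII dialect :func:`read_pssm` consumes."""
    pssm = np.asarray(pssm)
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(PSSM_ALPHABET) + "\n")
        for i, aa in enumerate(sequence):
            row = " ".join(f"{int(round(v)):3d}" for v in pssm[i])
            fh.write(f"{i + 1:5d} {aa}  {row}" + "  " + " ".join(["0.0"] * 2) + "\n")


def read_fragment_library(path: str) -> FragmentLibrary:
    """Fragment TSV: columns id, window, phi_1..phi_w, psi_1..psi_w."""
    lib = FragmentLibrary()
    windows = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id"):
            raise ValueError(f"{path}: expected TSV header starting with 'id'")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            w = int(parts[1])
            vals = [float(v) for v in parts[2: 2 + 2 * w]]
            if len(vals) != 2 * w:
                raise ValueError(f"{path}: fragment row with wrong angle count")
            lib.add(vals[:w], vals[w:])
            windows.add(w)
    if windows:
        lib.window = min(windows)
    return lib


def write_fragment_library(path: str, library: FragmentLibrary) -> None:
    w = library.window
    with open(path, "w") as fh:
        cols = [f"phi_{k + 1}" for k in range(w)] + [f"psi_{k + 1}" for k in range(w)]
        fh.write("\t".join(["id", "window"] + cols) + "\n")
        for k, (fw, phi, psi) in enumerate(library.fragments):
            vals = [f"{v:.3f}" for v in np.concatenate([phi, psi])]
            fh.write("\t".join([f"frag{k:04d}", str(fw)] + vals) + "\n")
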