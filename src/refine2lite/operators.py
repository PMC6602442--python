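"""The six structure-perturbation operators of the refinement search.

Three drive local refinement — fragment assembly, loop modelling and
side-chain perturbation — and three drive larger changes — normal-mode
perturbation, structure hybridization and secondary-structure
perturbation. Every operator returns an :class:`OperatorResult`; failures
(no closure solution, empty patch library, no secondary-structure chunk)
are flagged no-ops rather than exceptions so the refinement loop can
re-draw. All operators are deterministic given the context's generator
state, keep the sequence unchanged, and leave the chain intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .config import DEFAULTS, IDEAL_GEOMETRY
from .energy import RelaxSchedule, relax
from .error_estimation import FragmentLibrary, ResidueErrorProfile
from .geometry import (
    BondGeometry,
    TorsionSeries,
    _loop_forward,
    assign_secondary_structure,
    compute_backbone_torsions,
    dihedral,
    kabsch_superpose,
    loop_closure_gap,
    place_atom,
    triaxial_loop_closure,
    wrap_angle,
)
from .sidechain import add_cb_atoms, current_chis, has_sidechains, repack_sidechains
from .structure_io import ProteinModel
from .threading import PatchLibrary


@dataclass
class OperatorContext:
    """Shared state the operators draw on during one refinement run."""

    error_profile: ResidueErrorProfile | None = None
    patch_library: PatchLibrary | None = None
    fraglib: FragmentLibrary | None = None
    pool: list[ProteinModel] | None = None
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))
    cfg: dict = field(default_factory=lambda: dict(DEFAULTS))


@dataclass
class OperatorResult:
    model: ProteinModel
    operator: str
    noop: bool = False


@dataclass
class ENModes:
    """Elastic-network normal modes over CA atoms.

    ``eigenvectors[:, j]`` is the 3L-vector of mode j; eigenvalues ascend.
    A connected network has exactly six near-zero (rigid-body) modes.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    cutoff: float
    spring_constant: float = 1.0

    def mode_vector(self, j: int) -> np.ndarray:
        """(L, 3) displacement pattern of mode j."""
        return self.eigenvectors[:, j].reshape(-1, 3)

    def n_rigid(self, tol: float = 1e-8) -> int:
        return int(np.sum(self.eigenvalues < tol))


def enm_energy(ca: np.ndarray, ca0: np.ndarray, cutoff: float, k: float = 1.0) -> float:
    """Network energy sum_k (|rij| - |rij0|)^2 over reference pairs in cutoff."""
    d0 = np.linalg.norm(ca0[:, None] - ca0[None, :], axis=-1)
    iu = np.triu_indices(len(ca0), k=1)
    mask = d0[iu] < cutoff
    d = np.linalg.norm(ca[iu[0][mask]] - ca[iu[1][mask]], axis=-1)
    return float(k * np.sum((d - d0[iu][mask]) ** 2))


def compute_enm_modes(model: ProteinModel, cutoff: float | None = None,
                      spring_constant: float = 1.0) -> ENModes:
    """Eigenmodes of the isotropic elastic-network Hessian on CA atoms."""
    cutoff = cutoff if cutoff is not None else DEFAULTS["enm_cutoff"]
    ca = model.coords("CA")
    L = len(ca)
    if L < 4:
        raise ValueError("elastic network needs at least 4 residues")
    diff = ca[:, None] - ca[None, :]
    dist = np.linalg.norm(diff, axis=-1)
    adj = (dist < cutoff) & ~np.eye(L, dtype=bool)
    ncomp, _ = connected_components(csr_matrix(adj), directed=False)
    if ncomp > 1:
        raise ValueError(
            f"elastic network disconnected at cutoff {cutoff} A; increase the cutoff"
        )
    H = np.zeros((3 * L, 3 * L))
    for i in range(L):
        for j in range(i + 1, L):
            if not adj[i, j]:
                continue
            e = diff[i, j] / dist[i, j]
            block = 2.0 * spring_constant * np.outer(e, e)
            si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
            H[si, sj] -= block
            H[sj, si] -= block
            H[si, si] += block
            H[sj, sj] += block
    vals, vecs = np.linalg.eigh(H)
    vals = np.clip(vals, -1e-9, None)
    return ENModes(vals, vecs, cutoff, spring_constant)


# ---------------------------------------------------------------------------
# torsion-window rebuilding with closure
# ---------------------------------------------------------------------------

def _window_anchors(bb: np.ndarray, s: int):
    """(C_prev, N_s, CA_s) anchor triple for a window starting at s >= 1."""
    return np.array([bb[s - 1, 2], bb[s, 0], bb[s, 1]])


def _build_backward_span(bb: np.ndarray, e: int, torsions: TorsionSeries,
                         phi_next: float) -> np.ndarray:
    """Backbone (e+1, 4, 3) of residues 0..e built backwards from residue e+1."""
    g = IDEAL_GEOMETRY
    out = np.zeros((e + 1, 4, 3))
    Nn, CAn, Cn = bb[e + 1, 0], bb[e + 1, 1], bb[e + 1, 2]
    phi_after = phi_next
    omega_after = 180.0
    for i in range(e, -1, -1):
        C_i = place_atom(Cn, CAn, Nn, g["bond_c_n"], g["angle_c_n_ca"], phi_after)
        CA_i = place_atom(CAn, Nn, C_i, g["bond_ca_c"], g["angle_ca_c_n"], omega_after)
        N_i = place_atom(Nn, C_i, CA_i, g["bond_n_ca"], g["angle_n_ca_c"], torsions.psi[i])
        out[i, 0], out[i, 1], out[i, 2] = N_i, CA_i, C_i
        out[i, 3] = place_atom(N_i, CA_i, C_i, g["bond_c_o"], g["angle_ca_c_o"],
                               wrap_angle(torsions.psi[i] + 180.0))
        Nn, CAn, Cn = N_i, CA_i, C_i
        phi_after = torsions.phi[i]
        omega_after = torsions.omega[i - 1] if i > 0 else 180.0
    return out


def replace_window_torsions(
    model: ProteinModel,
    s: int,
    e: int,
    phi_new: np.ndarray,
    psi_new: np.ndarray,
    rng: np.random.Generator,
    pivots: tuple[int, int, int] | None = None,
) -> ProteinModel | None:
    """Rebuild residues [s, e] (0-based) from new torsions, keeping the rest.

    Interior windows are re-closed by triaxial loop closure (a random
    solution is taken); terminal windows rebuild freely. Returns None when
    no closure exists. Side-chain atoms in the window are re-attached at
    their previous chi angles.
    """
    L = len(model)
    bb = model.backbone_coords()
    t = compute_backbone_torsions(model)
    w = e - s + 1
    proposal = TorsionSeries(
        np.asarray(phi_new, dtype=float).copy(),
        np.asarray(psi_new, dtype=float).copy(),
        np.full(w, 180.0),
    )
    if len(proposal) != w:
        raise ValueError("torsion window length mismatch")

    if s == 0 and e == L - 1:
        full = t.copy()
        full.phi[:] = proposal.phi
        full.psi[:] = proposal.psi
        full.phi[0] = np.nan
        full.psi[-1] = np.nan
        from .geometry import rebuild_backbone_from_torsions

        reb = rebuild_backbone_from_torsions(full, bb[0, :3], sequence=model.sequence)
        new_bb = reb.backbone_coords()
    elif s == 0:
        phi_next = t.phi[e + 1]
        new_bb = bb.copy()
        new_bb[: e + 1] = _build_backward_span(bb, e, proposal, phi_next)
    elif e == L - 1:
        n_anchor = _window_anchors(bb, s)
        geo = BondGeometry.ideal(w, psi=proposal.psi)
        new_bb = bb.copy()
        new_bb[s:] = _loop_forward(proposal, n_anchor, geo)
    else:
        n_anchor = _window_anchors(bb, s)
        c_anchor = bb[e + 1, :3]
        phi_next = t.phi[e + 1]
        if w < 3:
            return None
        if pivots is None:
            if w == 3:
                pivots = (0, 1, 2)
            else:
                pivots = tuple(sorted(rng.choice(w, size=3, replace=False)))
        sols = triaxial_loop_closure(proposal, n_anchor, c_anchor, pivots, phi_next)
        if not sols:
            return None
        sol = sols[int(rng.integers(len(sols)))]
        _, loop_bb = loop_closure_gap(sol, n_anchor, c_anchor, phi_next)
        new_bb = bb.copy()
        new_bb[s: e + 1] = loop_bb

    out = model.copy()
    old_chis = {
        i: current_chis(model.residues[i])
        for i in range(s, e + 1)
        if current_chis(model.residues[i])
    }
    out.set_backbone_coords(new_bb)
    _reattach_sidechains(out, s, e, old_chis)
    return out


def _reattach_sidechains(model: ProteinModel, s: int, e: int, old_chis: dict) -> None:
    from .sidechain import place_cb

    g = IDEAL_GEOMETRY
    for i in range(s, e + 1):
        res = model.residues[i]
        if "CB" in res.atoms:
            res.atoms["CB"] = place_cb(res.atoms["N"], res.atoms["CA"], res.atoms["C"])
        chis = old_chis.get(i, [])
        if chis and "CG" in res.atoms:
            res.atoms["CG"] = place_atom(res.atoms["N"], res.atoms["CA"], res.atoms["CB"],
                                         g["bond_cb_cg"], g["angle_sidechain"], chis[0])
            if len(chis) > 1 and "CD" in res.atoms:
                res.atoms["CD"] = place_atom(res.atoms["CA"], res.atoms["CB"],
                                             res.atoms["CG"], g["bond_cg_cd"],
                                             g["angle_sidechain"], chis[1])


# ---------------------------------------------------------------------------
# the six operators
# ---------------------------------------------------------------------------

def select_error_weighted_window(profile: ResidueErrorProfile, w: int, L: int,
                                 rng: np.random.Generator) -> int:
    """Window start drawn with probability proportional to summed predicted error."""
    err = profile.predicted_error
    if err is None:
        raise ValueError("profile has no predicted_error")
    starts = np.arange(L - w + 1)
    weights = np.array([err[s: s + w].sum() for s in starts], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    return int(rng.choice(starts, p=weights / weights.sum()))


def op_fragment_assembly(model: ProteinModel, ctx: OperatorContext) -> OperatorResult:
    """Rebuild an error-weighted window from a random library fragment."""
    name = "fragment_assembly"
    lib = ctx.fraglib
    if lib is None or len(lib) == 0 or ctx.error_profile is None:
        return OperatorResult(model.copy(), name, noop=True)
    w = lib.window
    L = len(model)
    if w > L:
        return OperatorResult(model.copy(), name, noop=True)
    frags = [(phi, psi) for fw, phi, psi in lib.fragments if fw == w]
    for _ in range(ctx.cfg["tlc_max_attempts"]):
        s = select_error_weighted_window(ctx.error_profile, w, L, ctx.rng)
        phi, psi = frags[int(ctx.rng.integers(len(frags)))]
        out = replace_window_torsions(model, s, s + w - 1, phi, psi, ctx.rng)
        if out is not None and not out.chain_gaps():
            out.provenance = "trial"
            return OperatorResult(out, name)
    return OperatorResult(model.copy(), name, noop=True)


def op_loop_modelling(
    model: ProteinModel,
    partner: ProteinModel,
    ulr: tuple[int, int],
    mode: str,
    ctx: OperatorContext,
    mix_coeff: float = 0.5,
) -> OperatorResult:
    """Mix a ULR's torsions with a partner's, or mutate them with Gaussian noise.

    ``ulr`` is a 1-based inclusive residue range; ``mode`` is 'mix' or
    'mutate'. Non-ULR torsions are untouched (pivot residues absorb the
    closure adjustment).
    """
    name = "loop_modelling"
    if mode not in ("mix", "mutate"):
        raise ValueError(f"unknown loop modelling mode {mode!r}")
    if len(partner) != len(model):
        raise ValueError("partner must have the same length")
    s, e = ulr[0] - 1, ulr[1] - 1
    if not (0 <= s <= e < len(model)):
        raise ValueError("ULR out of range")
    t = compute_backbone_torsions(model)
    phi = t.phi[s: e + 1].copy()
    psi = t.psi[s: e + 1].copy()
    for attempt in range(ctx.cfg["tlc_max_attempts"]):
        if mode == "mix":
            tp = compute_backbone_torsions(partner)
            from .geometry import circular_difference

            nphi = wrap_angle(phi + mix_coeff * circular_difference(tp.phi[s: e + 1], phi))
            npsi = wrap_angle(psi + mix_coeff * circular_difference(tp.psi[s: e + 1], psi))
        else:
            # shrink the mutation on retries: small perturbations stay near
            # the (closed) current loop, where closure is feasible
            sigma = ctx.cfg["loop_mutate_sigma"] * 0.8 ** attempt
            nphi = wrap_angle(phi + ctx.rng.normal(0.0, sigma, len(phi)))
            npsi = wrap_angle(psi + ctx.rng.normal(0.0, sigma, len(psi)))
        if s == 0:
            nphi[0] = t.phi[0]
        if e == len(model) - 1:
            npsi[-1] = t.psi[-1]
        out = replace_window_torsions(model, s, e, nphi, npsi, ctx.rng)
        if out is not None and not out.chain_gaps():
            out.provenance = "trial"
            return OperatorResult(out, name)
    return OperatorResult(model.copy(), name, noop=True)


def op_sidechain_perturbation(model: ProteinModel, ctx: OperatorContext) -> OperatorResult:
    """Repack side chains on the coarse rotamer grid; backbone untouched."""
    name = "sidechain_perturbation"
    if not has_sidechains(model):
        return OperatorResult(model.copy(), name, noop=True)
    out = repack_sidechains(model, ctx.rng)
    out.provenance = "trial"
    return OperatorResult(out, name)


def nma_displacement(modes: ENModes, mode_index: int, amplitude: float) -> np.ndarray:
    """(L, 3) CA displacement along one mode, RMS-normalized to ``amplitude``."""
    v = modes.mode_vector(mode_index)
    rms = np.sqrt(np.mean(np.sum(v ** 2, axis=1)))
    if rms < 1e-12:
        return np.zeros_like(v)
    return v * (amplitude / rms)


def op_normal_mode_perturbation(
    model: ProteinModel,
    ctx: OperatorContext,
    amplitude: float | None = None,
    n_low_modes: int | None = None,
) -> OperatorResult:
    """Displace the structure along a random low-frequency network mode."""
    name = "normal_mode_perturbation"
    amplitude = ctx.cfg["nma_amplitude"] if amplitude is None else amplitude
    n_low_modes = ctx.cfg["enm_n_low_modes"] if n_low_modes is None else n_low_modes
    if amplitude == 0.0:
        return OperatorResult(model.copy(), name)
    try:
        modes = compute_enm_modes(model, ctx.cfg["enm_cutoff"])
    except ValueError:
        return OperatorResult(model.copy(), name, noop=True)
    first = modes.n_rigid()
    n_avail = min(n_low_modes, modes.eigenvectors.shape[1] - first)
    if n_avail < 1:
        return OperatorResult(model.copy(), name, noop=True)
    j = first + int(ctx.rng.integers(n_avail))
    disp = nma_displacement(modes, j, amplitude)
    out = model.copy()
    for i, res in enumerate(out.residues):
        for atom in res.atoms:
            res.atoms[atom] = res.atoms[atom] + disp[i]
    # restore covalent geometry with a short unrestrained minimization
    out = relax(out, None, RelaxSchedule(steps=20, mode="minimize"))
    out.provenance = "trial"
    return OperatorResult(out, name)


def op_hybridization(model: ProteinModel, ctx: OperatorContext) -> OperatorResult:
    """Replace a backbone span with a homolog-derived patch.

    The patch is superposed onto the model through its two terminal
    residues on each side, copied in rigidly, and the four-residue flanks
    on both sides are re-closed by loop closure. Residues outside the
    patch and its flanks are untouched.
    """
    name = "hybridization"
    lib = ctx.patch_library
    if lib is None or len(lib) == 0:
        return OperatorResult(model.copy(), name, noop=True)
    L = len(model)
    order = ctx.rng.permutation(len(lib.patches))
    for k in order[: ctx.cfg["tlc_max_attempts"]]:
        src, (a1, b1), patch_bb = lib.patches[int(k)]
        a, b = a1 - 1, b1 - 1
        if b >= L or a < 5 or b > L - 7:
            continue
        bb = model.backbone_coords()
        anchor_rows = [0, 1, b - a - 1, b - a]
        pts_patch = patch_bb[anchor_rows][:, :3, :].reshape(-1, 3)
        pts_model = bb[[a, a + 1, b - 1, b]][:, :3, :].reshape(-1, 3)
        tr, _ = kabsch_superpose(pts_patch, pts_model)
        moved = tr.apply(patch_bb.reshape(-1, 3)).reshape(patch_bb.shape)
        work = model.copy()
        new_bb = bb.copy()
        new_bb[a: b + 1] = moved
        work.set_backbone_coords(new_bb)
        closed = _close_junction(work, a - 4, a - 1)
        if closed is None:
            continue
        closed = _close_junction(closed, b + 1, b + 4)
        if closed is None or closed.chain_gaps():
            continue
        _reattach_sidechains(closed, a, b, {})
        closed.provenance = "trial"
        closed.meta["patch"] = (src, (a1, b1))
        return OperatorResult(closed, name)
    return OperatorResult(model.copy(), name, noop=True)


def _span_proposal(bb: np.ndarray, s: int, e: int):
    """Current-coordinate torsions of [s, e] plus anchors for closure.

    Values computed across a broken bond are only a search seed.
    """
    w = e - s + 1
    phi = np.zeros(w)
    psi = np.zeros(w)
    for k, i in enumerate(range(s, e + 1)):
        phi[k] = dihedral(bb[i - 1, 2], bb[i, 0], bb[i, 1], bb[i, 2])
        psi[k] = dihedral(bb[i, 0], bb[i, 1], bb[i, 2], bb[i + 1, 0])
    n_anchor = np.array([bb[s - 1, 2], bb[s, 0], bb[s, 1]])
    c_anchor = bb[e + 1, :3]
    phi_next = dihedral(bb[e, 2], bb[e + 1, 0], bb[e + 1, 1], bb[e + 1, 2])
    return TorsionSeries(phi, psi, np.full(w, 180.0)), n_anchor, c_anchor, phi_next


def close_span(model: ProteinModel, s: int, e: int,
               max_gap: float = 0.4) -> ProteinModel | None:
    """Re-close a (possibly broken) span [s, e] onto its fixed surroundings.

    Tries triaxial closure over several pivot sets (preferring the
    solution closest to the current torsions); if the fixed geometry
    admits no exact closure — short windows between rigid anchors need
    not have one — a least-squares torsion fit over the whole window is
    accepted when the residual junction gap stays below ``max_gap``
    (relaxation heals that strain). Returns None on failure.
    """
    from .geometry import circular_difference
    from .threading import _least_squares_close

    bb = model.backbone_coords()
    w = e - s + 1
    if w < 3 or s < 1 or e > len(model) - 2:
        return None
    proposal, n_anchor, c_anchor, phi_next = _span_proposal(bb, s, e)
    pivot_sets = [(0, w // 2, w - 1)]
    if w >= 4:
        pivot_sets += [(0, 1, w - 1), (0, w - 2, w - 1)]
    best = None
    for pivots in pivot_sets:
        sols = triaxial_loop_closure(proposal, n_anchor, c_anchor, pivots, phi_next)
        if sols:
            best = min(sols, key=lambda so: float(
                np.sum(np.abs(circular_difference(so.phi, proposal.phi))) +
                np.sum(np.abs(circular_difference(so.psi, proposal.psi)))))
            break
    if best is None:
        fitted = _least_squares_close(proposal, n_anchor, c_anchor, phi_next)
        gap, _ = loop_closure_gap(fitted, n_anchor, c_anchor, phi_next)
        if gap > max_gap:
            return None
        best = fitted
    _, loop_bb = loop_closure_gap(best, n_anchor, c_anchor, phi_next)
    out = model.copy()
    new_bb = bb.copy()
    new_bb[s: e + 1] = loop_bb
    out.set_backbone_coords(new_bb)
    _reattach_sidechains(out, s, e, {})
    return out


# kept name used by the hybridization operator
_close_junction = close_span


def op_secondary_structure_perturbation(
    model: ProteinModel,
    ctx: OperatorContext,
    max_rot: float | None = None,
    max_trans: float | None = None,
) -> OperatorResult:
    """Rigidly rotate/translate one secondary-structure chunk.

    The chunk (>= 4 consecutive H or E residues) moves as a rigid body
    about its CA centroid; flanking loops are re-closed (short termini
    follow the chunk rigidly). Internal chunk geometry is preserved
    exactly.
    """
    name = "secondary_structure_perturbation"
    max_rot = ctx.cfg["ss_max_rotation"] if max_rot is None else max_rot
    max_trans = ctx.cfg["ss_max_translation"] if max_trans is None else max_trans
    chunks = assign_secondary_structure(model).chunks(min_len=4)
    if not chunks:
        return OperatorResult(model.copy(), name, noop=True)
    _, cs, ce = chunks[int(ctx.rng.integers(len(chunks)))]
    angle = np.radians(ctx.rng.uniform(0.0, max_rot))
    axis = ctx.rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    shift = ctx.rng.normal(size=3)
    shift *= ctx.rng.uniform(0.0, max_trans) / np.linalg.norm(shift)
    if max_rot == 0.0 and max_trans == 0.0:
        return OperatorResult(model.copy(), name)

    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t_pre = compute_backbone_torsions(model)
    work = model.copy()
    centroid = model.coords("CA")[cs: ce + 1].mean(axis=0)
    for i in range(cs, ce + 1):
        res = work.residues[i]
        for atom in res.atoms:
            res.atoms[atom] = R @ (res.atoms[atom] - centroid) + centroid + shift

    L = len(model)
    # N-side
    if cs >= 5:
        closed = _close_flank_onto_chunk(work, cs - 4, cs - 1, t_pre, n_side=True)
        if closed is None:
            return OperatorResult(model.copy(), name, noop=True)
        work = closed
    elif cs > 0:
        bb = work.backbone_coords()
        tw = TorsionSeries(t_pre.phi[:cs].copy(), t_pre.psi[:cs].copy(),
                           np.full(cs, 180.0))
        bb[:cs] = _build_backward_span(bb, cs - 1, tw, t_pre.phi[cs])
        work.set_backbone_coords(bb)
        _reattach_sidechains(work, 0, cs - 1, {})
    # C-side
    tail = L - 1 - ce
    if tail >= 5:
        closed = _close_flank_onto_chunk(work, ce + 1, ce + 4, t_pre, n_side=False)
        if closed is None:
            return OperatorResult(model.copy(), name, noop=True)
        work = closed
    elif tail > 0:
        bb = work.backbone_coords()
        w = tail
        tw = TorsionSeries(t_pre.phi[ce + 1:].copy(), t_pre.psi[ce + 1:].copy(),
                           np.full(w, 180.0))
        geo = BondGeometry.ideal(w, psi=tw.psi)
        n_anchor = np.array([bb[ce, 2],
                             place_atom(bb[ce, 0], bb[ce, 1], bb[ce, 2],
                                        IDEAL_GEOMETRY["bond_c_n"],
                                        IDEAL_GEOMETRY["angle_ca_c_n"], t_pre.psi[ce]),
                             np.zeros(3)])
        ca1 = place_atom(bb[ce, 1], bb[ce, 2], n_anchor[1],
                         IDEAL_GEOMETRY["bond_n_ca"], IDEAL_GEOMETRY["angle_c_n_ca"], 180.0)
        n_anchor[2] = ca1
        bb[ce + 1:] = _loop_forward(tw, n_anchor, geo)
        work.set_backbone_coords(bb)
        _reattach_sidechains(work, ce + 1, L - 1, {})
    if work.chain_gaps():
        return OperatorResult(model.copy(), name, noop=True)
    work.provenance = "trial"
    return OperatorResult(work, name)


def _close_flank_onto_chunk(model, s, e, t_pre, n_side):
    """TLC on flank [s, e] between the fixed region and the moved chunk."""
    bb = model.backbone_coords()
    w = e - s + 1
    phi = t_pre.phi[s: e + 1].copy()
    psi = t_pre.psi[s: e + 1].copy()
    n_anchor = np.array([bb[s - 1, 2], bb[s, 0], bb[s, 1]])
    if n_side:
        # flank's own N/CA come from fixed-side torsions: keep current coords
        pass
    else:
        # flank starts right after the moved chunk: derive N/CA from the chunk
        g = IDEAL_GEOMETRY
        N1 = place_atom(bb[s - 1, 0], bb[s - 1, 1], bb[s - 1, 2], g["bond_c_n"],
                        g["angle_ca_c_n"], t_pre.psi[s - 1])
        CA1 = place_atom(bb[s - 1, 1], bb[s - 1, 2], N1, g["bond_n_ca"],
                         g["angle_c_n_ca"], 180.0)
        n_anchor = np.array([bb[s - 1, 2], N1, CA1])
    c_anchor = bb[e + 1, :3]
    phi_next = t_pre.phi[e + 1]
    proposal = TorsionSeries(phi, psi, np.full(w, 180.0))
    from .geometry import circular_difference
    from .threading import _least_squares_close

    sol = None
    for pivots in [(0, w // 2, w - 1), (0, 1, w - 1), (0, w - 2, w - 1)]:
        sols = triaxial_loop_closure(proposal, n_anchor, c_anchor, pivots, phi_next)
        if sols:
            sol = min(sols, key=lambda so: float(
                np.sum(np.abs(circular_difference(so.phi, phi))) +
                np.sum(np.abs(circular_difference(so.psi, psi)))))
            break
    if sol is None:
        sol = _least_squares_close(proposal, n_anchor, c_anchor, phi_next)
        gap, _ = loop_closure_gap(sol, n_anchor, c_anchor, phi_next)
        if gap > 0.4:
            return None
    _, loop_bb = loop_closure_gap(sol, n_anchor, c_anchor, phi_next)
    out = model.copy()
    new_bb = bb.copy()
    new_bb[s: e + 1] = loop_bb
    out.set_backbone_coords(new_bb)
    _reattach_sidechains(out, s, e, {})
    return out


OPERATOR_NAMES = (
    "fragment_assembly",
    "loop_modelling",
    "sidechain_perturbation",
    "normal_mode_perturbation",
    "hybridization",
    "secondary_structure_perturbation",
)


def apply_random_operator(model: ProteinModel, ctx: OperatorContext) -> OperatorResult:
    """Draw an operator by configured weight and apply it."""
    weights = np.array([ctx.cfg["operator_weights"][n] for n in OPERATOR_NAMES])
    weights = weights / weights.sum()
    name = ctx.rng.choice(OPERATOR_NAMES, p=weights)
    if name == "fragment_assembly":
        return op_fragment_assembly(model, ctx)
    if name == "loop_modelling":
        ulrs = ctx.error_profile.ulrs if ctx.error_profile else []
        if not ulrs or not ctx.pool:
            return OperatorResult(model.copy(), name, noop=True)
        ulr = ulrs[int(ctx.rng.integers(len(ulrs)))]
        partner = ctx.pool[int(ctx.rng.integers(len(ctx.pool)))]
        mode = "mix" if ctx.rng.random() < 0.5 else "mutate"
        return op_loop_modelling(model, partner, ulr, mode, ctx,
                                 mix_coeff=float(ctx.rng.random()))
    if name == "sidechain_perturbation":
        return op_sidechain_perturbation(model, ctx)
    if name == "normal_mode_perturbation":
        return op_normal_mode_perturbation(model, ctx)
    if name == "hybridization":
        return op_hybridization(model, ctx)
    return op_secondary_structure_perturbation(model, ctx)
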