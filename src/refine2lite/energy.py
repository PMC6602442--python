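"""Composite energy function and restrained relaxation.

The energy is a linear combination of surrogate physics terms (soft-sphere
sterics, a backbone N-O hydrogen-bond well, a coarse statistical torsion
potential, a radius-of-gyration compactness term) and restraints derived
from the input structure (CA Cartesian anchors plus CA-CA and N-O pair
distances). Restraints take either the harmonic form w*d^2 or the bounded
Lorentzian form w*d^2/(d^2+c^2); within each restraint class the worst
``neglect_fraction`` of restraints is dropped at every evaluation, so a
locally wrong input region cannot pin the model.

Relaxation is a gradient-based Cartesian minimization of the restrained
total plus bonded-geometry terms (bond lengths, 1-3 distances, omega
planarity) that stand in for short restrained molecular dynamics; the
noisy-minimize mode interleaves seeded Gaussian kicks and side-chain
repacking between minimization segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .config import DEFAULTS, IDEAL_GEOMETRY, VDW_RADII
from .geometry import kabsch_superpose, wrap_angle
from .metrics import RAMA_BASINS
from .structure_io import ProteinModel

# bonded-geometry force constants (energy units per A^2 / per rad^2)
K_BOND = 100.0
K_13 = 30.0
K_OMEGA = 5.0

# hydrogen-bond well: reward around 2.7-3.3 A
HBOND_R0 = 3.0
HBOND_SIGMA = 0.3
HBOND_CUTOFF = 5.0

# statistical torsion term
RAMA_WEIGHTS = (0.50, 0.35, 0.15)
RAMA_SIGMA = 35.0      # degrees
RAMA_FLOOR = 1e-6

RG_COEF = 2.2          # Rg_expected = 2.2 * L^0.38 (A)
RG_EXP = 0.38


@dataclass
class RestraintSet:
    """Restraints derived from an input model.

    ``ca_pairs``/``no_pairs`` rows are (residue i, residue j) 0-based
    positions; targets in Angstrom. ``no_pairs`` couples backbone N of i
    with backbone O of j.
    """

    ca_anchor: np.ndarray                  # (L, 3) target CA coordinates
    ca_pairs: np.ndarray                   # (P, 2) int
    ca_pair_targets: np.ndarray            # (P,)
    no_pairs: np.ndarray                   # (Q, 2) int
    no_pair_targets: np.ndarray            # (Q,)
    form: str = "lorentzian"               # harmonic | lorentzian
    neglect_fraction: float = 0.10
    softness: float = 3.0                  # Lorentzian c (A)
    weight_anchor: float = 1.0
    weight_ca_pair: float = 1.0
    weight_no_pair: float = 1.0

    def __post_init__(self):
        if self.form not in ("harmonic", "lorentzian"):
            raise ValueError(f"unknown restraint form {self.form!r}")
        if not 0.0 <= self.neglect_fraction < 1.0:
            raise ValueError("neglect_fraction must be in [0, 1)")


@dataclass
class EnergyBreakdown:
    """Per-term energies; totals with and without the restraint term."""

    steric: float
    hbond: float
    torsion_stat: float
    compactness: float
    restraint: float

    @property
    def total_with_restraints(self) -> float:
        return self.steric + self.hbond + self.torsion_stat + self.compactness + self.restraint

    @property
    def total_without_restraints(self) -> float:
        return self.steric + self.hbond + self.torsion_stat + self.compactness


@dataclass
class RelaxSchedule:
    """Relaxation control: step count, mode, repack interval, seed."""

    steps: int
    mode: str = "minimize"                 # minimize | noisy-minimize
    sidechain_repack_every: int = 100
    rng_seed: int = 0

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.mode not in ("minimize", "noisy-minimize"):
            raise ValueError(f"unknown relax mode {self.mode!r}")


def build_restraints(
    initial: ProteinModel,
    form: str = "lorentzian",
    neglect_fraction: float | None = None,
    cfg: dict | None = None,
) -> RestraintSet:
    """Restraints from an input model: one CA anchor per residue, all CA-CA
    pairs with |i-j| >= 4 under 12 A, all backbone N-O pairs under 3.5 A."""
    cfg = cfg or DEFAULTS
    if neglect_fraction is None:
        neglect_fraction = (
            cfg["conservative_neglect_fraction"] if form == "harmonic"
            else cfg["neglect_fraction"]
        )
    ca = initial.coords("CA")
    n_xyz = initial.coords("N")
    o_xyz = initial.coords("O")
    L = len(ca)
    min_sep = cfg["ca_pair_min_sep"]
    ca_cut = cfg["ca_pair_cutoff"]
    no_cut = cfg["no_pair_cutoff"]
    pairs, ptargets = [], []
    d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
    for i in range(L):
        for j in range(i + min_sep, L):
            if d[i, j] < ca_cut:
                pairs.append((i, j))
                ptargets.append(d[i, j])
    nopairs, ntargets = [], []
    dno = np.linalg.norm(n_xyz[:, None] - o_xyz[None, :], axis=-1)
    for i in range(L):
        for j in range(L):
            if abs(i - j) >= 2 and dno[i, j] < no_cut:
                nopairs.append((i, j))
                ntargets.append(dno[i, j])
    return RestraintSet(
        ca_anchor=ca.copy(),
        ca_pairs=np.array(pairs, dtype=int).reshape(-1, 2),
        ca_pair_targets=np.array(ptargets, dtype=float),
        no_pairs=np.array(nopairs, dtype=int).reshape(-1, 2),
        no_pair_targets=np.array(ntargets, dtype=float),
        form=form,
        neglect_fraction=neglect_fraction,
        softness=cfg["lorentzian_softness"],
        weight_anchor=cfg["restraint_weight_anchor"],
        weight_ca_pair=cfg["restraint_weight_ca_pair"],
        weight_no_pair=cfg["restraint_weight_no_pair"],
    )


def _penalty(dev: np.ndarray, w: float, form: str, c: float):
    """Penalty and d(penalty)/d(dev) for deviation magnitudes >= 0."""
    d2 = dev ** 2
    if form == "harmonic":
        return w * d2, 2.0 * w * dev
    denom = d2 + c ** 2
    return w * d2 / denom, 2.0 * w * dev * c ** 2 / denom ** 2


def _neglect_mask(penalties: np.ndarray, fraction: float) -> np.ndarray:
    """Keep-mask dropping the ceil(fraction*N) largest penalties of a class."""
    n = len(penalties)
    keep = np.ones(n, dtype=bool)
    k = math.ceil(fraction * n)
    if 0 < k < n:
        keep[np.argsort(penalties)[n - k:]] = False
    elif k >= n and n > 0:
        keep[:] = False
    return keep


class _RestraintEval:
    """Restraint penalty + gradient at given coordinates.

    CA-anchor deviations are computed after superposing the anchor targets
    onto the current CAs; the gradient holds that superposition fixed
    (exact for uniform harmonic anchors, quasi-exact otherwise).
    """

    def __init__(self, restraints: RestraintSet, top: "_Topology"):
        self.r = restraints
        self.top = top
        L = len(top.ca_idx)
        if len(restraints.ca_anchor) != L:
            raise ValueError("restraint set does not match model length")
        for arr in (restraints.ca_pairs, restraints.no_pairs):
            if arr.size and arr.max() >= L:
                raise IndexError("restraint residue index out of range")

    def __call__(self, xyz: np.ndarray):
        r, top = self.r, self.top
        grad = np.zeros_like(xyz)
        total = 0.0
        ca = xyz[top.ca_idx]
        # --- CA anchors (superposed frame) ---
        tr, _ = kabsch_superpose(r.ca_anchor, ca)
        targets = tr.apply(r.ca_anchor)
        delta = ca - targets
        dev = np.linalg.norm(delta, axis=1)
        pen, dpen = _penalty(dev, r.weight_anchor, r.form, r.softness)
        keep = _neglect_mask(pen, r.neglect_fraction)
        total += float(pen[keep].sum())
        nz = keep & (dev > 1e-12)
        g = (dpen[nz] / dev[nz])[:, None] * delta[nz]
        np.add.at(grad, top.ca_idx[nz], g)
        # --- CA-CA pairs ---
        for pairs, targ, w, ai, bi in (
            (r.ca_pairs, r.ca_pair_targets, r.weight_ca_pair, top.ca_idx, top.ca_idx),
            (r.no_pairs, r.no_pair_targets, r.weight_no_pair, top.n_idx, top.o_idx),
        ):
            if len(pairs) == 0:
                continue
            ia = ai[pairs[:, 0]]
            ib = bi[pairs[:, 1]]
            diff = xyz[ia] - xyz[ib]
            dist = np.linalg.norm(diff, axis=1)
            dev = dist - targ
            pen, dpen = _penalty(np.abs(dev), w, r.form, r.softness)
            dpen = dpen * np.sign(dev)
            keep = _neglect_mask(pen, r.neglect_fraction)
            total += float(pen[keep].sum())
            nz = keep & (dist > 1e-12)
            g = (dpen[nz] / dist[nz])[:, None] * diff[nz]
            np.add.at(grad, ia[nz], g)
            np.add.at(grad, ib[nz], -g)
        return total, grad


def restraint_penalty(restraints: RestraintSet, model: ProteinModel) -> float:
    """Total restraint penalty of a model (neglect rule applied per class)."""
    top = _Topology(model)
    total, _ = _RestraintEval(restraints, top)(top.xyz)
    return total


class _Topology:
    """Static indexing of a model's atoms, bonded terms and torsion quads."""

    def __init__(self, model: ProteinModel):
        xyz, labels = model.atom_table()
        self.xyz = xyz
        self.labels = labels
        self.model = model
        L = len(model)
        index = {lab: k for k, lab in enumerate(labels)}
        self.index = index
        self.radii = np.array(
            [VDW_RADII.get(name[0], VDW_RADII["C"]) for _, name in labels]
        )
        self.respos = np.array([pos for pos, _ in labels])
        self.ca_idx = np.array([index[(i, "CA")] for i in range(L)])
        self.n_idx = np.array([index[(i, "N")] for i in range(L)])
        self.c_idx = np.array([index[(i, "C")] for i in range(L)])
        self.o_idx = np.array([index[(i, "O")] for i in range(L)])

        g = IDEAL_GEOMETRY
        bonds, btarg = [], []

        def bond(a, b, r0):
            bonds.append((a, b))
            btarg.append(r0)

        deg = np.radians
        d13 = lambda r1, r2, ang: math.sqrt(
            r1 * r1 + r2 * r2 - 2 * r1 * r2 * math.cos(deg(ang))
        )
        pairs13, t13 = [], []
        for i in range(L):
            n, ca, c, o = index[(i, "N")], index[(i, "CA")], index[(i, "C")], index[(i, "O")]
            bond(n, ca, g["bond_n_ca"])
            bond(ca, c, g["bond_ca_c"])
            bond(c, o, g["bond_c_o"])
            pairs13.append((n, c)); t13.append(d13(g["bond_n_ca"], g["bond_ca_c"], g["angle_n_ca_c"]))
            pairs13.append((ca, o)); t13.append(d13(g["bond_ca_c"], g["bond_c_o"], g["angle_ca_c_o"]))
            if (i, "CB") in index:
                cb = index[(i, "CB")]
                bond(ca, cb, g["bond_ca_cb"])
                if (i, "CG") in index:
                    cg = index[(i, "CG")]
                    bond(cb, cg, g["bond_cb_cg"])
                    pairs13.append((ca, cg)); t13.append(d13(g["bond_ca_cb"], g["bond_cb_cg"], g["angle_sidechain"]))
                    if (i, "CD") in index:
                        cd = index[(i, "CD")]
                        bond(cg, cd, g["bond_cg_cd"])
                        pairs13.append((cb, cd)); t13.append(d13(g["bond_cb_cg"], g["bond_cg_cd"], g["angle_sidechain"]))
            if i < L - 1:
                n1, ca1 = index[(i + 1, "N")], index[(i + 1, "CA")]
                bond(c, n1, g["bond_c_n"])
                pairs13.append((ca, n1)); t13.append(d13(g["bond_ca_c"], g["bond_c_n"], g["angle_ca_c_n"]))
                pairs13.append((c, ca1)); t13.append(d13(g["bond_c_n"], g["bond_n_ca"], g["angle_c_n_ca"]))
                pairs13.append((o, n1)); t13.append(d13(g["bond_c_o"], g["bond_c_n"], 360.0 - g["angle_ca_c_o"] - g["angle_ca_c_n"]))
        self.bonds = np.array(bonds, dtype=int)
        self.bond_targets = np.array(btarg)
        self.pairs13 = np.array(pairs13, dtype=int)
        self.targets13 = np.array(t13)
        self.omega_quads = np.array(
            [
                [self.ca_idx[i], self.c_idx[i], self.n_idx[i + 1], self.ca_idx[i + 1]]
                for i in range(L - 1)
            ],
            dtype=int,
        ).reshape(-1, 4)
        self.phi_quads = np.array(
            [
                [self.c_idx[i - 1], self.n_idx[i], self.ca_idx[i], self.c_idx[i]]
                for i in range(1, L)
            ],
            dtype=int,
        ).reshape(-1, 4)
        self.psi_quads = np.array(
            [
                [self.n_idx[i], self.ca_idx[i], self.c_idx[i], self.n_idx[i + 1]]
                for i in range(L - 1)
            ],
            dtype=int,
        ).reshape(-1, 4)
        # rama residues with both torsions defined: 1..L-2
        self.rama_phi = self.phi_quads[: L - 2] if L > 2 else self.phi_quads[:0]
        self.rama_psi = self.psi_quads[1: L - 1] if L > 2 else self.psi_quads[:0]

        # non-bonded candidates: residue separation >= 2
        iu = np.triu_indices(len(xyz), k=1)
        sep = np.abs(self.respos[iu[0]] - self.respos[iu[1]])
        keep = sep >= 2
        self.nb_i = iu[0][keep]
        self.nb_j = iu[1][keep]
        self.nb_r0 = self.radii[self.nb_i] + self.radii[self.nb_j] - 0.4
        # backbone N-O hydrogen-bond candidates
        hb = [
            (self.n_idx[i], self.o_idx[j])
            for i in range(L)
            for j in range(L)
            if abs(i - j) >= 2
        ]
        hb = np.array(hb, dtype=int).reshape(-1, 2)
        self.hb_i, self.hb_j = hb[:, 0], hb[:, 1]


def _dihedrals_and_grads(xyz, quads, want_grad=True):
    """Vectorized dihedrals (radians) and their coordinate gradients."""
    x1, x2, x3, x4 = (xyz[quads[:, k]] for k in range(4))
    b1 = x2 - x1
    b2 = x3 - x2
    b3 = x4 - x3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    phi = np.arctan2(y, x)
    if not want_grad:
        return phi, None
    sn1 = np.sum(n1 * n1, axis=1)
    sn2 = np.sum(n2 * n2, axis=1)
    g1 = (nb2 / sn1)[:, None] * n1
    g4 = -(nb2 / sn2)[:, None] * n2
    f12 = (np.sum(b1 * b2, axis=1) / nb2 ** 2)[:, None]
    f32 = (np.sum(b3 * b2, axis=1) / nb2 ** 2)[:, None]
    g2 = -(1.0 + f12) * g1 + f32 * g4
    g3 = f12 * g1 - (1.0 + f32) * g4
    return phi, (g1, g2, g3, g4)


def _accumulate_quad(grad, quads, gs, scale):
    for k, g in enumerate(gs):
        np.add.at(grad, quads[:, k], scale[:, None] * g)


def _physics_terms(xyz, top: "_Topology", want_grad=True):
    """Steric, hbond, torsion_stat, compactness energies and gradients."""
    grad = {name: np.zeros_like(xyz) for name in
            ("steric", "hbond", "torsion_stat", "compactness")} if want_grad else None

    # steric soft sphere
    diff = xyz[top.nb_i] - xyz[top.nb_j]
    d = np.linalg.norm(diff, axis=1)
    mask = d < top.nb_r0
    over = 1.0 - d[mask] / top.nb_r0[mask]
    e_steric = float(np.sum(over ** 2))
    if want_grad and np.any(mask):
        dd = (-2.0 * over / top.nb_r0[mask] / d[mask])[:, None] * diff[mask]
        np.add.at(grad["steric"], top.nb_i[mask], dd)
        np.add.at(grad["steric"], top.nb_j[mask], -dd)

    # backbone hydrogen-bond well
    diff = xyz[top.hb_i] - xyz[top.hb_j]
    d = np.linalg.norm(diff, axis=1)
    mask = d < HBOND_CUTOFF
    z = (d[mask] - HBOND_R0) / HBOND_SIGMA
    well = np.exp(-0.5 * z ** 2)
    e_hbond = float(-np.sum(well))
    if want_grad and np.any(mask):
        dEdd = well * z / HBOND_SIGMA
        g = (dEdd / d[mask])[:, None] * diff[mask]
        np.add.at(grad["hbond"], top.hb_i[mask], g)
        np.add.at(grad["hbond"], top.hb_j[mask], -g)

    # statistical torsion term
    e_rama = 0.0
    if len(top.rama_phi):
        phi, gphi = _dihedrals_and_grads(xyz, top.rama_phi, want_grad)
        psi, gpsi = _dihedrals_and_grads(xyz, top.rama_psi, want_grad)
        phi_d = np.degrees(phi)
        psi_d = np.degrees(psi)
        vals = np.zeros((len(phi_d), len(RAMA_BASINS)))
        dphis = np.zeros_like(vals)
        dpsis = np.zeros_like(vals)
        for k, ((bp, bs), w) in enumerate(zip(RAMA_BASINS, RAMA_WEIGHTS)):
            dphi = wrap_angle(phi_d - bp)
            dpsi = wrap_angle(psi_d - bs)
            vals[:, k] = w * np.exp(-(dphi ** 2 + dpsi ** 2) / (2 * RAMA_SIGMA ** 2))
            dphis[:, k] = dphi
            dpsis[:, k] = dpsi
        total_v = vals.sum(axis=1) + RAMA_FLOOR
        e_rama = float(-np.sum(np.log(total_v)))
        if want_grad:
            dEdphi = np.sum(vals * dphis, axis=1) / (RAMA_SIGMA ** 2 * total_v)
            dEdpsi = np.sum(vals * dpsis, axis=1) / (RAMA_SIGMA ** 2 * total_v)
            conv = 180.0 / np.pi
            _accumulate_quad(grad["torsion_stat"], top.rama_phi, gphi, dEdphi * conv)
            _accumulate_quad(grad["torsion_stat"], top.rama_psi, gpsi, dEdpsi * conv)

    # compactness
    ca = xyz[top.ca_idx]
    L = len(ca)
    center = ca.mean(axis=0)
    dev = ca - center
    rg = math.sqrt(float(np.mean(np.sum(dev ** 2, axis=1))))
    rg0 = RG_COEF * L ** RG_EXP
    e_comp = (rg - rg0) ** 2
    if want_grad and rg > 1e-9:
        g = (2.0 * (rg - rg0) / (L * rg)) * dev
        np.add.at(grad["compactness"], top.ca_idx, g)

    energies = {
        "steric": e_steric, "hbond": e_hbond,
        "torsion_stat": e_rama, "compactness": e_comp,
    }
    return energies, grad


def _bonded_terms(xyz, top: "_Topology", want_grad=True):
    grad = np.zeros_like(xyz) if want_grad else None
    total = 0.0
    for pairs, targets, k in (
        (top.bonds, top.bond_targets, K_BOND),
        (top.pairs13, top.targets13, K_13),
    ):
        diff = xyz[pairs[:, 0]] - xyz[pairs[:, 1]]
        d = np.linalg.norm(diff, axis=1)
        dev = d - targets
        total += float(k * np.sum(dev ** 2))
        if want_grad:
            g = (2.0 * k * dev / np.maximum(d, 1e-12))[:, None] * diff
            np.add.at(grad, pairs[:, 0], g)
            np.add.at(grad, pairs[:, 1], -g)
    if len(top.omega_quads):
        om, gs = _dihedrals_and_grads(xyz, top.omega_quads, want_grad)
        delta = np.arctan2(np.sin(om - np.pi), np.cos(om - np.pi))
        total += float(K_OMEGA * np.sum(delta ** 2))
        if want_grad:
            _accumulate_quad(grad, top.omega_quads, gs, 2.0 * K_OMEGA * delta)
    return total, grad


def evaluate_energy(
    model: ProteinModel,
    restraints: RestraintSet | None = None,
    weights: dict | None = None,
) -> EnergyBreakdown:
    """Weighted per-term energies of a model (no bonded-geometry terms)."""
    weights = weights or DEFAULTS["weights"]
    top = _Topology(model)
    energies, _ = _physics_terms(top.xyz, top, want_grad=False)
    restraint = 0.0
    if restraints is not None:
        restraint, _ = _RestraintEval(restraints, top)(top.xyz)
    return EnergyBreakdown(
        steric=weights["steric"] * energies["steric"],
        hbond=weights["hbond"] * energies["hbond"],
        torsion_stat=weights["torsion_stat"] * energies["torsion_stat"],
        compactness=weights["compactness"] * energies["compactness"],
        restraint=weights["restraint"] * restraint,
    )


def energy_and_gradient(
    model: ProteinModel,
    restraints: RestraintSet | None = None,
    weights: dict | None = None,
    include_bonded: bool = False,
    xyz: np.ndarray | None = None,
    top: "_Topology" | None = None,
):
    """Total energy (with restraints) and its analytic coordinate gradient."""
    weights = weights or DEFAULTS["weights"]
    top = top or _Topology(model)
    xyz = top.xyz if xyz is None else xyz
    energies, grads = _physics_terms(xyz, top, want_grad=True)
    total = sum(weights[k] * energies[k] for k in energies)
    grad = sum(weights[k] * grads[k] for k in energies)
    if restraints is not None:
        e_r, g_r = _RestraintEval(restraints, top)(xyz)
        total += weights["restraint"] * e_r
        grad = grad + weights["restraint"] * g_r
    if include_bonded:
        e_b, g_b = _bonded_terms(xyz, top)
        total += e_b
        grad = grad + g_b
    return total, grad


def relax(
    model: ProteinModel,
    restraints: RestraintSet | None,
    schedule: RelaxSchedule,
    weights: dict | None = None,
) -> ProteinModel:
    """Restrained Cartesian relaxation.

    ``minimize`` mode guarantees the final objective (weighted terms +
    restraints + bonded geometry) does not exceed the initial one;
    ``noisy-minimize`` interleaves seeded Gaussian coordinate kicks (and
    side-chain repacking, when side chains exist) between minimization
    segments to emulate a short heated trajectory.
    """
    if schedule.steps == 0:
        return model.copy()
    weights = weights or DEFAULTS["weights"]
    work = model.copy()
    top = _Topology(work)
    reval = _RestraintEval(restraints, top) if restraints is not None else None

    def objective(flat):
        xyz = flat.reshape(-1, 3)
        total, grad = energy_and_gradient(
            work, restraints=None, weights=weights, include_bonded=True,
            xyz=xyz, top=top,
        )
        if reval is not None:
            e_r, g_r = reval(xyz)
            total += weights["restraint"] * e_r
            grad = grad + weights["restraint"] * g_r
        if not np.isfinite(total):
            raise FloatingPointError("non-finite energy during relaxation")
        return total, grad.ravel()

    x0 = top.xyz.ravel().copy()
    best = {"x": x0.copy(), "f": np.inf}

    def tracked(flat):
        f, g = objective(flat)
        if f < best["f"]:
            best["f"], best["x"] = f, flat.copy()
        return f, g

    tracked(x0)
    if schedule.mode == "minimize":
        _scipy_minimize(
            tracked, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": schedule.steps, "maxcor": 12},
        )
    else:
        rng = np.random.default_rng(schedule.rng_seed)
        nseg = max(1, schedule.steps // max(1, schedule.sidechain_repack_every))
        seg_steps = max(1, schedule.steps // nseg)
        x = x0.copy()
        from .sidechain import has_sidechains, repack_sidechains

        for _ in range(nseg):
            x = x + rng.normal(0.0, DEFAULTS["noise_amplitude"], size=x.shape)
            if has_sidechains(work):
                _write_coords(work, top, x)
                repacked = repack_sidechains(work, rng)
                top2 = _Topology(repacked)
                x = top2.xyz.ravel().copy()
                work.residues = repacked.residues
                top.__init__(work)
            res = _scipy_minimize(
                objective, x, jac=True, method="L-BFGS-B",
                options={"maxiter": seg_steps, "maxcor": 12},
            )
            x = res.x
        best["x"] = x

    out = work.copy()
    _write_coords(out, _Topology(out), best["x"])
    out.provenance = model.provenance
    return out


def _write_coords(model: ProteinModel, top: "_Topology", flat: np.ndarray) -> None:
    xyz = flat.reshape(-1, 3)
    for (pos, name), row in zip(top.labels, xyz):
        model.residues[pos].atoms[name] = row.copy()
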