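"""Backbone geometry: torsions, rebuilding, superposition, loop closure.

Coordinates are Cartesian in Angstrom, torsions in degrees in (-180, 180].
Rebuilding is deterministic NeRF-style placement from ideal covalent
geometry (overridable per call with geometry extracted from a model, which
makes torsion<->coordinate round trips exact).

The loop-closure solver follows the classic three-pivot ("triaxial")
reduction: with all non-pivot torsions held fixed, the three pivot CA atoms
form a triangle with known side lengths whose middle vertex moves on a
circle; for each position on that circle the two outer pivots reduce to
two-cone intersections, leaving a single scalar closure equation (the
N-CA-C bond angle at the middle pivot) in one variable. Roots are located
by a dense scan and polished with Brent's method; each root yields the six
pivot torsions that rejoin the chain to the fixed anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .config import IDEAL_GEOMETRY
from .structure_io import ProteinModel, model_from_backbone


# ---------------------------------------------------------------------------
# elementary vector algebra
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def _cross(a, b):
    # component formula: much faster than np.cross for small arrays
    ax, ay, az = a[..., 0], a[..., 1], a[..., 2]
    bx, by, bz = b[..., 0], b[..., 1], b[..., 2]
    return np.stack([ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx], axis=-1)


def wrap_angle(deg):
    """Map angle(s) in degrees to (-180, 180]."""
    a = np.asarray(deg, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def circular_difference(a, b):
    """Signed circular difference a - b in degrees, in (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = _cross(b0, b1)
    n2 = _cross(b1, b2)
    m1 = _cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    v1 = _unit(np.asarray(p0, dtype=float) - np.asarray(p1))
    v2 = _unit(np.asarray(p2, dtype=float) - np.asarray(p1))
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c with |cd|=bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    # scalar arithmetic: this is the innermost loop of chain rebuilding
    from math import cos, radians, sin, sqrt

    ax, ay, az = float(a[0]), float(a[1]), float(a[2])
    bx, by, bz = float(b[0]), float(b[1]), float(b[2])
    cx, cy, cz = float(c[0]), float(c[1]), float(c[2])
    theta = radians(angle_deg)
    chi = radians(torsion_deg)
    ux, uy, uz = cx - bx, cy - by, cz - bz            # b -> c
    un = sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx, vy, vz = bx - ax, by - ay, bz - az            # a -> b
    nx = vy * uz - vz * uy
    ny = vz * ux - vx * uz
    nz = vx * uy - vy * ux
    nn = sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * uz - nz * uy
    my = nz * ux - nx * uz
    mz = nx * uy - ny * ux
    d0 = -bond * cos(theta)
    d1 = bond * sin(theta) * cos(chi)
    d2 = -bond * sin(theta) * sin(chi)
    return np.array(
        [cx + d0 * ux + d1 * mx + d2 * nx,
         cy + d0 * uy + d1 * my + d2 * ny,
         cz + d0 * uz + d1 * mz + d2 * nz]
    )


# ---------------------------------------------------------------------------
# torsion series and bond geometry
# ---------------------------------------------------------------------------

@dataclass
class TorsionSeries:
    """Per-residue phi/psi/omega in degrees; undefined entries are NaN.

    ``omega[i]`` is the peptide torsion between residues i and i+1;
    ``phi[0]``, ``psi[-1]`` and ``omega[-1]`` are undefined.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if not (len(self.phi) == len(self.psi) == len(self.omega)):
            raise ValueError("phi, psi, omega must have equal length")

    def __len__(self) -> int:
        return len(self.phi)

    def copy(self) -> "TorsionSeries":
        return TorsionSeries(self.phi.copy(), self.psi.copy(), self.omega.copy())


@dataclass
class RigidTransform:
    """Proper rotation + translation; applies as ``x @ rotation.T + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class BondGeometry:
    """Per-residue bond lengths/angles used when rebuilding from torsions."""

    bond_n_ca: np.ndarray
    bond_ca_c: np.ndarray
    bond_c_o: np.ndarray
    bond_c_n: np.ndarray        # between i and i+1; last entry unused
    angle_n_ca_c: np.ndarray
    angle_ca_c_o: np.ndarray
    angle_ca_c_n: np.ndarray    # between i and i+1
    angle_c_n_ca: np.ndarray    # between i and i+1
    o_dihedral: np.ndarray      # dihedral N-CA-C-O in degrees

    @classmethod
    def ideal(cls, n: int, psi: np.ndarray | None = None) -> "BondGeometry":
        g = IDEAL_GEOMETRY
        full = lambda v: np.full(n, v, dtype=float)
        if psi is None:
            o_dih = full(180.0)
        else:
            o_dih = np.where(np.isfinite(psi), wrap_angle(np.asarray(psi) + 180.0), 180.0)
        return cls(
            full(g["bond_n_ca"]), full(g["bond_ca_c"]), full(g["bond_c_o"]),
            full(g["bond_c_n"]), full(g["angle_n_ca_c"]), full(g["angle_ca_c_o"]),
            full(g["angle_ca_c_n"]), full(g["angle_c_n_ca"]), o_dih,
        )

    @classmethod
    def from_model(cls, model: ProteinModel) -> "BondGeometry":
        bb = model.backbone_coords()   # (L, 4, 3): N CA C O
        n = len(model)
        N, CA, C, O = bb[:, 0], bb[:, 1], bb[:, 2], bb[:, 3]
        dist = lambda a, b: np.linalg.norm(a - b, axis=-1)
        geo = cls.ideal(n)
        geo.bond_n_ca = dist(N, CA)
        geo.bond_ca_c = dist(CA, C)
        geo.bond_c_o = dist(C, O)
        geo.angle_n_ca_c = np.array([bond_angle(N[i], CA[i], C[i]) for i in range(n)])
        geo.angle_ca_c_o = np.array([bond_angle(CA[i], C[i], O[i]) for i in range(n)])
        geo.o_dihedral = np.array(
            [dihedral(N[i], CA[i], C[i], O[i]) for i in range(n)]
        )
        for i in range(n - 1):
            geo.bond_c_n[i] = dist(C[i], N[i + 1])
            geo.angle_ca_c_n[i] = bond_angle(CA[i], C[i], N[i + 1])
            geo.angle_c_n_ca[i] = bond_angle(C[i], N[i + 1], CA[i + 1])
        return geo


class ChainBreakError(ValueError):
    """Raised when torsions are requested across a broken chain."""


def compute_backbone_torsions(model: ProteinModel) -> TorsionSeries:
    """Standard phi/psi/omega series of a chain-intact model."""
    gaps = model.chain_gaps()
    if gaps:
        i = gaps[0]
        raise ChainBreakError(
            f"chain break between residues {model.residues[i].index} and "
            f"{model.residues[i + 1].index}"
        )
    bb = model.backbone_coords()
    n = len(model)
    N, CA, C = bb[:, 0], bb[:, 1], bb[:, 2]
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    for i in range(n):
        if i > 0:
            phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < n - 1:
            psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
            omega[i] = dihedral(CA[i], C[i], N[i + 1], CA[i + 1])
    return TorsionSeries(phi, psi, omega)


def rebuild_backbone_from_torsions(
    torsions: TorsionSeries,
    anchor: np.ndarray,
    bond_geometry: BondGeometry | None = None,
    sequence: str | None = None,
) -> ProteinModel:
    """Rebuild a backbone-only model from torsions and first-residue anchors.

    ``anchor`` is a (3, 3) array with the first residue's N, CA, C. Bond
    geometry defaults to ideal values (with O placed trans to psi).
    Undefined *interior* torsions raise; the terminal phi/psi may be NaN.
    """
    n = len(torsions)
    anchor = np.asarray(anchor, dtype=float)
    if anchor.shape != (3, 3):
        raise ValueError("anchor must be the (3,3) N/CA/C coordinates of residue 1")
    for name, arr, lo, hi in (
        ("phi", torsions.phi, 1, n), ("psi", torsions.psi, 0, n - 1),
        ("omega", torsions.omega, 0, n - 1),
    ):
        bad = np.where(~np.isfinite(arr[lo:hi]))[0]
        if bad.size:
            raise ValueError(f"undefined interior torsion {name} at position {bad[0] + lo + 1}")
    geo = bond_geometry or BondGeometry.ideal(n, psi=torsions.psi)
    bb = np.zeros((n, 4, 3))
    bb[0, 0], bb[0, 1], bb[0, 2] = anchor
    for i in range(n):
        N, CA, C = bb[i, 0], bb[i, 1], bb[i, 2]
        bb[i, 3] = place_atom(N, CA, C, geo.bond_c_o[i], geo.angle_ca_c_o[i],
                              geo.o_dihedral[i])
        if i == n - 1:
            break
        N1 = place_atom(N, CA, C, geo.bond_c_n[i], geo.angle_ca_c_n[i], torsions.psi[i])
        CA1 = place_atom(CA, C, N1, geo.bond_n_ca[i + 1], geo.angle_c_n_ca[i],
                         torsions.omega[i])
        C1 = place_atom(C, N1, CA1, geo.bond_ca_c[i + 1], geo.angle_n_ca_c[i + 1],
                        torsions.phi[i + 1])
        bb[i + 1, 0], bb[i + 1, 1], bb[i + 1, 2] = N1, CA1, C1
    seq = sequence or "A" * n
    return model_from_backbone(seq, bb, provenance="trial")


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the optimal proper-rotation transform and the resulting RMSD.
    Requires >= 3 non-degenerate points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("superposition requires at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate (rank-deficient) point configuration")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


# ---------------------------------------------------------------------------
# secondary structure from torsion bins
# ---------------------------------------------------------------------------

@dataclass
class SSAssignment:
    """Per-residue secondary-structure label in {H, E, C}."""

    labels: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.labels)

    def chunks(self, min_len: int = 4) -> list[tuple[str, int, int]]:
        """(label, start, end) runs of H/E of at least ``min_len``; 0-based inclusive."""
        out = []
        i = 0
        while i < len(self.labels):
            j = i
            while j + 1 < len(self.labels) and self.labels[j + 1] == self.labels[i]:
                j += 1
            if self.labels[i] in "HE" and j - i + 1 >= min_len:
                out.append((self.labels[i], i, j))
            i = j + 1
        return out


def assign_secondary_structure(model: ProteinModel) -> SSAssignment:
    """Torsion-bin assignment: H for helical phi/psi, E for extended, else C.

    Bins: H if phi in (-100,-30) and psi in (-80,-5); E if phi in (-180,-80)
    and psi in (80,180) or (-180,-170); else C. Singleton H/E runs are
    smoothed to C. Terminal residues with undefined torsions are C.
    """
    t = compute_backbone_torsions(model)
    labels = []
    for phi, psi in zip(t.phi, t.psi):
        if not (np.isfinite(phi) and np.isfinite(psi)):
            labels.append("C")
        elif -100 < phi < -30 and -80 < psi < -5:
            labels.append("H")
        elif -180 < phi < -80 and (80 < psi <= 180 or -180 <= psi < -170):
            labels.append("E")
        else:
            labels.append("C")
    for i, lab in enumerate(labels):  # smooth singletons
        if lab in "HE":
            prev_same = i > 0 and labels[i - 1] == lab
            next_same = i < len(labels) - 1 and labels[i + 1] == lab
            if not prev_same and not next_same:
                labels[i] = "C"
    return SSAssignment(labels)


# ---------------------------------------------------------------------------
# triaxial loop closure
# ---------------------------------------------------------------------------

def _loop_forward(torsions: TorsionSeries, n_anchor: np.ndarray,
                  geo: BondGeometry) -> np.ndarray:
    """Build loop backbone (m, 4, 3) from (C_prev, N1, CA1) anchors.

    Unlike :func:`rebuild_backbone_from_torsions`, phi of the *first* loop
    residue is used (the anchor supplies the preceding C).
    """
    m = len(torsions)
    C_prev, N1, CA1 = np.asarray(n_anchor, dtype=float)
    bb = np.zeros((m, 4, 3))
    bb[0, 0], bb[0, 1] = N1, CA1
    bb[0, 2] = place_atom(C_prev, N1, CA1, geo.bond_ca_c[0], geo.angle_n_ca_c[0],
                          torsions.phi[0])
    for i in range(m):
        N, CA, C = bb[i, 0], bb[i, 1], bb[i, 2]
        bb[i, 3] = place_atom(N, CA, C, geo.bond_c_o[i], geo.angle_ca_c_o[i],
                              geo.o_dihedral[i])
        if i == m - 1:
            break
        N1_ = place_atom(N, CA, C, geo.bond_c_n[i], geo.angle_ca_c_n[i], torsions.psi[i])
        CA1_ = place_atom(CA, C, N1_, geo.bond_n_ca[i + 1], geo.angle_c_n_ca[i],
                          torsions.omega[i])
        C1_ = place_atom(C, N1_, CA1_, geo.bond_ca_c[i + 1], geo.angle_n_ca_c[i + 1],
                         torsions.phi[i + 1])
        bb[i + 1, 0], bb[i + 1, 1], bb[i + 1, 2] = N1_, CA1_, C1_
    return bb


def loop_closure_gap(
    torsions: TorsionSeries,
    n_anchor: np.ndarray,
    c_anchor: np.ndarray,
    phi_next: float,
    omega_last: float = 180.0,
    geo: BondGeometry | None = None,
) -> tuple[float, np.ndarray]:
    """Rebuild a loop and measure how far its continuation misses the C anchor.

    Returns (gap, loop backbone). The gap is the maximum coordinate error
    over the predicted N/CA/C of the anchor residue after the loop.
    """
    m = len(torsions)
    geo = geo or BondGeometry.ideal(m, psi=torsions.psi)
    bb = _loop_forward(torsions, n_anchor, geo)
    N_t, CA_t, C_t = np.asarray(c_anchor, dtype=float)
    g = IDEAL_GEOMETRY
    Nn = place_atom(bb[-1, 0], bb[-1, 1], bb[-1, 2], g["bond_c_n"], g["angle_ca_c_n"],
                    torsions.psi[-1])
    CAn = place_atom(bb[-1, 1], bb[-1, 2], Nn, g["bond_n_ca"], g["angle_c_n_ca"],
                     omega_last)
    Cn = place_atom(bb[-1, 2], Nn, CAn, g["bond_ca_c"], g["angle_n_ca_c"], phi_next)
    gap = max(
        float(np.linalg.norm(Nn - N_t)),
        float(np.linalg.norm(CAn - CA_t)),
        float(np.linalg.norm(Cn - C_t)),
    )
    return gap, bb


def _cone_intersection(axis, u, cos_a, cos_c, sign):
    """Unit d with d.axis=cos_a, d.u=cos_c; vectorized over leading dims.

    Returns (d, valid mask). ``sign`` selects the branch off the axis-u plane.
    """
    g = np.sum(axis * u, axis=-1)
    denom = 1.0 - g ** 2
    valid = denom > 1e-12
    denom = np.where(valid, denom, 1.0)
    A = (cos_a - g * cos_c) / denom
    B = (cos_c - g * cos_a) / denom
    C2 = 1.0 - A ** 2 - B ** 2 - 2.0 * A * B * g
    valid = valid & (C2 >= 0.0)
    C = np.sqrt(np.clip(C2, 0.0, None))
    n = _cross(np.broadcast_to(axis, u.shape), u)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    n = n / np.where(nn > 1e-12, nn, 1.0)
    d = A[..., None] * axis + B[..., None] * u + sign * C[..., None] * n
    return d, valid, C2


def _frame_from(a, b):
    """Orthonormal frame (e1, e2, e3) with e1 along a, e2 in span(a,b); vectorized."""
    e1 = _unit(a)
    proj = b - np.sum(b * e1, axis=-1, keepdims=True) * e1
    e2 = _unit(proj)
    e3 = _cross(e1, e2)
    return e1, e2, e3


def _coeffs(point, origin, e1, e2, e3):
    v = point - origin
    return np.array([np.dot(v, e1), np.dot(v, e2), np.dot(v, e3)])


def _from_coeffs(coef, origin, e1, e2, e3):
    return origin + coef[0] * e1 + coef[1] * e2 + coef[2] * e3


def triaxial_loop_closure(
    torsions: TorsionSeries,
    n_anchor: np.ndarray,
    c_anchor: np.ndarray,
    pivots: tuple[int, int, int],
    phi_next: float,
    omega_last: float = 180.0,
    n_scan: int = 1080,
    gap_tol: float = 1e-6,
) -> list[TorsionSeries]:
    """All pivot-torsion assignments that close the loop onto both anchors.

    ``torsions`` covers the loop residues (phi/psi/omega, degrees); entries
    at the three ``pivots`` (0-based loop positions, p1 < p2 < p3) are free
    and will be overwritten. ``n_anchor`` = (C_prev, N1, CA1) coordinates,
    ``c_anchor`` = (N, CA, C) of the residue after the loop; ``phi_next`` is
    that residue's (fixed) phi. Returns a list of closed TorsionSeries; an
    empty list means no real solution.
    """
    m = len(torsions)
    p1, p2, p3 = pivots
    if not (0 <= p1 < p2 < p3 <= m - 1):
        raise ValueError("pivots must be distinct, ordered, inside the loop")
    if m < 3:
        raise ValueError("loop must have at least 3 residues")

    geo = BondGeometry.ideal(m, psi=torsions.psi)
    g = IDEAL_GEOMETRY
    eta = g["angle_n_ca_c"]

    # probe build with arbitrary pivot torsions to get exact fixed atoms and
    # rigid-body shapes (coefficients are invariant to the arbitrary values)
    probe = torsions.copy()
    for p in (p1, p2, p3):
        probe.phi[p] = 60.0
        probe.psi[p] = 60.0
    fwd = _loop_forward(probe, n_anchor, geo)

    N1p = fwd[p1, 0]
    CA1p = fwd[p1, 1]
    a1 = _unit(CA1p - N1p)                      # phi axis at pivot 1
    # body B1: atoms C(p1) .. CA(p2) in the frame anchored at CA(p1)
    f1 = _frame_from(fwd[p1, 2] - CA1p, fwd[p2, 1] - CA1p)
    r12 = float(np.linalg.norm(fwd[p2, 1] - CA1p))
    cos_c1 = float(np.dot(_unit(fwd[p1, 2] - CA1p), _unit(fwd[p2, 1] - CA1p)))
    cos_d1 = float(np.cos(np.radians(180.0 - eta)))  # angle(a1, CA1->C1)
    b1_N_p2 = _coeffs(fwd[p2, 0], CA1p, *f1)

    # backward build from the C anchor
    N_t, CA_t, C_t = np.asarray(c_anchor, dtype=float)
    bwd = np.full((m, 4, 3), np.nan)
    nxt = (N_t, CA_t, C_t)  # N, CA, C of residue after current
    probe_b = probe
    phi_after = phi_next
    omega_after = omega_last
    for i in range(m - 1, p2 - 1, -1):
        Nn, CAn, Cn = nxt
        C_i = place_atom(Cn, CAn, Nn, g["bond_c_n"], g["angle_c_n_ca"], phi_after)
        CA_i = place_atom(CAn, Nn, C_i, g["bond_ca_c"], g["angle_ca_c_n"], omega_after)
        N_i = place_atom(Nn, C_i, CA_i, g["bond_n_ca"], g["angle_n_ca_c"],
                         probe_b.psi[i])
        bwd[i, 0], bwd[i, 1], bwd[i, 2] = N_i, CA_i, C_i
        nxt = (N_i, CA_i, C_i)
        phi_after = probe_b.phi[i]
        omega_after = probe_b.omega[i - 1] if i > 0 else 180.0

    CA3p = bwd[p3, 1]
    C3p = bwd[p3, 2]
    a3 = _unit(C3p - CA3p)                      # psi axis direction at pivot 3
    f3 = _frame_from(bwd[p3, 0] - CA3p, bwd[p2, 1] - CA3p)
    r23 = float(np.linalg.norm(bwd[p2, 1] - CA3p))
    cos_c3 = float(np.dot(_unit(bwd[p3, 0] - CA3p), _unit(bwd[p2, 1] - CA3p)))
    cos_d3 = float(np.cos(np.radians(eta)))     # angle(CA3->C3, CA3->N3)
    b2_C_p2 = _coeffs(bwd[p2, 2], CA3p, *f3)

    # CA2 circle from the pivot triangle
    r13v = CA3p - CA1p
    r13 = float(np.linalg.norm(r13v))
    if r13 < 1e-9 or r13 > r12 + r23 or r13 < abs(r12 - r23):
        return []
    u13 = r13v / r13
    x = (r12 ** 2 - r23 ** 2 + r13 ** 2) / (2.0 * r13)
    rho2 = r12 ** 2 - x ** 2
    if rho2 <= 1e-12:
        return []
    rho = np.sqrt(rho2)
    center = CA1p + x * u13
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u13)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1c = _unit(_cross(u13, ref))
    e2c = _cross(u13, e1c)

    def geometry_at(theta, sA, sB):
        """N2, CA2, C2 positions (vectorized over theta and branch signs)."""
        th = np.atleast_1d(np.asarray(theta, dtype=float))
        sA = np.asarray(sA, dtype=float)
        sB = np.asarray(sB, dtype=float)
        if sA.ndim:
            sA = sA[:, None]
            sB = sB[:, None]
        ca2 = center + rho * (np.cos(th)[:, None] * e1c + np.sin(th)[:, None] * e2c)
        u = _unit(ca2 - CA1p)
        d1, ok1, c2a = _cone_intersection(a1, u, cos_d1, cos_c1, sA)
        up = _unit(ca2 - CA3p)
        d3, ok3, c2b = _cone_intersection(a3, up, cos_d3, cos_c3, sB)
        lf1 = _frame_from(d1, u)
        lf3 = _frame_from(d3, up)
        c = b1_N_p2
        N2 = CA1p + c[0] * lf1[0] + c[1] * lf1[1] + c[2] * lf1[2]
        c = b2_C_p2
        C2 = CA3p + c[0] * lf3[0] + c[1] * lf3[1] + c[2] * lf3[2]
        margin = np.minimum(c2a, c2b)
        return ca2, N2, C2, d1, d3, lf1, lf3, ok1 & ok3, margin

    def closure_fn(theta, sA, sB, with_margin=False):
        ca2, N2, C2, _, _, _, _, ok, margin = geometry_at(theta, sA, sB)
        v1 = _unit(N2 - ca2)
        v2 = _unit(C2 - ca2)
        ang = np.degrees(np.arccos(np.clip(np.sum(v1 * v2, axis=-1), -1.0, 1.0)))
        out = ang - eta
        out[~ok] = np.nan
        if with_margin:
            return out, margin
        return out

    thetas = np.linspace(0.0, 2.0 * np.pi, n_scan, endpoint=False)
    cell = 2.0 * np.pi / n_scan
    branches = [(1.0, 1.0), (1.0, -1.0), (-1.0, 1.0), (-1.0, -1.0)]

    # one coarse scan covering all four branches
    TH = np.tile(thetas, 4)
    SA = np.repeat([b[0] for b in branches], n_scan)
    SB = np.repeat([b[1] for b in branches], n_scan)
    vals_all, margin_all = closure_fn(TH, SA, SB, with_margin=True)
    vals_all = vals_all.reshape(4, n_scan)
    margin_all = margin_all.reshape(4, n_scan)

    # adaptively refine suspicious cells: validity boundaries (NaN
    # neighbours), narrow validity slivers (margin near zero while
    # invalid), and cells near small-magnitude local extrema can hide
    # root pairs or boundary roots that leave no coarse sign change
    fine_theta, fine_branch = [], []
    for bi, (sA, sB) in enumerate(branches):
        vals = vals_all[bi]
        margin = margin_all[bi]
        finite = np.isfinite(vals)
        nxt = np.roll(finite, -1)
        suspicious = finite != nxt
        suspicious |= ~finite & (margin > -0.05)
        suspicious |= np.roll(~finite & (margin > -0.05), 1)
        absv = np.where(finite, np.abs(vals), np.inf)
        is_min = (absv < 30.0) & (absv <= np.roll(absv, 1)) & (absv <= np.roll(absv, -1))
        suspicious |= is_min | np.roll(is_min, -1)
        ks = np.where(suspicious)[0]
        if len(ks):
            sub = (thetas[ks][:, None] + cell * np.arange(1, 64) / 64.0).ravel()
            fine_theta.append(sub)
            fine_branch.append(np.full(len(sub), bi))
    base_theta = np.concatenate([thetas] * 4)
    base_branch = np.repeat(np.arange(4), n_scan)
    if fine_theta:
        all_theta = np.concatenate([base_theta] + fine_theta)
        all_branch = np.concatenate([base_branch] + fine_branch)
    else:
        all_theta, all_branch = base_theta, base_branch
    sa_of = np.array([b[0] for b in branches])
    sb_of = np.array([b[1] for b in branches])
    vals_fine_all = closure_fn(all_theta, sa_of[all_branch], sb_of[all_branch])

    # bracket detection per branch (numpy), then one global bisection
    reg_lo, reg_hi, reg_b = [], [], []
    bnd_lo, bnd_hi, bnd_tv, bnd_vv, bnd_b = [], [], [], [], []
    roots_theta: list[float] = []
    roots_branch: list[int] = []
    for bi in range(4):
        sel = all_branch == bi
        order = np.argsort(all_theta[sel])
        th = all_theta[sel][order]
        v = vals_fine_all[sel][order]
        th2 = np.roll(th, -1).copy()
        th2[-1] = th[0] + 2.0 * np.pi
        v2 = np.roll(v, -1)
        f0, f1 = np.isfinite(v), np.isfinite(v2)
        for k in np.where(f0 != f1)[0]:
            tv, vv = (th[k], v[k]) if f0[k] else (th2[k], v2[k])
            if abs(vv) <= 45.0:
                bnd_lo.append(th[k]); bnd_hi.append(th2[k])
                bnd_tv.append(tv); bnd_vv.append(vv); bnd_b.append(bi)
        with np.errstate(invalid="ignore"):
            sign_change = f0 & f1 & ((v == 0.0) | (v * v2 < 0.0))
        for k in np.where(sign_change)[0]:
            reg_lo.append(th[k]); reg_hi.append(th2[k]); reg_b.append(bi)

    def _bisect(lo, hi, b_idx, func_vals_at):
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        vlo = func_vals_at(lo, b_idx)
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            vmid = func_vals_at(mid, b_idx)
            take_lo = np.isnan(vmid) | (np.sign(vmid) != np.sign(vlo))
            hi = np.where(take_lo, mid, hi)
            lo = np.where(take_lo, lo, mid)
            vlo = np.where(take_lo, vlo, vmid)
        return 0.5 * (lo + hi)

    g_at = lambda t, b: closure_fn(t, sa_of[b], sb_of[b])
    m_at = lambda t, b: closure_fn(t, sa_of[b], sb_of[b], with_margin=True)[1]

    if bnd_lo:
        b_idx = np.array(bnd_b)
        tb = _bisect(bnd_lo, bnd_hi, b_idx, m_at)
        for tb_k, tv, vv, bi in zip(tb, bnd_tv, bnd_vv, bnd_b):
            tbi, vbi = None, np.nan
            for eps in (0.0, 1e-12, 1e-10, 1e-8):
                tc = tb_k + np.sign(tv - tb_k) * eps if eps else tb_k
                vc = float(g_at(np.array([tc]), np.array([bi]))[0])
                if np.isfinite(vc):
                    tbi, vbi = tc, vc
                    break
            if tbi is None:
                continue
            if vv * vbi < 0.0:
                # oriented bracket: valid endpoint first, so NaN midpoints
                # (beyond the boundary) shrink toward the valid side
                reg_lo.append(tv); reg_hi.append(tbi); reg_b.append(bi)
            elif abs(vbi) < 0.05:
                roots_theta.append(tbi); roots_branch.append(bi)
    if reg_lo:
        b_idx = np.array(reg_b)
        polished = _bisect(reg_lo, reg_hi, b_idx, g_at)
        roots_theta.extend(polished)
        roots_branch.extend(b_idx)

    solutions: list[TorsionSeries] = []
    seen: list[np.ndarray] = []
    for root, bi in zip(roots_theta, roots_branch):
        sA, sB = branches[int(bi)]
        sol = _solution_at(float(root), sA, sB, geometry_at, torsions, fwd, bwd,
                           n_anchor, c_anchor, pivots, CA1p, N1p, CA3p, C3p,
                           N_t, g)
        if sol is None:
            continue
        gap, _ = loop_closure_gap(sol, n_anchor, c_anchor, phi_next,
                                  omega_last, None)
        if gap > gap_tol:
            continue
        key = np.concatenate([sol.phi[[p1, p2, p3]], sol.psi[[p1, p2, p3]]])
        if any(np.max(np.abs(circular_difference(key, s))) < 1e-3 for s in seen):
            continue
        seen.append(key)
        solutions.append(sol)
    return solutions


def _solution_at(theta, sA, sB, geometry_at, torsions, fwd, bwd, n_anchor, c_anchor,
                 pivots, CA1p, N1p, CA3p, C3p, N_t, g):
    """Extract the six pivot torsions for a polished closure root."""
    p1, p2, p3 = pivots
    m = len(torsions)
    ca2, N2, C2, d1, d3, lf1, lf3, ok, _ = geometry_at(np.array([theta]), sA, sB)
    if not ok[0]:
        return None
    ca2, N2, C2 = ca2[0], N2[0], C2[0]
    d1, d3 = d1[0], d3[0]
    lf1 = tuple(f[0] for f in lf1)
    lf3 = tuple(f[0] for f in lf3)
    C1 = CA1p + g["bond_ca_c"] * d1
    N3 = CA3p + g["bond_n_ca"] * d3

    # N(p1+1), C(p2-1) via the B1 frame; C(p2), N(p2+1), C(p3-1) via B2.
    f1 = _frame_from(fwd[p1, 2] - CA1p, fwd[p2, 1] - CA1p)
    f3 = _frame_from(bwd[p3, 0] - CA3p, bwd[p2, 1] - CA3p)
    to_lab1 = lambda pt: _from_coeffs(_coeffs(pt, CA1p, *f1), CA1p, *lf1)
    to_lab3 = lambda pt: _from_coeffs(_coeffs(pt, CA3p, *f3), CA3p, *lf3)

    N_p1n = to_lab1(fwd[p1 + 1, 0]) if p1 + 1 < p2 else N2
    C_p2m = to_lab1(fwd[p2 - 1, 2]) if p2 - 1 > p1 else C1
    N_p2n = to_lab3(bwd[p2 + 1, 0]) if p2 + 1 < p3 else N3
    C_p3m = to_lab3(bwd[p3 - 1, 2]) if p3 - 1 > p2 else C2
    C_prev = np.asarray(n_anchor, dtype=float)[0] if p1 == 0 else fwd[p1 - 1, 2]
    N_p3n = N_t if p3 == m - 1 else bwd[p3 + 1, 0]

    sol = torsions.copy()
    sol.phi[p1] = dihedral(C_prev, N1p, CA1p, C1)
    sol.psi[p1] = dihedral(N1p, CA1p, C1, N_p1n)
    sol.phi[p2] = dihedral(C_p2m, N2, ca2, C2)
    sol.psi[p2] = dihedral(N2, ca2, C2, N_p2n)
    sol.phi[p3] = dihedral(C_p3m, N3, CA3p, C3p)
    sol.psi[p3] = dihedral(N3, CA3p, C3p, N_p3n)
    return sol
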