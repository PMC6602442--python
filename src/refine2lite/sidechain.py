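"""Coarse side-chain handling: CB placement and grid-rotamer repacking.

Side chains are modelled at reduced detail: CB placed from the backbone,
then up to two pseudo-atoms (CG, CD) whose chi1/chi2 torsions are drawn
from the coarse gauche+/gauche-/trans grid. Repacking is a greedy sweep
minimizing the soft-sphere steric overlap; backbone coordinates are never
touched.
"""

from __future__ import annotations

import numpy as np

from .config import IDEAL_GEOMETRY, VDW_RADII
from .structure_io import ProteinModel

#: the coarse chi grid (degrees): gauche-, gauche+, trans
CHI_GRID = (-60.0, 60.0, 180.0)


def place_cb(res_n: np.ndarray, res_ca: np.ndarray, res_c: np.ndarray) -> np.ndarray:
    """Ideal CB position from backbone N/CA/C (tetrahedral branch)."""
    b = IDEAL_GEOMETRY["bond_ca_cb"]
    n_dir = res_n - res_ca
    c_dir = res_c - res_ca
    n_dir /= np.linalg.norm(n_dir)
    c_dir /= np.linalg.norm(c_dir)
    bisector = -(n_dir + c_dir)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(c_dir, n_dir)
    perp /= np.linalg.norm(perp)
    # ~54.75 deg off the backbone-plane bisector gives the L-configuration
    ang = np.radians(54.75)
    return res_ca + b * (np.cos(ang) * bisector + np.sin(ang) * perp)


def add_cb_atoms(model: ProteinModel) -> ProteinModel:
    """Return a copy with CB placed on every non-glycine residue lacking one."""
    out = model.copy()
    for res in out.residues:
        if res.aa != "G" and "CB" not in res.atoms:
            res.atoms["CB"] = place_cb(res.atoms["N"], res.atoms["CA"], res.atoms["C"])
    return out


def _chi_atoms(res) -> list[tuple[str, tuple[str, str, str]]]:
    """(moving atom, frame atoms) for each chi this residue carries."""
    out = []
    if "CG" in res.atoms and "CB" in res.atoms:
        out.append(("CG", ("N", "CA", "CB")))
        if "CD" in res.atoms:
            out.append(("CD", ("CA", "CB", "CG")))
    return out


def has_sidechains(model: ProteinModel) -> bool:
    return any("CG" in r.atoms for r in model.residues)


def current_chis(res) -> list[float]:
    from .geometry import dihedral

    chis = []
    for atom, (a, b, c) in _chi_atoms(res):
        chis.append(dihedral(res.atoms[a], res.atoms[b], res.atoms[c], res.atoms[atom]))
    return chis


def _steric_overlap(moving: np.ndarray, env: np.ndarray, env_radii: np.ndarray,
                    mov_radii: np.ndarray) -> float:
    if len(env) == 0 or len(moving) == 0:
        return 0.0
    d = np.linalg.norm(moving[:, None, :] - env[None, :, :], axis=-1)
    r0 = mov_radii[:, None] + env_radii[None, :] - 0.4
    over = np.clip(1.0 - d / r0, 0.0, None)
    return float(np.sum(over ** 2))


def repack_sidechains(model: ProteinModel, rng: np.random.Generator) -> ProteinModel:
    """Greedy grid repack of chi1/chi2 minimizing steric overlap.

    Residues are visited in a seeded random order; each takes the chi
    combination from the coarse grid with the least overlap against all
    atoms of other residues (separation >= 2). Backbone atoms are
    bit-identical to the input.
    """
    from .geometry import place_atom

    out = model.copy()
    packable = [i for i, r in enumerate(out.residues) if _chi_atoms(r)]
    if not packable:
        return out
    order = list(packable)
    rng.shuffle(order)
    g = IDEAL_GEOMETRY
    for i in order:
        res = out.residues[i]
        env_xyz, env_rad = [], []
        for j, other in enumerate(out.residues):
            if abs(j - i) < 2:
                continue
            for name, xyz in other.atoms.items():
                env_xyz.append(xyz)
                env_rad.append(VDW_RADII.get(name[0], VDW_RADII["C"]))
        env_xyz = np.asarray(env_xyz) if env_xyz else np.zeros((0, 3))
        env_rad = np.asarray(env_rad) if len(env_rad) else np.zeros(0)
        chis = _chi_atoms(res)
        best, best_coords = np.inf, None
        grids = [CHI_GRID] * len(chis)
        from itertools import product

        for combo in product(*grids):
            coords = {}
            frame = dict(res.atoms)
            for (atom, (a, b, c)), chi in zip(chis, combo):
                bond = g["bond_cb_cg"] if atom == "CG" else g["bond_cg_cd"]
                pos = place_atom(frame[a], frame[b], frame[c], bond,
                                 g["angle_sidechain"], chi)
                coords[atom] = pos
                frame[atom] = pos
            mov = np.array(list(coords.values()))
            mrad = np.array([VDW_RADII["C"]] * len(mov))
            score = _steric_overlap(mov, env_xyz, env_rad, mrad)
            if score < best:
                best, best_coords = score, coords
        for atom, pos in best_coords.items():
            res.atoms[atom] = pos
    return out
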