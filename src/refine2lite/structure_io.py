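"""Single-chain protein models: the core data types plus PDB reading/writing.

The in-memory model is deliberately small: an ordered list of residues,
each holding a name->coordinate map for its atoms. Backbone completeness
(N, CA, C, O), strictly increasing numbering and chain intactness are the
invariants the rest of the package relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .config import CHAIN_BREAK_CN, MAX_RESIDUES

BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine read as MET
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}


class PDBFormatError(ValueError):
    """Raised when an input structure violates the single-chain contract."""


@dataclass
class Residue:
    """One amino acid: 1-based index, one-letter code, atom coordinates (A)."""

    index: int
    aa: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "Residue":
        return Residue(self.index, self.aa, {k: v.copy() for k, v in self.atoms.items()})

    def has_backbone(self) -> bool:
        return all(name in self.atoms for name in BACKBONE_ATOMS)


@dataclass
class ProteinModel:
    """A single protein chain being refined.

    ``provenance`` labels where the model came from
    (input | trial | threaded | final).
    """

    chain_id: str
    residues: list[Residue]
    provenance: str = "input"
    meta: dict = field(default_factory=dict)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def copy(self) -> "ProteinModel":
        return ProteinModel(
            self.chain_id, [r.copy() for r in self.residues], self.provenance,
            dict(self.meta),
        )

    # --- array views -------------------------------------------------
    def coords(self, atom: str) -> np.ndarray:
        """(L, 3) array of one named atom per residue (must exist everywhere)."""
        return np.array([r.atoms[atom] for r in self.residues], dtype=float)

    def backbone_coords(self) -> np.ndarray:
        """(L, 4, 3) array of N, CA, C, O coordinates."""
        return np.array(
            [[r.atoms[a] for a in BACKBONE_ATOMS] for r in self.residues], dtype=float
        )

    def set_backbone_coords(self, bb: np.ndarray) -> None:
        bb = np.asarray(bb, dtype=float)
        if bb.shape != (len(self), 4, 3):
            raise ValueError(f"expected shape {(len(self), 4, 3)}, got {bb.shape}")
        for res, row in zip(self.residues, bb):
            for name, xyz in zip(BACKBONE_ATOMS, row):
                res.atoms[name] = np.array(xyz, dtype=float)

    def atom_table(self) -> tuple[np.ndarray, list[tuple[int, str]]]:
        """All atom coordinates plus parallel (residue position, atom name) labels.

        Residue position is the 0-based position in ``residues`` (not the
        author-assigned index). Order: residues in chain order, backbone
        atoms first, side-chain atoms in sorted name order.
        """
        xyz, labels = [], []
        for pos, res in enumerate(self.residues):
            names = [a for a in BACKBONE_ATOMS if a in res.atoms]
            names += sorted(a for a in res.atoms if a not in BACKBONE_ATOMS)
            for name in names:
                xyz.append(res.atoms[name])
                labels.append((pos, name))
        return np.asarray(xyz, dtype=float), labels

    def chain_gaps(self, threshold: float = CHAIN_BREAK_CN) -> list[int]:
        """0-based positions i where the C(i)-N(i+1) distance exceeds threshold."""
        gaps = []
        for i in range(len(self) - 1):
            d = np.linalg.norm(self.residues[i].atoms["C"] - self.residues[i + 1].atoms["N"])
            if d > threshold:
                gaps.append(i)
        return gaps


@dataclass
class ValidationReport:
    """Outcome of input validation; ``ok`` iff there are no violations."""

    n_residues: int
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def model_from_backbone(
    sequence: str,
    backbone: np.ndarray,
    chain_id: str = "A",
    start_index: int = 1,
    provenance: str = "input",
) -> ProteinModel:
    """Build a backbone-only model from an (L, 4, 3) N/CA/C/O coordinate array."""
    backbone = np.asarray(backbone, dtype=float)
    if backbone.shape != (len(sequence), 4, 3):
        raise ValueError("backbone shape must be (len(sequence), 4, 3)")
    residues = [
        Residue(
            start_index + i,
            aa,
            {name: np.array(backbone[i, j]) for j, name in enumerate(BACKBONE_ATOMS)},
        )
        for i, aa in enumerate(sequence)
    ]
    return ProteinModel(chain_id, residues, provenance)


def read_pdb(path: str, chain: str | None = None) -> ProteinModel:
    """Read a single-chain protein model from a PDB file.

    Alternate locations resolve to the highest-occupancy copy, hydrogens
    and waters/heteroatoms are ignored, MSE is read as MET, and only the
    first model of a multi-model file is used. A file with several protein
    chains requires an explicit ``chain`` selector.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no models found")
    st.setup_entities()
    model = st[0]
    chains = [ch for ch in model if _has_protein(ch)]
    if not chains:
        raise PDBFormatError(f"{path}: no protein chains found")
    if chain is not None:
        chains = [ch for ch in chains if ch.name == chain]
        if not chains:
            raise PDBFormatError(f"{path}: chain {chain!r} not found")
    elif len(chains) > 1:
        names = ", ".join(ch.name for ch in chains)
        raise PDBFormatError(
            f"{path}: multiple chains ({names}); pass an explicit chain selector"
        )
    gchain = chains[0]

    residues: list[Residue] = []
    incomplete: list[str] = []
    for gres in gchain:
        if gres.name not in THREE_TO_ONE:
            if gres.is_amino_acid():
                raise PDBFormatError(
                    f"{path}: unsupported non-standard residue {gres.name} "
                    f"{gres.seqid.num}"
                )
            continue  # heteroatoms, waters
        atoms: dict[str, np.ndarray] = {}
        best_occ: dict[str, float] = {}
        for atom in gres:
            if atom.element.is_hydrogen:
                continue
            name = atom.name
            if name == "SE":  # MSE selenium -> treat as SD-like, skip
                continue
            if name in atoms and atom.occ <= best_occ.get(name, -1.0):
                continue
            atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
            best_occ[name] = atom.occ
        res = Residue(gres.seqid.num, THREE_TO_ONE[gres.name], atoms)
        if not res.has_backbone():
            missing = [a for a in BACKBONE_ATOMS if a not in atoms]
            incomplete.append(f"{gres.name} {gres.seqid.num} missing {'/'.join(missing)}")
            continue
        if not all(np.all(np.isfinite(v)) for v in atoms.values()):
            raise PDBFormatError(f"{path}: non-finite coordinates at residue {gres.seqid.num}")
        residues.append(res)
    if incomplete:
        raise PDBFormatError(
            f"{path}: residues lacking backbone atoms: " + "; ".join(incomplete)
        )
    if not residues:
        raise PDBFormatError(f"{path}: no complete amino-acid residues")
    return ProteinModel(gchain.name, residues, provenance="input")


def _has_protein(chain: gemmi.Chain) -> bool:
    return any(res.name in THREE_TO_ONE for res in chain)


def write_pdb(model: ProteinModel, path: str) -> None:
    """Write standard ATOM records (element column populated) plus TER/END."""
    lines = []
    serial = 1
    for res in model.residues:
        resname = ONE_TO_THREE[res.aa]
        names = [a for a in BACKBONE_ATOMS if a in res.atoms]
        names += sorted(a for a in res.atoms if a not in BACKBONE_ATOMS)
        for name in names:
            x, y, z = res.atoms[name]
            element = name[0] if name[0] in "CNOS" else "C"
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad_name}{'':1s}{resname:>3s} "
                f"{model.chain_id:1s}{res.index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    last = model.residues[-1]
    lines.append(
        f"TER   {serial:5d}      {ONE_TO_THREE[last.aa]:>3s} "
        f"{model.chain_id:1s}{last.index:4d}"
    )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def validate_input(model: ProteinModel, max_residues: int = MAX_RESIDUES) -> ValidationReport:
    """Check the refinement-input contract; returns a report, never raises.

    Violation codes: OVER_LENGTH (> ``max_residues`` residues), CHAIN_BREAK
    (internal C-N gap > 2.0 A or a jump in residue numbering),
    NON_INCREASING (numbering not strictly increasing), MISSING_BACKBONE,
    NON_FINITE.
    """
    violations: list[str] = []
    n = len(model.residues)
    if n > max_residues:
        violations.append(f"OVER_LENGTH: {n} residues exceeds limit of {max_residues}")
    for res in model.residues:
        if not res.has_backbone():
            violations.append(f"MISSING_BACKBONE: residue {res.index}")
        elif not all(np.all(np.isfinite(v)) for v in res.atoms.values()):
            violations.append(f"NON_FINITE: residue {res.index}")
    indices = [r.index for r in model.residues]
    for a, b in zip(indices, indices[1:]):
        if b <= a:
            violations.append(f"NON_INCREASING: residue numbering {a} -> {b}")
        elif b != a + 1:
            violations.append(f"CHAIN_BREAK: numbering gap between residues {a} and {b}")
    if not any(v.startswith(("MISSING_BACKBONE", "NON_FINITE")) for v in violations):
        for i in model.chain_gaps():
            violations.append(
                "CHAIN_BREAK: C-N distance > "
                f"{CHAIN_BREAK_CN} A between residues "
                f"{model.residues[i].index} and {model.residues[i + 1].index}"
            )
    return ValidationReport(n_residues=n, violations=violations)
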