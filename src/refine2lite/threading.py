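"""Threading the input sequence onto homolog structures.

Given a homolog structure and a pairwise alignment, aligned query residues
inherit the homolog's backbone coordinates; unaligned query segments are
rebuilt with generic loop torsions and closed back onto the flanking
anchors (triaxial closure for segments of three or more residues, a
least-squares torsion fit for shorter ones). Threaded models are kept only
if their TM-score to the input model exceeds 0.5, then lightly optimized;
their non-ULR backbone windows become the patch library that the structure
hybridization operator draws from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .config import DEFAULTS, IDEAL_GEOMETRY
from .energy import RelaxSchedule, build_restraints, relax
from .geometry import TorsionSeries, loop_closure_gap, place_atom, triaxial_loop_closure
from .metrics import tm_score
from .sidechain import add_cb_atoms, has_sidechains, repack_sidechains
from .structure_io import ProteinModel, Residue


@dataclass
class AlignmentPair:
    """A pairwise query-template alignment (gapped strings of equal length)."""

    query_seq: str
    template_seq: str
    template_id: str = ""

    def __post_init__(self):
        if len(self.query_seq) != len(self.template_seq):
            raise ValueError("aligned sequences must have equal length")

    @property
    def query_ungapped(self) -> str:
        return self.query_seq.replace("-", "")

    @property
    def template_ungapped(self) -> str:
        return self.template_seq.replace("-", "")

    def coverage(self) -> float:
        """Fraction of query residues aligned to a template residue."""
        both = sum(
            1 for q, t in zip(self.query_seq, self.template_seq)
            if q != "-" and t != "-"
        )
        return both / max(len(self.query_ungapped), 1)


@dataclass
class PatchLibrary:
    """Non-ULR backbone fragments harvested from optimized threaded models.

    Each patch: (source id, 1-based inclusive query residue range,
    backbone coordinates (len, 4, 3)).
    """

    patches: list[tuple[str, tuple[int, int], np.ndarray]] = field(default_factory=list)
    window_bounds: tuple[int, int] = (5, 15)

    def __len__(self):
        return len(self.patches)


def read_alignment_fasta(path: str) -> AlignmentPair:
    """Aligned FASTA with exactly two sequences; first is the query."""
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned sequences, got {len(records)}")
    return AlignmentPair(
        query_seq=str(records[0].seq).upper(),
        template_seq=str(records[1].seq).upper(),
        template_id=records[1].id,
    )


def read_a3m(path: str) -> list[AlignmentPair]:
    """A3M alignment: first sequence is the ungapped query master.

    Lowercase template letters are insertions relative to the query and
    are dropped; '-' is a deletion. Returns one pairwise alignment per
    template row.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: A3M needs a query plus at least one template")
    query = str(records[0].seq).replace("-", "").upper()
    out = []
    for rec in records[1:]:
        row = str(rec.seq)
        tmpl_cols = [ch for ch in row if not ch.islower()]
        if len(tmpl_cols) != len(query):
            raise ValueError(
                f"{path}: row {rec.id} has {len(tmpl_cols)} match columns, "
                f"query has {len(query)}"
            )
        out.append(AlignmentPair(query, "".join(tmpl_cols).upper(), rec.id))
    return out


def _generic_loop_torsions(n: int) -> TorsionSeries:
    """Polyproline-II-like open loop used as the rebuild proposal."""
    return TorsionSeries(
        np.full(n, -70.0), np.full(n, 140.0), np.full(n, 180.0)
    )


def thread_sequence(
    input_seq: str, homolog: ProteinModel, alignment: AlignmentPair
) -> ProteinModel:
    """Thread ``input_seq`` onto a homolog backbone through an alignment.

    Aligned residues take the homolog's N/CA/C/O; unaligned segments are
    rebuilt and closed onto the flanking anchors. Side chains reduce to an
    ideal CB. ``meta['rebuilt']`` lists 0-based rebuilt positions.
    """
    if alignment.query_ungapped != input_seq:
        raise ValueError("alignment query does not match the input sequence")
    if alignment.template_ungapped != homolog.sequence:
        raise ValueError("alignment template does not match the homolog sequence")
    L = len(input_seq)
    coords: list[np.ndarray | None] = [None] * L
    qi = ti = 0
    for q, t in zip(alignment.query_seq, alignment.template_seq):
        if q != "-" and t != "-":
            res = homolog.residues[ti]
            coords[qi] = np.array([res.atoms[a] for a in ("N", "CA", "C", "O")])
        if q != "-":
            qi += 1
        if t != "-":
            ti += 1

    rebuilt = [i for i, c in enumerate(coords) if c is None]
    bb = np.zeros((L, 4, 3))
    for i, c in enumerate(coords):
        if c is not None:
            bb[i] = c
    for start, end in _segments(rebuilt):
        _rebuild_segment(bb, coords, start, end)

    residues = [
        Residue(i + 1, aa, {n: bb[i, k].copy() for k, n in enumerate(("N", "CA", "C", "O"))})
        for i, aa in enumerate(input_seq)
    ]
    model = ProteinModel(homolog.chain_id, residues, provenance="threaded",
                         meta={"rebuilt": rebuilt, "template_id": alignment.template_id})
    return add_cb_atoms(model)


def _segments(positions: list[int]) -> list[tuple[int, int]]:
    segs = []
    for p in positions:
        if segs and p == segs[-1][1] + 1:
            segs[-1] = (segs[-1][0], p)
        else:
            segs.append((p, p))
    return segs


def _rebuild_segment(bb: np.ndarray, coords, start: int, end: int) -> None:
    """Fill an unaligned span [start, end] between (or beyond) anchors."""
    L = len(coords)
    g = IDEAL_GEOMETRY
    n_seg = end - start + 1
    if start == 0 and end == L - 1:
        raise ValueError("alignment leaves no aligned residue to anchor on")
    if start == 0:
        # N-terminal extension: build backwards from the first anchor
        _extend_terminus(bb, anchor=end + 1, start=start, end=end, forward=False)
        return
    if end == L - 1:
        _extend_terminus(bb, anchor=start - 1, start=start, end=end, forward=True)
        return
    prev = bb[start - 1]
    nxt = bb[end + 1]
    c_anchor = nxt[:3]
    # the next residue's phi involves the segment's last C, which is being
    # placed, so it is genuinely free here; fix it at a generic loop value.
    # The preceding residue's psi only positions the inserted segment, so it
    # is free too — sampled across closure attempts.
    phi_next = -70.0
    rng = np.random.default_rng(10_000 + start)
    closed = None
    best = None
    best_gap = np.inf
    # dense grid over the free pre-segment psi: exact closure somewhere on
    # this circle is far preferable to a strained least-squares fit
    psi_prev_grid = list(np.linspace(-180.0, 175.0, 72))
    for attempt in range(len(psi_prev_grid) + 12):
        psi_prev = (psi_prev_grid[attempt] if attempt < len(psi_prev_grid)
                    else float(rng.uniform(-180, 180)))
        N1 = place_atom(prev[0], prev[1], prev[2], g["bond_c_n"],
                        g["angle_ca_c_n"], psi_prev)
        CA1 = place_atom(prev[1], prev[2], N1, g["bond_n_ca"],
                         g["angle_c_n_ca"], 180.0)
        n_anchor = np.array([prev[2], N1, CA1])
        proposal = _generic_loop_torsions(n_seg)
        if attempt >= len(psi_prev_grid):
            proposal.phi = proposal.phi + rng.uniform(-60, 60, n_seg)
            proposal.psi = proposal.psi + rng.uniform(-60, 60, n_seg)
        if n_seg >= 3:
            pivots = (0, n_seg // 2, n_seg - 1)
            sols = triaxial_loop_closure(proposal, n_anchor, c_anchor, pivots, phi_next)
            if sols:
                closed = (sols[0], n_anchor)
                break
        fitted = _least_squares_close(proposal, n_anchor, c_anchor, phi_next)
        gap, _ = loop_closure_gap(fitted, n_anchor, c_anchor, phi_next)
        if gap < best_gap:
            best_gap, best = gap, (fitted, n_anchor)
        if gap < 1e-3:
            break
    if closed is None:
        closed = best
    torsions, n_anchor = closed
    _, loop_bb = loop_closure_gap(torsions, n_anchor, c_anchor, phi_next)
    bb[start: end + 1] = loop_bb
    junction = np.linalg.norm(bb[end, 2] - nxt[0])
    if junction > IDEAL_GEOMETRY["bond_c_n"] + 0.1:
        # no exact torsion-space closure exists (tight insertions between
        # spatially adjacent anchors); distribute the strain over the
        # segment's covalent geometry, keeping aligned residues fixed
        bb[start: end + 1] = _cartesian_patch(bb[start: end + 1], prev, nxt)


def _extend_terminus(bb, anchor, start, end, forward):
    g = IDEAL_GEOMETRY
    rng = range(start, end + 1) if forward else range(end, start - 1, -1)
    prev = bb[anchor]
    for i in rng:
        if forward:
            N = place_atom(prev[0], prev[1], prev[2], g["bond_c_n"], g["angle_ca_c_n"], 140.0)
            CA = place_atom(prev[1], prev[2], N, g["bond_n_ca"], g["angle_c_n_ca"], 180.0)
            C = place_atom(prev[2], N, CA, g["bond_ca_c"], g["angle_n_ca_c"], -70.0)
            O = place_atom(N, CA, C, g["bond_c_o"], g["angle_ca_c_o"], -40.0)
        else:
            C = place_atom(prev[2], prev[1], prev[0], g["bond_c_n"], g["angle_c_n_ca"], -70.0)
            CA = place_atom(prev[1], prev[0], C, g["bond_ca_c"], g["angle_ca_c_n"], 180.0)
            N = place_atom(prev[0], C, CA, g["bond_n_ca"], g["angle_n_ca_c"], 140.0)
            O = place_atom(N, CA, C, g["bond_c_o"], g["angle_ca_c_o"], -40.0)
        bb[i] = np.array([N, CA, C, O])
        prev = bb[i]


def _cartesian_patch(seg_bb: np.ndarray, prev: np.ndarray, nxt: np.ndarray) -> np.ndarray:
    """Least-squares Cartesian repair of a segment's covalent geometry.

    Bond lengths and 1-3 (angle) distances inside the segment and across
    both junctions are pulled to ideal values; a weak positional tether
    keeps the result near the torsion-space solution. Flanking residues
    never move.
    """
    g = IDEAL_GEOMETRY
    n = len(seg_bb)
    x0 = seg_bb.reshape(-1, 3)
    N, CA, C, O = 0, 1, 2, 3
    idx = lambda i, a: 4 * i + a

    pairs, targets = [], []

    def bond(i, j, r0):
        pairs.append((i, j))
        targets.append(r0)

    import math

    d13 = lambda r1, r2, ang: math.sqrt(
        r1 * r1 + r2 * r2 - 2 * r1 * r2 * math.cos(math.radians(ang)))
    for i in range(n):
        bond(idx(i, N), idx(i, CA), g["bond_n_ca"])
        bond(idx(i, CA), idx(i, C), g["bond_ca_c"])
        bond(idx(i, C), idx(i, O), g["bond_c_o"])
        bond(idx(i, N), idx(i, C), d13(g["bond_n_ca"], g["bond_ca_c"], g["angle_n_ca_c"]))
        bond(idx(i, CA), idx(i, O), d13(g["bond_ca_c"], g["bond_c_o"], g["angle_ca_c_o"]))
        if i < n - 1:
            bond(idx(i, C), idx(i + 1, N), g["bond_c_n"])
            bond(idx(i, CA), idx(i + 1, N), d13(g["bond_ca_c"], g["bond_c_n"], g["angle_ca_c_n"]))
            bond(idx(i, C), idx(i + 1, CA), d13(g["bond_c_n"], g["bond_n_ca"], g["angle_c_n_ca"]))
    fixed = {"prev_C": prev[2], "prev_CA": prev[1], "next_N": nxt[0], "next_CA": nxt[1]}
    anchored = [
        (idx(0, N), fixed["prev_C"], g["bond_c_n"]),
        (idx(0, N), fixed["prev_CA"], d13(g["bond_ca_c"], g["bond_c_n"], g["angle_ca_c_n"])),
        (idx(0, CA), fixed["prev_C"], d13(g["bond_c_n"], g["bond_n_ca"], g["angle_c_n_ca"])),
        (idx(n - 1, C), fixed["next_N"], g["bond_c_n"]),
        (idx(n - 1, CA), fixed["next_N"], d13(g["bond_ca_c"], g["bond_c_n"], g["angle_ca_c_n"])),
        (idx(n - 1, C), fixed["next_CA"], d13(g["bond_c_n"], g["bond_n_ca"], g["angle_c_n_ca"])),
    ]

    def resid(flat):
        x = flat.reshape(-1, 3)
        out = []
        for (i, j), r0 in zip(pairs, targets):
            out.append(np.linalg.norm(x[i] - x[j]) - r0)
        for i, p, r0 in anchored:
            out.append(np.linalg.norm(x[i] - p) - r0)
        out.extend(0.05 * (flat - x0.ravel()))
        return np.array(out)

    res = least_squares(resid, x0.ravel(), method="trf", max_nfev=400)
    return res.x.reshape(n, 4, 3)


def _least_squares_close(proposal, n_anchor, c_anchor, phi_next):
    """Numeric fallback closure over all segment torsions."""
    n = len(proposal)

    def unpack(x):
        t = proposal.copy()
        t.phi = x[:n].copy()
        t.psi = x[n:].copy()
        return t

    def resid(x):
        gap, _ = loop_closure_gap(unpack(x), n_anchor, c_anchor, phi_next)
        # direction-resolved residuals give the optimizer a useful signal
        t = unpack(x)
        from .geometry import BondGeometry, _loop_forward

        geo = BondGeometry.ideal(n, psi=t.psi)
        bb = _loop_forward(t, n_anchor, geo)
        g = IDEAL_GEOMETRY
        Nn = place_atom(bb[-1, 0], bb[-1, 1], bb[-1, 2], g["bond_c_n"],
                        g["angle_ca_c_n"], t.psi[-1])
        CAn = place_atom(bb[-1, 1], bb[-1, 2], Nn, g["bond_n_ca"],
                         g["angle_c_n_ca"], 180.0)
        return np.concatenate([Nn - c_anchor[0], CAn - c_anchor[1]])

    x0 = np.concatenate([proposal.phi, proposal.psi])
    res = least_squares(resid, x0, method="trf", max_nfev=400)
    return unpack(res.x)


def filter_homologs_by_tmscore(
    threaded: list[ProteinModel],
    input_model: ProteinModel,
    threshold: float = 0.5,
) -> list[ProteinModel]:
    """Keep threaded models with TM-score strictly above ``threshold``."""
    return [m for m in threaded if tm_score(m, input_model) > threshold]


def optimize_threaded(
    models: list[ProteinModel],
    cfg: dict | None = None,
    seed: int = 0,
) -> list[ProteinModel]:
    """Light stand-in optimization: one repack plus a short restrained relax."""
    cfg = cfg or DEFAULTS
    out = []
    for k, m in enumerate(models):
        work = m
        if has_sidechains(work):
            work = repack_sidechains(work, np.random.default_rng(seed + k))
        rs = build_restraints(work, form=cfg["restraint_form"], cfg=cfg)
        sched = RelaxSchedule(steps=cfg["relax_steps_short"], mode="minimize")
        relaxed = relax(work, rs, sched, weights=cfg["weights"])
        relaxed.provenance = "threaded"
        relaxed.meta = dict(m.meta)
        out.append(relaxed)
    return out


def extract_patch_library(
    optimized_threaded: list[ProteinModel],
    ulrs: list[tuple[int, int]],
    window_bounds: tuple[int, int] = (5, 15),
) -> PatchLibrary:
    """Sliding non-ULR backbone windows from optimized threaded models.

    ULR ranges are 1-based inclusive. Window starts advance by the minimum
    window length (the stride); all lengths within bounds are emitted.
    No patch intersects a ULR residue.
    """
    wmin, wmax = window_bounds
    lib = PatchLibrary(window_bounds=window_bounds)
    for m in optimized_threaded:
        L = len(m)
        blocked = np.zeros(L, dtype=bool)
        for s, e in ulrs:
            blocked[s - 1: e] = True
        rebuilt = m.meta.get("rebuilt", [])
        for p in rebuilt:
            blocked[p] = True
        src = m.meta.get("template_id", m.provenance)
        spans = _segments([i for i in range(L) if not blocked[i]])
        bb = m.backbone_coords()
        for s0, e0 in spans:
            span_len = e0 - s0 + 1
            if span_len < wmin:
                continue
            for start in range(s0, e0 + 1, wmin):
                for length in range(wmin, wmax + 1):
                    if start + length - 1 > e0:
                        break
                    lib.patches.append(
                        (src, (start + 1, start + length), bb[start: start + length].copy())
                    )
    return lib
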