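"""Analytic loop closure: perturb a loop's pivot torsions, then rejoin it.

Builds a random 12-residue chain, randomizes the six pivot torsions of an
interior 6-residue loop, and enumerates every torsion assignment that
re-closes the chain onto the fixed anchors. Each solution rebuilds with a
closure gap below 1e-6 A, and the original conformation is always among
the solutions (its closure depends only on the non-pivot torsions).
"""

import numpy as np

from refine2lite.fixtures import perturb_structure, make_two_helix_bundle
from refine2lite.geometry import (
    TorsionSeries,
    compute_backbone_torsions,
    loop_closure_gap,
    triaxial_loop_closure,
)

model = perturb_structure(make_two_helix_bundle(6, 3), 2.0, seed=1)
t = compute_backbone_torsions(model)
bb = model.backbone_coords()
s, e = 3, 8                       # 0-based loop residues 4..9
pivots = (0, 3, 5)

loop = TorsionSeries(t.phi[s:e + 1].copy(), t.psi[s:e + 1].copy(), np.full(6, 180.0))
n_anchor = np.array([bb[s - 1, 2], bb[s, 0], bb[s, 1]])
c_anchor = bb[e + 1, :3]

rng = np.random.default_rng(7)
proposal = loop.copy()
for p in pivots:
    proposal.phi[p] = rng.uniform(-180, 180)
    proposal.psi[p] = rng.uniform(-180, 180)

gap_before, _ = loop_closure_gap(proposal, n_anchor, c_anchor, t.phi[e + 1])
solutions = triaxial_loop_closure(proposal, n_anchor, c_anchor, pivots, t.phi[e + 1])
print(f"open-chain gap after randomizing pivots: {gap_before:.2f} A")
print(f"closure solutions found: {len(solutions)}")
for k, sol in enumerate(solutions):
    gap, _ = loop_closure_gap(sol, n_anchor, c_anchor, t.phi[e + 1])
    print(f"  solution {k}: closure gap {gap:.2e} A, "
          f"pivot phis {np.round(sol.phi[list(pivots)], 1)}")
print("each solution is a distinct loop conformation that exactly rejoins "
      "the fixed anchors; the refinement operators draw among them.")
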