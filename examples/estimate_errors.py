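"""Residue-wise error estimation and ULR detection on a planted case.

The benchmark case perturbs a two-helix bundle mostly in its loop; the
RMSF/FRAG/MSA scores plus the default linear model should flag exactly
that region as unreliable.
"""

import numpy as np

from refine2lite.energy import RelaxSchedule, build_restraints
from refine2lite.error_estimation import estimate_profile
from refine2lite.fixtures import make_refinement_case

case = make_refinement_case(size=40, start_rmsd=2.5, seed=0)
restraints = build_restraints(case.start)
profile = estimate_profile(
    case.start, restraints, case.fraglib, pssm=case.pssm,
    n_runs=6, schedule=RelaxSchedule(steps=60, mode="noisy-minimize",
                                     sidechain_repack_every=20),
)

print("residue  rmsf(A)  frag(deg)  msa  predicted_error")
for i in range(len(case.start)):
    marker = " <-- truly perturbed loop" if case.loop_range[0] <= i + 1 <= case.loop_range[1] else ""
    print(f"{i + 1:4d}    {profile.rmsf[i]:6.3f}   {profile.frag[i]:7.2f} "
          f"{profile.msa[i]:6.2f}   {profile.predicted_error[i]:6.3f}{marker}")
print(f"\ndetected ULRs (1-based ranges): {profile.ulrs}")
print(f"planted loop:                   {[case.loop_range]}")
print("a ULR overlapping the planted loop means the error model localized "
      "the perturbation from structure + conservation signals alone.")
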