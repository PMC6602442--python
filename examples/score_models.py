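"""Model accuracy metrics on a synthetic benchmark pair.

Generates a 40-residue two-helix native plus a 2.5 A decoy "prediction"
and prints every metric the package computes. GDT-HA and TM-score search
over superpositions; LDDT and the clash score are superposition-free.
"""

from refine2lite.fixtures import make_refinement_case
from refine2lite.metrics import accuracy_report

case = make_refinement_case(size=40, start_rmsd=2.5, seed=0)
rep = accuracy_report(case.start, case.native)

print("start model vs native:")
print(f"  CA-RMSD        {rep.ca_rmsd:7.3f} A   (global backbone error)")
print(f"  GDT-HA         {rep.gdt_ha:7.2f}     (0-100; high-accuracy fit fraction)")
print(f"  LDDT           {rep.lddt:7.2f}     (0-100; local distances preserved)")
print(f"  TM-score       {rep.tm_score:7.3f}     (>0.5 means same fold)")
print(f"  clashes/1000   {rep.clash_per_1000:7.2f}     (steric quality)")
print(f"  Rama favored   {rep.rama_favored:7.3f}     (backbone torsion quality)")
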