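# refine2lite

Desk-scale refinement of predicted protein structures: estimate where a
model is locally wrong, then improve it by an iterative pool-based
conformational search with six structure move sets, restrained relaxation,
and restraint-free final scoring — plus the accuracy metrics (GDT-HA, LDDT,
TM-score, clash score) needed to evaluate the result.

It is aimed at structural bioinformaticians who have a single-chain model
(from template-based or deep-learning prediction) and want to polish it, or
who want a compact, fully testable implementation of the refinement
machinery itself: analytic triaxial loop closure, elastic-network modes,
fragment assembly, restraint energies, and superposition-based metrics.

## The method in brief

**Local error estimation.** Three per-residue scores — RMSF (CA fluctuation
over an ensemble of noisy restrained relaxations), FRAG (disagreement with a
backbone fragment library, in degrees), and MSA (a sign-flipped PSSM
conservation signal) — combine linearly,

    error_i = b0 + b1·RMSF_i + b2·FRAG_i + b3·MSA_i ,

and stretches of consecutive high-error residues become *unreliable local
regions* (ULRs), the targets of rebuilding.

**Search.** An initial pool of 48 structures is generated from the input by
re-building the termini and ULR loops. Each cycle applies structure
operators 10 times to every member (480 trials): fragment assembly, loop
modelling and side-chain repacking drive local refinement; normal-mode
perturbation, hybridization with homolog-derived patches, and rigid
secondary-structure moves drive larger changes. Trials relax under
restraints derived from the input — CA anchors plus CA–CA and N–O pair
distances, harmonic (w·d²) or Lorentzian (w·d²/(d²+c²)), with the worst 10%
neglected — and feed back into the pool: a low-energy trial replaces the
highest-energy member within a closeness radius that widens over the five
cycles. All 2400 generated structures are then re-scored *without*
restraints; the 10 lowest-energy models get a final full-atom optimization
and are reported ranked.

Every piece of backbone surgery re-closes the chain exactly by triaxial
loop closure: three pivot residues' (phi, psi) are solved so the perturbed
segment rejoins its anchors with sub-1e-6 Å gaps.

See `docs/methods.md` for the full model, parameter tables, and the design
choices.

## Worked example

`examples/refine_toy.py` builds a synthetic benchmark — a 40-residue
two-helix bundle as "native", a 2.5 Å decoy as the starting model, a
planted-conservation PSSM, a fragment library and two homolog decoys — and
refines the start with restraints built from the native (the benchmarking
mode that stands in for a known answer):

```text
$ python examples/refine_toy.py
structures scored: 120 (= 8 x 5 x 3)
  cycle 0: pool min   -38.66, mean   -36.32, closeness 0.50 A
  cycle 1: pool min   -41.47, mean   -40.39, closeness 1.25 A
  cycle 2: pool min   -41.90, mean   -41.68, closeness 2.00 A
GDT-HA:  start  64.4  ->  model 1  83.7
CA-RMSD: start  2.37  ->  model 1  1.09 A
```

The pool minimum falls monotonically (the replacement rule only ever swaps
in lower-energy structures), the closeness radius widens per schedule, and
the top-ranked model ends substantially closer to the native — GDT-HA up 19
points, CA-RMSD halved. The other examples show the metrics
(`score_models.py`), the error profile localizing the planted bad loop
(`estimate_errors.py`: detected ULR 18–23 vs true loop 19–22), and loop
closure enumerating all re-closing conformations (`loop_closure.py`).

The same functionality is available from the shell:

```bash
refine2lite make-case --size 40 --rmsd 2.5 --seed 0 --out case
refine2lite score case/start.pdb case/native.pdb
refine2lite estimate-error case/start.pdb --pssm case/case.pssm --fraglib case/case.fraglib.tsv
refine2lite run case/start.pdb --out refined --capacity 8 --trials 5 --cycles 3 --relax-scale 0.4
refine2lite config --show
```

`run` writes `model_01.pdb` … `model_10.pdb`, a `report.tsv` (per-model
energy, CA-RMSD to input, clashes per 1000 atoms, Ramachandran-favored
fraction) and a `log.jsonl` with per-cycle pool statistics. Runs are
deterministic given `--seed`.

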