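# Methods

`refine2lite` implements a desk-scale protein-model refinement protocol:
estimate where a single-chain model is locally wrong, then improve it by an
iterative pool-based conformational search whose moves concentrate on the
unreliable regions, under restraints that keep the trustworthy parts in
place. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Structural model and geometry

Models are single protein chains with complete N/CA/C/O backbones
(coordinates in Angstrom, residues 1-based, ranges inclusive). Side chains
are coarse: an ideally placed CB plus up to two pseudo-atoms (CG, CD) whose
chi1/chi2 angles live on the gauche-/gauche+/trans grid. Inputs are limited
to 300 residues and may not have internal chain breaks (a break is a
consecutive C-N distance above 2.0 A — the ideal peptide bond is 1.33 A —
or a gap in residue numbering); the CLI rejects such inputs, the library
only warns, since the cap is operational rather than algorithmic.

Backbone rebuilding is deterministic NeRF placement from phi/psi/omega with
ideal bond lengths and angles (N-CA 1.458, CA-C 1.525, C-N 1.329 A; omega
fixed at 180 deg — cis peptides are not sampled). Rebuilding can instead use
bond geometry extracted from a model, which makes torsion <-> coordinate
round trips exact; tests rely on that. Secondary structure is assigned from
torsion bins (H: phi in (-100,-30), psi in (-80,-5); E: phi in (-180,-80),
psi in (80,180) or below -170; singleton H/E smoothed to C) rather than
hydrogen-bond patterns, avoiding any DSSP dependency; the bins are the
package's contract.

### Triaxial loop closure

Loop moves perturb a window's torsions and must rejoin the chain exactly.
The solver is the classic three-pivot reduction: with non-pivot torsions
frozen, the three pivot CA atoms form a triangle of known side lengths whose
middle vertex moves on a circle; each circle position reduces the outer
pivots to two-cone intersections (two branches each), leaving one scalar
closure equation — the N-CA-C angle at the middle pivot — in one variable.
Rather than assembling the 16th-degree resultant polynomial, the equation is
solved numerically: a 1080-point scan per branch, adaptive 64x refinement of
suspicious cells (validity boundaries of the cone intersections, narrow
validity slivers, small-magnitude extrema — all of which can hide root pairs
or roots at branch-merge points), and vectorized bisection to ~1e-15 rad.
Solutions are verified by rebuilding (closure gap below 1e-6 A) and
deduplicated on the six pivot torsions. Tests check the solution *count*
against an independent multi-start least-squares search over the six pivot
torsions.

Closure does not always exist: a short window between rigid anchors is an
over-constrained mechanism, and e.g. a three-residue insertion between two
spatially adjacent template residues has *no* ideal-geometry closure at all.
Where operators hit this, they retry other pivots/windows and finally fall
back to a least-squares torsion fit (accepted if the residual junction gap
stays under 0.4 A, which the bonded terms of the next relaxation absorb);
threading additionally repairs hopeless insertions by a Cartesian
least-squares patch of the segment's covalent geometry, never moving aligned
residues.

## Accuracy metrics

* **CA-RMSD** after Kabsch superposition.
* **GDT-HA**: mean over 0.5/1/2/4 A of the maximal fraction of CA atoms
  superposable under the threshold. Exact maximization is infeasible in
  general; the maximizer is a seeded fit-select heuristic (seeds: full
  chain, contiguous windows of length 3-7, and for chains of <= 10/14
  residues all residue quadruples/triples), iterating superpose ->
  select-within-cutoff and re-fitting every k-closest subset. On small toys
  this provably reaches the exhaustive-enumeration optimum (tested); on
  large chains it is a lower bound, never worse than a single global fit.
* **TM-score** with d0 = 1.24 (L-15)^(1/3) - 1.8, clamped to 0.5 A below
  L = 16 (with a warning), maximized by the same machinery.
* **LDDT**, superposition-free: atom pairs within 15 A in the reference at
  residue separation >= 2; fraction of pairs preserved within 0.5/1/2/4 A,
  averaged and scaled to [0, 100]. All-atom over the atoms both models
  share, or CA-only for coarse models; no stereochemistry penalty term.
* **Stereochemistry** is reported as clashes per 1000 atoms (non-bonded
  pairs at residue separation >= 2 closer than the vdW-radius sum minus
  0.4 A; radii C 1.70, N 1.55, O 1.52, S 1.80) together with a
  Ramachandran-favored fraction (within 55 deg of the helix/sheet/left-helix
  basins). The MolProbity composite itself is not computed.

## Energy function

The refinement energy is a linear combination of four surrogate physics /
statistics terms and restraints. It is this package's own documented
contract, not a reimplementation of any published force field:

| term | form | default weight |
|---|---|---|
| steric | sum (1 - r/r0)^2 for r < r0 = ri + rj - 0.4 A | 1.0 |
| hbond | -exp(-(r-3.0)^2 / (2*0.3^2)) over backbone N-O pairs, r < 5 A | 0.5 |
| torsion_stat | -log of a 3-basin Gaussian Ramachandran mixture (sigma 35 deg) | 0.2 |
| compactness | (Rg - 2.2 L^0.38)^2 | 0.05 |
| restraints | see below | 1.0 |

Restraints derive from the input structure: one Cartesian CA anchor per
residue, all CA-CA pairs with |i-j| >= 4 under 12 A, and all backbone N-O
pairs under 3.5 A. Deviations d enter either harmonically (w d^2) or through
the bounded Lorentzian w d^2/(d^2+c^2) with softness c = 3.0 A, whose
gradient vanishes at large deviation — the mechanism that lets the default
mode sample widely while the harmonic "conservative" mode stays local.
Within each class the worst ceil(f N) restraints are dropped at every
evaluation (f = 0.10 by default, 0.05 in conservative mode), so a locally
wrong input region cannot pin the search. CA-anchor deviations are measured
in a superposed frame (anchors Kabsch-fit onto the current CAs), making the
term invariant to rigid drift; its gradient holds the superposition fixed
per evaluation, which is exact for uniform harmonic anchors (envelope
argument) and quasi-exact otherwise. Per-class weights default to 1.0
(anchors) and 0.3 (distance pairs), chosen once so the restraint and physics
terms have the same order of magnitude on the synthetic fixtures.

Relaxation stands in for short restrained molecular dynamics: L-BFGS
minimization of the restrained total plus bonded-geometry terms (bond
lengths, 1-3 distances, omega planarity; spring constants 100 / 30 / 5)
that keep covalent geometry within ~2% of ideal. Three schedules exist —
long, standard, and post-loop-modelling — with step counts 1200 : 250 : 100,
preserving the 14.4 : 3.0 : 1.2 ratio of the relaxation spans they emulate;
only the ratio is contractual and a single scale factor shrinks all three
together. Minimize mode returns the best configuration seen, so the final
objective never exceeds the initial one. Noisy-minimize interleaves seeded
Gaussian coordinate kicks (sigma 0.08 A) and side-chain repacking between
minimization segments.

## Local error estimation

Three per-residue scores feed a linear error model:

* **RMSF**: CA fluctuation over 24 noisy-minimize relaxations (distinct
  seeds, repacking interleaved), after iterative superposition onto the
  ensemble mean.
* **FRAG**: per window position, the minimum over library fragments of the
  mean circular |delta phi| + |delta psi| (degrees); per residue, the mean
  over covering windows. Fragment window defaults to 7; libraries are read
  from TSV or generated from a structure's own windows plus noisy copies.
* **MSA**: the sign-flipped mean of the 20 PSSM components per position
  (high conservation scores => low expected error; the row mean is used,
  with the native-residue component available as an option), optionally
  smoothed by a centered moving average.

Predicted error = intercept + w_rmsf*RMSF + w_frag*FRAG + w_msa*MSA, clamped
at zero. Shipped default coefficients are (0, 1.0, 0.05, 0.3) — roughly
balancing the three scores' scales on the synthetic cases — and
`fit_error_model` recalibrates them by OLS when per-residue true errors are
available. Unreliable local regions (ULRs) are maximal runs of residues
above a threshold (default mean + 1 SD of the prediction), merging runs
separated by at most one below-threshold residue and discarding runs shorter
than three.

## Threading and patches

Homolog structures arrive with pairwise alignments (aligned FASTA or A3M).
The query sequence is threaded onto each homolog backbone; unaligned query
segments are rebuilt and closed as described above, and flagged. Homologs
covering under 40% of the query are skipped; threaded models are kept only
if their TM-score to the *threaded model vs the input* exceeds 0.5
(strictly), then lightly optimized (one repack plus a short restrained
relaxation). Sliding backbone windows (lengths 5-15, stride 5) over spans
that touch neither a predicted ULR nor a rebuilt segment form the patch
library for the hybridization operator.

## Structure operators

Six moves, all deterministic given the context RNG, all sequence-preserving
and chain-intact; failure (no closure, empty library, no chunk) returns the
input flagged as a no-op so the search can re-draw:

1. **Fragment assembly** — a window chosen with probability proportional to
   its summed predicted error gets a random library fragment's torsions,
   re-closed triaxially (random pivots).
2. **Loop modelling** — a ULR's torsions are either circularly interpolated
   toward another pool member's (mix) or Gaussian-perturbed (mutate, sigma
   30 deg, shrinking over retries); pivots absorb the closure adjustment.
3. **Side-chain perturbation** — greedy grid repack; backbone bit-identical.
4. **Normal-mode perturbation** — an elastic-network model on CAs (springs
   between pairs within 10 A, unit spring constant) gives the Hessian; one
   of the 10 lowest non-rigid modes (uniform draw) displaces every residue
   by its CA mode component, RMS-normalized to 1.0 A, followed by a short
   unrestrained minimization to restore covalent geometry. A connected
   network has exactly six near-zero modes, which is asserted.
5. **Hybridization** — a random patch is superposed onto the model through
   its two terminal residues on each side, copied in rigidly, and the
   four-residue flanks are re-closed; the patch interior equals the donor
   exactly.
6. **Secondary-structure perturbation** — a helix/strand chunk (>= 4
   residues) rotates rigidly up to 10 deg about its CA centroid and
   translates up to 1 A; flanking loops re-close, short termini follow the
   chunk rigidly. Chunk-internal geometry is preserved exactly.

Operator selection is a uniform-by-default weighted draw, re-drawn up to
five times on no-ops.

## The search

An initial pool of 48 members is built from the input by fragment-assembly
re-building of the termini (3 residues, on by default) and every ULR, each
member with its own random draws, followed by a short restrained relaxation.
Each cycle applies operators 10 times to every member (480 trials), relaxes
each trial (short schedule after loop modelling, standard otherwise), and
scores it with the restrained total. Trials enter the pool lowest-energy
first: a trial replaces the highest-energy member within the closeness
radius (CA-RMSD), or the globally worst member if nothing is close, and only
ever replaces a higher-energy member — so pool size is conserved and the
pool minimum is non-increasing. The closeness radius grows linearly from
0.5 to 2.0 A over the five cycles, pushing later sampling outward. After the
cycles, all 2400 generated structures are re-scored *without* restraints,
the 10 lowest get a final full-atom optimization (repack plus unrestrained
minimization), and are returned re-ranked. The master seed fans out to
every stage through `numpy` SeedSequence spawning; identical seeds give
bit-identical results.

Conservative mode switches the restraints to harmonic with 5% neglect;
everything else is unchanged.

## Synthetic benchmarks — what they show

The fixtures generate everything the protocol consumes: ideal helices, a
clash-free antiparallel two-helix bundle (frozen turn torsions for loop
lengths 3 and 4), torsion-space decoys hit a target CA-RMSD within 20% by
bisection of a fixed seeded noise direction, synthetic PSSMs with planted
conservation, fragment libraries (native windows + noisy copies), and
homolog decoys with identity alignments at 0.8 A and 8 A perturbation —
calibrated once against the TM-score implementation so that exactly one
homolog passes the 0.5 filter, then frozen.

The standard benchmark case perturbs a 40-residue bundle mostly in its loop
and termini (global CA-RMSD 2.5 A), plants the matching conservation signal,
and asks the protocol to (a) flag the loop as a ULR and (b) improve GDT-HA
to the native when restraints are built *from the native* (the
oracle-restraint mode that replaces unavailable experimental benchmark
pairs). Both hold across seeds at toy search sizes (pool 8, 5 trials/member,
3 cycles, relaxation scaled to 40%).

These cases are deliberately easy in ways real refinement targets are not:
the native is near a minimum of the surrogate energy by construction, the
homologs are perturbed copies rather than true homologs, the conservation
signal is planted, and oracle restraints point at the answer. Passing them
demonstrates that the machinery — error localization, sampling operators,
closure, pool dynamics, scoring — works as specified, not that the surrogate
energy would refine blind predictions; problem sizes (20-40 residues,
hundreds to thousands of trials) were chosen so the full protocol, at its
true default pool arithmetic, runs on a single core in minutes.

## Known limitations

* The energy is a coarse surrogate; absolute energies are meaningless and
  only rankings within a run are used.
* No cis peptides, no backbone-dependent rotamers, at most two chi angles.
* Non-bonded terms are all-pairs (O(n^2)); fine to the 300-residue cap,
  inefficient beyond.
* GDT-HA/TM maximization is exact only where exhaustive enumeration is
  feasible; elsewhere it is a strong lower bound.
* The Lorentzian-anchor gradient is quasi-exact (superposition held fixed);
  L-BFGS tolerates this, and descent is enforced by keeping the best-seen
  configuration.
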