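# Methods

## The ensemble model

All computations operate on the equilibrium ensemble of pseudoknot-free
(nested) secondary structures.  A structure is a set of base pairs (i, j),
1-based, i < j, in which no residue pairs twice, no two pairs cross, every
pair is one of {AU, UA, GC, CG, GU, UG}, and every hairpin loop contains at
least h = 3 unpaired residues.  The empty structure is admissible and has
energy zero by convention, so the partition function satisfies Z ≥ 1.

Free energies come from loop decomposition: each pair closes exactly one
loop and the structure energy is the sum of loop energies; the exterior
loop is free.  Loop classes and their parameters (all kcal/mol, bundled in
`src/ribosnitch/params/default.yaml`, selectable per run via `--params`):

| term | form | default | rationale |
|---|---|---|---|
| stacked pair | table E(outer pair, inner pair) | −3.4 … −0.2 | follows the canonical nearest-neighbor ordering: GC-rich steps strongest, GU wobble weakest |
| hairpin loop | table by size 3–9, then E(s_max) + 1.75·RT·ln(s/s_max) | 5.4–6.4 | destabilising, with Jacobson–Stockmayer logarithmic growth |
| bulge loop | table by size 1–6 + same extrapolation | 2.8–4.4 | |
| internal loop | table by total size 2–10 + extrapolation | 1.5–2.5 | symmetric in the two strand gaps; no asymmetry penalty |
| multiloop | a + b·branches + c·unpaired | a = 3.4, b = 0.4, c = 0.0 | the affine form standard in O(n³) folding |
| temperature | T, kelvin | 310.15 | physiological |
| gas constant | R, kcal/(mol·K) | 0.0019872 | |

Two hard constraints are part of the model itself, not soft penalties:
hairpin loops shorter than h are forbidden, and bulge/internal loops with
more than 30 unpaired residues in total are forbidden.  The size cap keeps
the interior-loop scan of the dynamic programs bounded (standard practice)
and — because the exhaustive enumerator applies the identical rule — keeps
every engine component defined on *exactly* the same structure set.

This model is deliberately compact.  It omits sequence-dependent loop
terminal mismatches, dangling ends, special tetraloop bonuses, coaxial
stacking and terminal-AU penalties.  The omissions change absolute
probabilities relative to full Turner-parameter engines; they do not change
the method, which is engine-agnostic.  The `vienna` engine adapter
(ViennaRNA Python bindings) can be substituted wherever published absolute
correlation values must be reproduced.

## Engine components and their cross-validation

Four routes into the same ensemble, agreeing exactly on admissibility and
energies:

* **Partition function** (`thermo.partition_function`): McCaskill-style
  inside–outside recursions over four interval quantities (paired,
  one-multiloop-branch, at-least-one-branch, unconstrained), O(n³) time,
  O(n²) memory.  The multiloop outside term is accumulated with per-row
  helper sums to stay cubic.
* **MFE folding** (`thermo.mfe_structure`): Zuker-style minimisation over
  the identical decomposition, with a deterministic traceback.
* **Boltzmann sampler** (`thermo.sample_structures`): stochastic traceback
  through the inside matrices; every decomposition step draws a branch with
  probability proportional to its share of the local partition function, so
  samples are exact i.i.d. draws, not approximate.  RNG is numpy PCG64
  with an explicit integer seed recorded in every sample.
* **Enumeration oracle** (`thermo.enumerate_structures`): exhaustive
  recursion over all admissible pair sets (refused above 20 nt), with
  energies computed by an explicit loop-tree walk that shares no code with
  the dynamic programs.

The test suite holds the dynamic programs to the oracle at 1e-9 absolute on
hundreds of seeded random sequences, and holds the sampler to the oracle
distribution by total-variation distance at 20 000 draws.  Because oracle
and engine agree exactly on the model, these are sharp correctness checks,
not statistical smoke tests.

### Numerical choices

* **Rescaling.**  Inside/outside quantities are rescaled per nucleotide
  (scale derived from the MFE with a 1.07 safety factor) so partition
  functions of long, stable sequences stay inside double range; pairing
  probabilities are scale-free ratios.  `log Z` is always exact; `z`
  overflows to inf only beyond exp(700).
* **Tie-breaking.**  Co-optimal MFE structures are resolved by a fixed
  traceback preference order (hairpin, then stack/interior loops by
  ascending inner indices, then multiloop splits; pairing preferred at the
  smallest indices).  Repeated runs return the identical structure.
* **Degenerate Pearson inputs.**  If both accessibility vectors are
  constant and elementwise equal (1e-12), r := 1; if constant but unequal,
  or exactly one is constant, r := 0 with a logged warning.  This keeps
  every mutation rankable — relevant for pair-free sequences where both
  vectors are identically zero.
* **Ranking.**  rank = #{mutations with r ≤ r(target)}, self included, so
  ties enlarge the rank and the p-value (conservative).  p ∈ [1/3n, 1].
* **Mutation order.**  Scans enumerate positions ascending, variant bases
  A<C<G<U; outputs are byte-reproducible under fixed seeds.

## Ensemble characterisation

Sampled structures are encoded as length-n 0/1 vectors (1 = paired).  The
PCA basis is built once from a pooled subsample — by default 1000
structures per sequence out of 5000 sampled — so wild type and mutants are
projected into one shared coordinate system; mean-centering uses the pooled
mean and no variance scaling is applied (bits are homoscedastic).
Components get a deterministic sign (largest-magnitude loading positive).
Cluster occupancies come from k-means (default k = 3, 50 restarts, fixed
seed) fit on the pooled projections; per-cluster representative structures
are those nearest the centroids.  K-means on two components is a
reproducible surrogate for reading clusters off a scatter plot by eye; with
well-separated clouds the assignment is insensitive to the seed, but
cluster *numbers* are arbitrary labels and occupancy tables should be
compared by matching centroids, not label order.

## Fixtures: what they emulate and what they do not

`random_sequence` draws i.i.d. residues at a target GC fraction —
compositionally realistic, but with none of the evolved structure of real
UTRs.  `design_hairpin` gives sequences with a single dominant helix.
`design_switch` rejection-samples an 18-nt construct with two mutually
exclusive helices sharing a central strand, certified against the
enumeration oracle at construction time: the wild type forms helix A with
probability > 0.8; a designated toggling mutation (which breaks a helix-A
pair) drops that below 0.4 and ranks in the lowest decile of the full
mutation scan; a designated neutral loop mutation scores r > 0.99.  The
switch is a miniature of the riboSNitch mechanism — mutation-driven
repartitioning between discrete conformations — at a size where the exact
ensemble is enumerable.

Passing on these fixtures demonstrates that the pipeline recovers known
ensemble shifts and known-null mutations under a model where ground truth
is exact.  It does not demonstrate accuracy on real UTRs, which differ in
length, composition, evolved structure, and in the adequacy of any
nearest-neighbor model (no pseudoknots, no tertiary contacts, no protein
binding).

## Known limitations

* **Mutation locality is sequence-class dependent.**  On evolved UTRs with
  a well-defined dominant fold, the large majority of substitutions barely
  move the ensemble.  On uniform-random sequences the ensembles are
  shallower and substitutions rearrange them more often: in the bundled
  analysis of twenty random 100-mers (`scripts/acceptance.py`,
  `fraction_mutations_r_above_0.9_pct`) roughly 55–60% of mutations score
  r > 0.9 — under this package's internal model and likewise under the
  Turner-parameter reference engine.  Empirical p-values remain valid
  regardless (they are ranks within each sequence's own scan), but
  intuition formed on real UTRs should not be transferred to random
  controls.
* Pseudoknots are outside the structure space; the ensemble is nested-only.
* The MFE-based comparison distribution uses one deterministically chosen
  co-optimal structure per mutant; co-optimality is common under a
  0.1-granular parameter table.
* Absolute correlation values are engine- and parameter-set dependent;
  only within-engine comparisons (ranks, p-values, occupancy shifts) are
  meaningful across studies.
* `mutation_scan` is O(n) partition functions of O(n³) each; scans above
  1000 nt are refused unless forced.
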