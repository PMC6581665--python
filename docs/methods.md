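# Methods

This note documents the models, estimators and numerical conventions in
`karyoinfer`, the assumptions behind them, and what the synthetic-data
generator does and does not emulate.

## Morphometrics

**Quantities.** For a metaphase plate with chromosome lengths
`L_i = short_i + long_i`, relative length is `RL_i = 100·L_i/ΣL_j`
(compositional: sums to 100 within a plate) and the centromeric index is
`CI_i = 100·short_i/L_i ∈ [0, 50]`. Both are scale-free, so measurement
units (µm, pixels) are never converted or validated beyond positivity.

**Summaries.** Karyotype tables report per-chromosome mean ± SD over N
plates (conventionally N = 20, measured on haploid male metaphases in
haplodiploid wasps). SDs use the sample (N−1) convention, 0 at N = 1.
Reports round to two decimals; all internal computation is full
precision.

**Plate-to-plate chromosome identity.** Without banding there is no
marker-based correspondence between plates. When the input carries no
labels, chromosomes are labelled by rank of total length within each
plate (largest = 1) — the only information-preserving default; an
explicit label column overrides it. Rank labelling misassigns
chromosomes whose length distributions overlap; this is a property of
the data, not of the estimator, and shows up as inflated SDs.

**Centromere classes.** The classical arm-ratio guideline categories are
applied as CI bands with lower-closed breakpoints 12.5 / 25 / 37.5
(acrocentric, subtelocentric, submetacentric, metacentric). Wasp
karyotype tables commonly use a three-class vocabulary; a merge flag
(default on in the pipelines) reports submetacentrics as metacentric.
Classification is a total monotone step function of CI.

**Ingest robustness.** Hand-built measurement tables sometimes list arms
in the wrong order; short > long is auto-swapped with a logged warning
rather than rejected. Under arm-partition noise, a near-metacentric
chromosome legitimately produces such rows, so the swap is also the
correct censoring of CI at 50.

## Homolog matching

Cost between chromosome i of karyotype A and j of karyotype B:

    d(i, j) = |RL_i − RL_j| / s_RL + |CI_i − CI_j| / s_CI,

with `s` the pooled SD of the pair, `√((s_i² + s_j²)/2)`, floored at 0.5
percentage points (printed SDs of exactly 0 — e.g. CI of an acrocentric —
would otherwise dominate the cost). The matching minimises total cost
over one-to-one assignments (Hungarian algorithm, rectangular when the
haploid numbers differ); pairs with d above a threshold (default 3,
a ≈ 3-sigma rule per coordinate) are dissolved into the unmatched sets.

Costs are capped just above the threshold *before* solving. Without the
cap, a chromosome that has no admissible partner (e.g. a fusion product)
still competes for columns and can displace genuinely similar pairs; with
the cap it pays a flat price wherever it lands, and the solver returns
the matching that is optimal under the dissolution rule. Tests verify
equivalence against exhaustive enumeration of all assignments for ≤ 6
chromosomes.

## Fusion / fission inference

Because RL is a conserved percentage of the haploid set, a fusion product
must carry the summed RL of its components. For every unmatched product
candidate and 2-subset of unmatched components,

    z = (RL_prod − RL_1 − RL_2) / √(s_prod²/N_prod + (s_1² + s_2²)/N_comp),

with two-sided normal p. The test *screens*: candidates are retained when
equality is **not** rejected (p ≥ α, default 0.05) — the inference argues
from compatibility, not difference — and are ranked by |z| ascending with
lexicographic tie-breaks. Fission detection is the mirror image (the
aberrant higher-n karyotype supplies the components). Chromosomes measured
at N < 2 are refused (no sample SD); equal haploid numbers are refused
(event direction undefined).

Known limitation: RLs within a plate are compositional and hence
negatively correlated, but published tables give only marginal SDs, so
the z ignores covariances. For a sum of two components this overstates
the variance, making the screen conservative (it retains slightly too
readily).

**Mechanism scoring.** Arm lengths are recovered from the means
(`short = CI·RL/100`). With the larger-CI component in the metacentric
role (RL_m, arms s_m/l_m) and the other in the acrocentric role (RL_a),
the predicted product CI is

* centric fusion (presupposing a pericentric inversion of the
  metacentric component): arms (RL_m, RL_a) → `100·min/(RL_m+RL_a)`;
* tandem onto the long arm: arms (s_m, l_m + RL_a);
* tandem onto the short arm: arms (s_m + RL_a, l_m).

Scores are ranked by |predicted − observed CI|; means only, no
uncertainty propagation — the mechanism question is inherently
qualitative at table resolution. When both components are telocentric the
short-arm tandem attachment coincides with the centric geometry and is
reported as a single degenerate tandem entry. Predictions are invariant
to component order.

**Hybrids and segregation.** The F1 female complement is one haploid set
per parent: total count n_a + n_b always; matched chromosomes pair,
unmatched ones are single copies. A fusion-heterozygous hybrid (one
product singleton vs two component singletons) produces haploid gametes
carrying either form with probability ½ each — no recombination or
segregation-distortion model — giving the exact 1:1 expectation alongside
a seeded binomial simulation.

## Sequence distances and the NUMT screen

p-distance = differing / comparable sites, sites with N or `-` in either
sequence excluded. Deletion default is pairwise (the common default for
uncorrected-distance summaries); complete-set deletion drops every column
containing N/`-` in any sequence and therefore never retains more sites.
Clade means are unweighted over pairs; within-clade means are undefined
(reported missing) for singleton clades. Alignment is an input, not a
computation: COI amplicons are indel-free in frame, and external aligners
do that job.

The NUMT screen translates under NCBI translation table 5 (invertebrate
mitochondrial: TGA→Trp, ATA→Met, AGA/AGG→Ser; stops TAA/TAG only),
flagging internal stop codons and gap/ambiguity codons; the best reading
frame minimises internal stops (ties to the lowest frame). IUPAC
ambiguity codes beyond N are collapsed to N on ingest with a logged
count; U maps to T.

## Synthetic-data generator

**Karyotypes.** `make_karyotype_from_table` inverts the summary
statistics into exact arms (set total = summed RL means ≈ 100 units).
Rearrangement events conserve total chromatin length exactly:
centric fusion joins two (near-)acrocentric operands at their centromeres
(arms = the operand totals; CI > 12.5 operands are refused until a
pericentric inversion is applied); tandem fusions extend the designated
recipient arm by the donor's total; pericentric inversion exchanges
segments across the centromere at breakpoint fractions of each arm;
fission breaks the designated arm at a fraction from the centromere, the
acentric fragment surviving as a telocentric (terminal neocentromere).

**Measurement noise.** Per plate, each chromosome total is
truth × (1 + ε), ε ~ N(0, rl_cv) truncated at ±3 CV (multiplicative,
because per-cell chromosome condensation scales lengths); the arm
partition is jittered the same way (arm_cv) and renormalised to the
sampled total. Noise on absolute lengths makes downstream RLs
compositional with realistic negative covariances without modelling them
explicitly. Defaults rl_cv = arm_cv = 0.05 and N = 20 reproduce the RL SD
magnitudes of published N = 20 wasp tables (≈ 0.75–1.8 RL percent); these
defaults are the simulation's study conditions, not tuning knobs. What
the generator does **not** emulate: plate-level global condensation
factors (irrelevant: RL normalises them out), segmentation/rotation
errors of image analysis, inter-observer bias, and chromosome
misidentification beyond what rank labelling induces — so passing tests
show estimator correctness under the stated noise model, not robustness
to every failure mode of real microscopy.

**Sequences.** Tips evolve on a star-of-stars tree (root → clade
ancestors → tips) under exact Jukes–Cantor transition kernels. Targets
are expected mean p-distances: converted to additive JC branch lengths by
`d = −¾·ln(1 − 4p/3)`, tip branches are half the within-clade target, and
root branches solve `b_i + b_j = d_ij − τ_i − τ_j` (exact for three
clades; non-negative least squares beyond). JC (equal rates, uniform
base composition) suffices because only uncorrected distances are
consumed downstream; it does not emulate codon-position rate
heterogeneity or the AT bias of real insect mtDNA. In coding mode the
root is drawn from stop-free codons and any substitution creating a
frame-0 stop is reverted to the parent codon — the output is stop-free by
construction, at the cost of a small (≲ 3%) downward bias on realised
divergence that the closure tolerances absorb.

## Verification design

Each estimator is checked against an independent oracle: the matcher
against exhaustive assignment enumeration; fusion/fission detection
against generator truth (noise-free closure gives z = 0 exactly; noisy
closure at the default noise model must rank the true pair first in
≥ 95% of 200 seeded replicates); the clade simulator against the
estimator it feeds (20-seed closure within three Monte-Carlo SDs of the
replicate mean); translation against the full 64-codon table.

The event-recovery rate is defined over the |z| ranking with the
retention screen disabled: under the exact RL-sum null the α-level screen
rejects the true candidate with probability ≈ α by construction, so
screen retention measures the screen's size, not the ranking's ability to
recover the event.

Problem sizes (200 replicates of two 20-plate karyotypes; 20 seeds of a
26-tip, 679-site alignment; 100 random matching instances) were chosen so
the full verification suite runs in seconds while keeping Monte-Carlo
error well below the tolerances tested.

## Numerical conventions

Ties break deterministically everywhere: decreasing RL then decreasing CI
then input order in karyograms; ascending |z| then label order in
candidate lists; lowest frame index in the reading-frame search. All
randomness flows through `numpy.random.default_rng` seeds; entry points
default to seed 1841 (an arbitrary fixed constant, the description year
of the wasp the demo data belong to). Validation errors (malformed
input) and computation errors (well-formed input, undefined request) are
distinct exception types and CLI exit codes (2 and 3).
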