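# Methods

This note documents the statistical models, conventions and design choices
behind `sciseq`, in the order the pipeline runs them.

## Study design and containers

The pipeline operates on an `ExpressionStudy`: a non-negative FPKM matrix
(features × samples) with per-sample stage/replicate metadata, optional 95%
confidence bound matrices, and — for isoform-level studies — a total
isoform→gene map. The default design is three ordered stages
(`CTR`, `D2`, `D7`; an uninjured control and two post-injury time points)
with 2, 3 and 3 biological replicates. All tables on disk are TSV, UTF-8,
one header line; feature ids are case-sensitive. Interaction edges are
stored as unordered pairs: orientation and duplicates collapse, self-loops
are dropped with a warning (the upstream interaction databases carry no
self-interaction semantics we could preserve). Genes missing from the
annotation default to location `other` without drug information, a
permissive default that lets prioritization run on partial annotations.

## Detection threshold

An estimate is *reliable* iff its CI lower bound is strictly positive.
Rates are defined on the pooled calls (one global threshold for the study,
not per sample):

- `reliability(t)` — fraction of estimates with FPKM ≥ t that are reliable;
- `fp_rate(t) = 1 − reliability(t)`;
- `fn_rate(t)` — fraction of all reliable estimates below t (signal
  discarded by thresholding).

These operationalizations are one consistent reading of "false positive /
false negative rate" for detection curves; alternative definitions can be
built from the returned call table. Grid points where no estimate reaches
the threshold are flagged undefined rather than set to 0. The default grid
is logarithmic, 50 points over 0.001–10 FPKM. `select_threshold` returns
the smallest grid threshold whose reliability reaches the target (default
0.99), with the achieved reliability and FN rate alongside; an unattainable
target raises with the maximum achievable value. `floor_fpkm` replaces
values below the threshold by the threshold (idempotent, order-preserving,
CI matrices untouched) so that downstream ratios cannot be inflated by
near-zero denominators.

## Differential expression

Fold change is the ratio of stage means of floored FPKMs. The significance
test is the classic pooled-variance unpaired two-sided t-test on raw FPKM
replicate values — defensible at n as small as 2 vs 3 — with Welch and
log2-scale variants available as options (raw-scale pooled t is the
default). Degenerate zero-variance groups yield p = 1 for equal means and
p = 0 (with a warning) for differing means instead of NaN propagation. A
gene is significant iff FC > 2 or FC < 1/2 *and* p < 0.05; no
multiple-testing correction enters the call, but BH q-values are reported
for transparency. Top-fraction selection takes the `ceil(fraction × n)`
significant genes per direction with the largest |log2 FC|, the denominator
being the significant genes of that direction; ties break lexicographically
by gene id so results are deterministic.

## Trajectory clustering

Clustering operates on the 3-point stage-mean profiles of genes whose
floored stage means change more than 2-fold between some pair of stages.
Profiles are standardized per gene with the population (n) standard
deviation — stated explicitly so test values are exact. Fuzzy c-means is
the Bezdek alternating scheme (membership exponent 2/(m−1), objective
Σ u^m d²), initialized by k-means++-style seeding from the given seed,
iterated until the objective decreases by < 1e-9 or 500 iterations. The
defaults k = 9 (the nine trajectory groups the injury time course resolves
into) and m = 1.25 (a common fuzzifier for standardized expression
trajectories) are package choices. Sample QC: 1 − Pearson distance over the
top-3000-variance genes, complete-linkage agglomeration, deterministic leaf
order (sample ids sorted before linkage).

## Network prioritization

The interaction network is the induced subgraph over focus genes,
optionally grown by their first neighbors; isolated nodes are removed
(genes without connections carry no network evidence). Connection number is
the undirected degree over distinct neighbors (multi-edge types collapse);
edges are treated as undirected throughout — whether the source databases
intend direction is not recoverable from an edge list, so none is assumed.
The candidate filter keeps surface-accessible genes (plasma membrane or
extracellular space) with fold change beyond the cutoff, plus any gene with
drug information regardless of location. Ranking is by descending
`RI = |log_b FC| × degree` with b = 2 by default; the log base rescales all
RI values by a positive constant, so the *ordering* is base-invariant and
only absolute RI values depend on b. Ties break by higher degree, then gene
id. Up- and down-regulated focus genes can be prioritized in separate
networks (the pipeline default), mirroring stage responses that are
dominated by one direction.

## Isoform analysis

An isoform is expressed in a stage when its stage-mean FPKM reaches the
detection threshold (the same global 0.1-FPKM-style threshold as the gene
level, for consistency). The major isoform is the stage-mean argmax (exact
ties take the lexicographically smallest id and are flagged); a switch is a
change of major isoform between any two stages, reported as the earliest
such stage pair. The literal argmax rule (margin 1.0) is the default; an
optional dominance margin (e.g. 1.5×: the new major must exceed the old by
that factor in the later stage) suppresses noise-driven flips and caps the
false-call rate near zero under a no-switch null. Per-isoform one-way
fixed-effects ANOVA across stages uses the textbook F statistic with the
same degenerate-input conventions as the t-test. Expressed-isoform counts
are reported both per stage and for isoforms expressed in *all* stages
(the histogram uses the all-stage count; both readings of "expressed in all
stages" are therefore available).

## Enrichment

Fisher over-representation is the one-sided hypergeometric upper tail of
the query/set overlap within the universe of detected genes (not the whole
annotation), BH-corrected across sets. The rank-based engine orders genes
by descending log2 FC (ties by id) and computes the weighted KS running
sum: hits add `|metric|^p` normalized by the in-set total, misses subtract
`1/(N − N_set)`; ES is the signed maximum deviation, the leading edge the
set members at or before (after, for negative ES) the extremum. The weight
default p = 1 is the standard weighted statistic.

The permutation null randomizes gene labels (same-size random sets) rather
than phenotypes: with 2–3 replicates per stage, phenotype permutation has
too few distinct permutations to be meaningful. NES divides ES by the mean
|null ES| of the same sign; nominal p is `(r + 1)/(n_same_sign + 1)` so it
is never zero and honors the 1/n_perm floor; FDR across queried sets is BH.
A note on null centering: the signed-extreme ES is *exactly* mean-centered
under gene-label randomization only for the unweighted statistic (p = 0),
because reversing the ranked list negates the running sum; with p = 1 the
weights are tied to list positions, and the mean null ES drifts slightly
negative when the metric mass concentrates in the DE tails. The package's
null-centering diagnostics therefore use p = 0, while scoring keeps the
more sensitive p = 1.

## qPCR quantification

Technical replicate Ct values are averaged per gene × sample; ΔCt subtracts
the housekeeping mean per biological sample; biological replicates are
averaged on the ΔCt scale per stage (the natural scale for cycle data);
ΔΔCt is the treated-minus-control difference of those stage means and
fold = 2^−ΔΔCt with amplification efficiency fixed at 2. Adding a constant
to every Ct of a sample (plate offset) cancels exactly. The reported fold
spread is the SD across treated biological replicates of per-replicate
2^−ΔΔCt values (one of several defensible error-bar conventions; this one
is stated so it can be compared). Concordance against expression fold
changes reports Pearson and Spearman correlations of log2 folds and the
sign-agreement fraction over shared gene × contrast pairs (≥ 3 required).

## Synthetic data generator

The generator emulates the study design so that every stage of the pipeline
is testable against known truth. What it models:

- **Baselines**: per-gene 2^Normal(3, 2) FPKM (median ~8, wide dynamic
  range); a configurable fraction (default 5%) of truly silent genes with
  truth 0.
- **Differential expression**: per injured stage, fractions of up/down
  genes (default 5% + 5%) with |log2 FC| ~ Normal(2, 0.5) truncated at 1,
  so the >2-fold selections are well populated.
- **Replicate noise**: multiplicative log-normal (additive Gaussian on
  log2, default sd 0.25) — the standard bulk-expression assumption.
- **Detection limit and CIs**: bounds are symmetric on the log2 scale with
  half-width `a + b/√(FPKM + ε)` (wider toward the limit), minus/plus a
  linear term proportional to the detection limit with a uniform factor.
  Truly silent genes register a small spurious background signal
  (2^Normal(−1.5, 1) × detection limit), emulating read misassignment.
  The constants (a = 0.08, b = 0.05, uniform factor 0.75–1.75) are
  calibrated so that, under defaults, pooled reliability is ≈ 0.97 at
  0.04 FPKM and ≈ 0.99 at 0.1 FPKM, silent-gene estimates are unreliable
  ≥ 95% of the time, and the selected threshold tracks the planted limit.
  They describe no real CI estimator; they reproduce its qualitative
  behaviour.
- **Network**: preferential attachment (m = 2) over 300 genes (hubs and DE
  genes preferentially included in the node pool). Planted hubs are the
  earliest (naturally high-degree) nodes, topped up to a minimum degree
  (default 25); hub genes are drawn from the strongest up-regulated genes,
  and the first hub is additionally given the globally largest planted
  |log2 FC| and the strictly largest degree. This "prime candidate"
  encodes the framework's premise — a strongly responding, highly connected,
  surface-accessible gene — and its recovery at rank 1 validates the RI
  machinery end to end.
- **Isoforms**: per-gene isoform counts on 1–12 with P(1–5) = 0.99;
  Dirichlet base proportions; per-sample proportions jittered on log2
  (sd 0.2) and renormalized, so isoform values sum *exactly* to the gene
  value in every sample. Switch events (default 5% of genes) are planted
  only in multi-isoform genes expressed in every stage (truth ≥ 2× the
  detection limit — a major isoform is undefined otherwise) and reverse the
  dominance of the two leading isoforms across the time course (0.70/0.20
  → 0.20/0.70), the one-declines-while-the-other-rises pattern.
- **qPCR**: Ct = housekeeping Ct (default 20) + a per-gene offset −
  log2(expression relative to control), technical triplicates with Gaussian
  cycle noise (sd 0.1).
- **Trajectory archetypes** (for clustering validation): standardized
  3-point profiles lie on a circle in the plane orthogonal to the constant
  vector; k = 9 evenly spaced directions give nine distinct shapes
  (up-up, up-flat, down-down, …) with Gaussian within-archetype noise.

A single global seed drives everything; sub-generators derive their streams
from (seed, fixed offset), so a fixed seed fixes every output bitwise.

What the generator does **not** model: read-level sampling and depth,
batch/lane effects, gene length or GC biases, correlated noise between
genes, mixed cell-type composition shifts, annotation errors, or any real
CI estimator's behaviour. Passing tests therefore demonstrate that the
implementations recover what the emulated statistical structure plants —
not that the thresholds or rates would take the same values on any
particular real dataset.

## Problem sizes and determinism

Validation runs use 500–2000 genes with the 2/3/3 replicate design (10,000
genes for the t-test size check), 20 seeds for recovery-rate statements,
1000 random tables for brute-force equivalences, and 100–1000 permutations
for enrichment nulls; these sizes give stable Monte-Carlo estimates while
keeping the full validation in the minutes range. All randomness flows
through explicit seeds; the pipeline manifest records parameters, seeds and
SHA-256 checksums of every output, and re-running a config reproduces the
checksums exactly.

## Known limitations

- Raw-scale t-tests on FPKM are what the pipeline specifies, but log-scale
  testing (available via option) is usually better behaved for strongly
  skewed expression.
- With 2 control replicates, the t-test has 3 degrees of freedom in the
  default design; power statements in the validation use 3v3.
- The RI log base affects absolute RI values (not order); published RI
  numbers from other sources may assume a different base.
- Fisher's universe should be the detected-gene set; supplying the whole
  genome as universe will overstate enrichment.
- The enrichment engine implements gene-label permutation only; sample
  (phenotype) permutation is deliberately out of scope at these replicate
  counts.
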