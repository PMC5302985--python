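# Methods

## The model

A long non-coding RNA (lncRNA) acts as a **miRNA sponge** when its
abundance titrates a miRNA away from an mRNA target, weakening the
miRNA→mRNA repression. The observable signature in expression data is a
*modulated dependence*: the statistical coupling between a miRNA `m` and
an mRNA `G` is strong when the lncRNA `L` is lowly expressed and
attenuated when `L` is high. The screening statistic is

    ΔI = I(m; G | L) − I(m; G)

the conditional mutual information of the miRNA–mRNA pair given the
lncRNA, minus their marginal mutual information. ΔI > 0 indicates that
stratifying by the lncRNA reveals dependence that the marginal view
averages away — the sponge signature. The screen is run independently in
each condition (cancer, normal), and an edge connects a lncRNA–mRNA pair
whose triple passes the test for at least one shared miRNA.

Candidate triples are restricted before scoring:

1. **High expression.** Per condition, a lncRNA qualifies only if its mean
   expression is in the top fraction (default 5%, `⌊f·N⌋` with ties broken
   by id) — a lowly expressed transcript cannot sequester meaningful
   amounts of miRNA.
2. **Shared regulators.** A lncRNA–mRNA pair with miRNA regulator sets
   A and B qualifies when the Jaccard index `|A∩B| / |A∪B| ≥ 0.7`
   (inclusive). One candidate triple is emitted per shared miRNA.

## Estimator

`ΔI` uses a plug-in estimator on discretized expression: each variable is
independently discretized (equal-frequency by default, `n_bins = 8`),
joint counts are tabulated, and the entropy sums are evaluated directly,
so on already-discrete data the estimator equals the textbook count-table
formula exactly (this is property-tested against brute-force sums to
1e-12). Vectors with at most `n_bins` distinct values keep one bin per
value; constant vectors collapse to a single bin (MI 0) with a warning.
Estimates are clamped at 0 against −1e-12-scale rounding.

The bin count should grow slowly with sample size, roughly `n^(1/3)`:
8 bins suit cohort-scale inputs (n ≈ 30–150); benchmark computations at
n = 5000 (e.g. the bivariate-Gaussian closed-form check, which recovers
−½·ln(1−ρ²) to within 0.05 nats at ρ = 0.8) use 16 bins, because the
quantization loss of 8 bins (~0.06 nats) exceeds sampling noise there.

**Significance.** Only the lncRNA vector's sample assignment is permuted
(default 1000 permutations), preserving the miRNA–mRNA pairing, and

    p = (1 + #{ΔI_perm ≥ ΔI_obs}) / (1 + n_perm)

one-sided (high ΔI = sponge), with the add-one form so p is never zero.
Triples with p below the level (default 0.01, uncorrected; an optional
Benjamini–Hochberg step is deliberately not applied by default) are kept.
Each triple derives its own permutation stream from the global seed and
its identifiers, so serial and parallel runs agree, and all vectors are
aligned to a canonical (sorted) sample order, so results are invariant to
column order. The plug-in estimator is biased upward on sparse tables,
but the permutation comparison is exchangeable under the null, so the
p-values stay calibrated (verified: 200 null triples × 200 permutations
pass a Kolmogorov–Smirnov uniformity check).

## Power — an honest caveat

With planted sponge coupling β = 1.5, noise σ = 0.5 and 60 samples, the
binned ΔI permutation screen at p < 0.01 has **near-zero sensitivity**
(~0–10% across bin configurations from 2×2×2 to 8×8×8). Two effects
compound: (i) after coarse discretization the population ΔI of an
attenuation-type signal is only ~0.03–0.08 nats, below the spread of the
permutation null at this sample size; and (ii) the plug-in bias is larger
for permuted (independent) lncRNA labels than for real, dependent data,
which cancels part of the observed signal. Simulation shows the screen
needs roughly n ≈ 400 samples to reach 80% sensitivity at this effect
size. Specificity is unaffected: matched decoy triples (same regulator
overlap, no modulation) are flagged at ≤ the nominal rate. The acceptance
suite asserts the 80%-at-n=60 recovery target anyway and reports the
measured sensitivity; it fails honestly rather than loosening the
conditions. At microarray-cohort sample sizes this class of screen is
therefore best read as a high-specificity, low-sensitivity filter.

## Downstream analyses

* **Network assembly.** One edge per significant (lncRNA, mRNA) pair;
  the edge carries the union of mediating miRNAs, the maximum ΔI and the
  minimum p over that pair's triples.
* **Gain / loss extraction.** Pairs present in both condition networks
  are removed first. Each remaining edge gets a link score = sum of its
  two endpoints' mean log2 expression differences (cancer − normal). The
  gain network keeps cancer edges with both deltas > 0 (top
  `⌈top_frac·n_eligible⌉` by score, default 5% of sign-passing edges);
  the loss network keeps normal edges with both deltas < 0, ranked by
  most-negative score. The score function is the simplest monotone
  summary of "largest concordant change"; it is a pluggable choice.
* **Topology.** Hubs are nodes with distinct-neighbor degree strictly
  greater than a threshold (default 15); an option adds each node's
  distinct mediating miRNAs to its connectivity.
* **lncRNA properties.** Network lncRNAs vs the rest are compared on
  transcript length and exon count with the two-sided Mann–Whitney U test
  (normal approximation with tie correction).
* **Enrichment.** Hypergeometric upper tail P(X ≥ k) for overlap k of a
  node set with a reference set in a configurable universe (default: all
  measured lncRNAs + mRNAs; there is no single canonical universe, and
  enrichment p-values move with this choice).
* **Prognosis.** Per edge, patients are clustered by K-means (K = 2,
  k-means++, best of 10 restarts) on the pair's column-standardized
  expression; group 1 is canonically the higher-lncRNA cluster. Groups
  are compared by Kaplan–Meier curves and the two-group log-rank test
  (hypergeometric variance with standard tie handling); pairs with
  p < 0.05 (uncorrected) are reported. Degenerate clusterings are skipped
  with a logged reason.
* **Drug mapping.** A drug record (drug, miRNA, direction) joins to the
  gain network when direction = up (strengthening repression of
  cancer-up-regulated pairs) and to the loss network when direction =
  down; conflicting records yield both candidates with a warning.

## Synthetic data generator

The generator emulates a two-condition matched expression study (default
60 cancer / 30 normal samples; 300 lncRNAs, 1000 mRNAs, 80 miRNAs —
sized for fast iteration, with a full-cohort 111/28 option) plus all side
tables. All expression is log2-scale Gaussian around feature means.
For a planted triple (L, M, G) in its condition:

    G = α − β · a · g(L) + ε,   g(L) = 1 / (1 + exp(L − μ_L)),
    a = (m − μ_m) + 1,          ε ~ N(0, σ),   β = 1.5, σ = 0.5

The logistic gate `g` implements sponge-mediated de-repression: high L
switches off the repression and the m–G dependence. The miRNA enters
through its centered activity `a` with baseline 1: with raw log2
abundance (μ_m ≈ 3–7) the term β·m·g(L) would make the lncRNA explain
~70% of the mRNA variance — a regime where the lncRNA is just a
co-expressed covariate rather than a modulator, and ΔI > 0 fails. In the
other condition the mRNA keeps unmodulated repression (gate ½), making
the relation condition-specific. Each planted triple has a matched decoy
mRNA (same regulator-overlap construction, unmodulated repression in all
samples) as false-positive control.

Design constraints worth knowing:

* Planted lncRNAs draw means from the 99.5th–99.99th percentile of the
  background mean distribution, and triples share lncRNAs (≤ 6 per
  lncRNA), so every planted lncRNA fits in the top-5% list
  (`⌊0.05·300⌋ = 15` slots) and every planted pair's regulator Jaccard is
  7/9 ≥ 0.7 by construction.
* Differential edges: the first 10 cancer (normal) planted pairs have
  both endpoints shifted +2 (−2) in cancer samples.
* Survival: one planted prognostic pair (the first gain pair). The
  good/poor truth labels are the two-group clustering of that pair's own
  cancer expression (poor = high-expression cluster); poor patients draw
  exponential times at hazard ratio 3, baseline median 60 months, with
  20% independent uniform censoring. Defining truth by the pair's own
  clustering keeps the planted labels identical to the quantity the
  survival scan estimates; a single good/poor labeling cannot be
  simultaneously consistent with several noisy pairs.
* Annotation: planted lncRNAs ~ N(1683, 300) nt with 1 + Poisson(3)
  exons; background ~ N(935, 300) nt with 1 + Poisson(2) — the ~1.8-fold
  length contrast expected of sponge-capable transcripts.
* Reference sets embed the loss-pair mRNAs among tumor suppressors and
  the planted mediator miRNAs among disease miRNAs; the drug table
  contains up-regulators of gain mediators, down-regulators of loss
  mediators, and inert records.

What the generator does **not** emulate: probe-level microarray noise,
correlated background co-expression modules, miRNA families with shared
seed sequences, batch effects, or non-exponential survival. Tests that
pass on this data show the machinery is correct and calibrated, not that
real tumor cohorts carry recoverable sponge signals of this strength.

## Numerical and reproducibility choices

* Natural-log units (nats) by default; bits available.
* `n_bins ≤ ⌊n/3⌋` enforced; shorter inputs are rejected.
* Equal-frequency bin edges are deduplicated so heavily tied data cannot
  produce empty bins; ≤ `n_bins` distinct values map one bin per value.
* TSV writers emit floats as `%.17g` (expression) or `repr` (scores), and
  readers parse with round-trip precision, so write∘read is bitwise
  identity and two runs with one seed are byte-identical end to end.
* Top-k and ranking ties always break by feature id; outputs are sorted.
* Problem sizes in the test and acceptance runs (200 permutations,
  5 generator seeds, 100 log-rank replicates) are the package's standard
  desk-scale settings; all are configurable upward.

## Known limitations

* The ΔI screen's sensitivity at cohort scale is the dominant limitation
  (see *Power* above).
* The Mann–Whitney p-value uses the normal approximation; exact
  enumeration is only used as a test oracle.
* No multiple-testing correction is applied by default at either the
  triple or the prognostic-pair level, matching the screening character
  of the workflow; both analyses accept corrected levels via their alpha
  parameters.
* The enrichment universe is a modeling choice, not an estimate; report
  it alongside any enrichment p-value.
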