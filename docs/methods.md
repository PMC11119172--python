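# Methods

This note documents the statistical model behind `proteostrat`, the
choices made where the procedure admitted more than one reasonable
reading, and what the synthetic-data experiments do and do not show.

## Data model and preprocessing

The input is a wide matrix of raw label-free quantification (LFQ)
intensities, protein groups × samples, with an explicit missing marker:
in LFQ proteomics an absent value means the protein was not detected in
that run, and detection failure is strongly abundance-dependent
(missing *not* at random, left-censored). The pipeline enforces a fixed
transform order through scale/provenance flags on the matrix container,
so a stage applied out of order raises instead of silently producing
nonsense:

1. **Immunoglobulin unification** (raw scale). Mass-spectrometry
   identification splits immunoglobulins into constant-chain and
   complete-protein accession codes. Given a raw→unified code mapping,
   rows sharing a unified code are summed cell-wise; a unified cell is
   missing only when every constituent is missing. Summation must
   happen on the raw (linear) scale — intensities are additive there,
   log2 values are not.
2. **log2 transform.** Variance stabilisation for parametric testing.
3. **Missingness filter.** Proteins missing in *more than* 10% of
   samples are discarded; exactly 10% is kept (the rule is strict
   "more than"). With 34 samples this puts the boundary between 3
   missing (8.8%, kept) and 4 missing (11.8%, dropped).
4. **SampMin imputation** (log2 scale). Each missing cell of sample *s*
   is replaced by 0.95 × the minimum *observed* log2 intensity of *s* —
   a per-sample detection-floor proxy. Two readings of "0.95 × min"
   exist and both are implemented: the default multiplies the log2
   minimum by 0.95 (the formula applied verbatim on the analysis
   scale); `mode="raw"` applies 0.95 to the raw-scale minimum, i.e.
   imputes min + log2(0.95) ≈ min − 0.074. The default is the more
   conservative (lower) fill whenever the log2 minimum is positive.
   A per-protein variant (`mode="*-protein"`) is available but not the
   default: the per-sample reading matches the name ("Samp") and the
   left-censoring rationale.
5. **Sub-datasets.** The diagnosis analysis uses controls + stable
   COPD; the exacerbation analysis uses stable + exacerbated COPD.
   Sub-datasets are cut **before** filtering/imputation and each is
   filtered and imputed on its own samples, so a protein may survive in
   one sub-dataset and not the other.

No normalisation beyond log2 is applied (no median centering, quantile
normalisation or batch correction), and features enter clustering
unscaled; optional z-scoring exists but is off by default.

## Consensus clustering

Samples are the clustered objects; a sample's feature vector is its
full imputed log2 profile. The base clusterer is K-means with
best-of-*n* random initialisations ("restarts", default 5000 for a
reference run); inside the consensus resampling loop the per-resample
restart count is bounded (default 10) because the resampling itself
averages over initialisation noise and a large best-of there costs
H-fold compute for negligible gain.

For each candidate k ∈ {2, 3, 4}, H = 500 subsamples of 80% of the
samples (without replacement) are clustered, and the consensus matrix
entry M<sub>ij</sub> is the fraction of co-clustering among the
resamples that drew both i and j. Pairs never co-drawn (possible only
at very small H) get 0 with a machine-readable warning; the diagonal is
1 by convention.

**Choosing k.** From the empirical CDF F of the off-diagonal consensus
values, the area A(k) = ∫₀¹F = 1 − mean(values) is computed exactly
(many implementations use a truncated histogram sum; the difference is
the tail segment above the largest observed value and does not change
any ordering we observed). Δ(k) is the relative area increase. Two
selection rules are provided:

* `select_method="pac"` (default): pick the k minimising PAC(k), the
  proportion of off-diagonal consensus values in (0.1, 0.9). PAC is 0
  exactly when every resample agrees on the partition and grows with
  any instability; ties go to the smallest k.
* `select_method="delta"`: the classic rule — the largest k with
  Δ(k) ≥ 0.1, else argmax Δ.

PAC is the default because the Δ rule is not a reliable detector at
this cohort scale: splitting a single isotropic Gaussian cloud of
10–20 samples still raises A by ~20% per extra k (the split is
different in every subsample, smearing the consensus), so Δ(k) stays
above any threshold low enough to also accept genuine structure, and
the Δ(4) of genuinely four-cluster data (~0.15) overlaps the Δ(4) of
two-cluster data (~0.13). PAC separates the same simulations cleanly
(0 at the planted K, ≥ 0.16 elsewhere). Both criteria are reported in
the per-run Δ-area table.

**Final partition.** The ensemble labels are obtained by cutting the
average-linkage hierarchical tree of the dissimilarity 1 − M at the
selected k, then relabelled 0..k−1 in order of first appearance so runs
are byte-reproducible.

All randomness descends from one master seed via a stable per-stage
hash, so stages can be re-run in isolation and a full re-run is
byte-identical.

## Confrontation with clinical groups

Clusters carry no clinical information, so cluster→class assignment is
part of the evaluation. The assignment maximises overall accuracy over
all nonempty proper subsets of clusters marked predicted-positive
(exhaustive; ≤ 4 clusters in practice). Majority voting is *not*
equivalent: when both clusters are majority-stable-COPD, majority
voting degenerates while accuracy maximisation still produces the
discriminating assignment. From the resulting TP/FP/FN/TN:

SE = TP/(TP+FN), SP = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
ACC = (TP+TN)/n, MCC = (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Zero denominators yield NaN markers, not exceptions.

**CI convention.** Half-widths are Wald: 100·1.96·√(p̂(1−p̂)/n),
rounded to integer percentage points. `ci_mode="paper"` (default) uses
the positive-class size as n for *every* metric — this is the
convention that reproduces the published tables and is documented as
reverse-engineered, not as the statistically conventional choice —
while `ci_mode="per_metric"` uses each metric's own denominator.

**Display rounding.** The published tables round proportions to three
decimals and then the percentage half-up (19/21 → 0.905 → 90.5 → 91).
`percent_display` implements this double-rounding so reported
percentages match the printed ones digit for digit.

The Fisher exact p (two-sided, hypergeometric) is computed on the
prediction × group 2×2 table; Bonferroni uses the number of
confrontation analyses (2) as family size, and the number of covariates
for covariate tables. Covariates are compared with a Kolmogorov–Smirnov
normality check (recorded), a Levene gate (center = mean, α = 0.05)
choosing Student vs Welch t-tests for continuous variables, and Fisher
exact for binary categorical ones.

## Differential abundance

Run on the filtered log2 matrix **without** imputation: imputed values
would manufacture signal exactly where detection differs between
clusters. A protein is testable when detected in ≥ 50% of the samples
of *each* cluster (inclusive at the boundary) and has ≥ 2 present
values per cluster (an implementation floor recorded per skipped
protein). Levene's test with center = mean (the classic variant;
Brown–Forsythe median centering is selectable) at α = 0.05 gates
Student vs Welch; log2FC is the difference of cluster mean log2
intensities, cluster A (smaller label, reported first) minus cluster B.
Benjamini–Hochberg step-up q-values are computed over the single family
of all tested proteins; q < 0.05 with positive/negative log2FC yields
an over/under call relative to cluster A. Identical degenerate groups
(zero variance, equal means) give p = 1. The remote protein-name
mapping step of the original workflow is replaced by an offline join
against a user-supplied two-column mapping table.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
at the scale of the motivating study (10 controls + 24 stable + 10
exacerbated samples, ~350 protein groups):

* log2 intensities ~ Normal(μ₀ + effect, σ), raw = 2^log2, with
  μ₀ = 20 and σ = 1 log2 units (typical LFQ dynamic-range location and
  between-sample spread); the effect is a constant log2 mean shift on a
  chosen subset of proteins in one designated group, so log2FC and the
  t-test gates are directly interpretable. Unequal-variance scenarios
  come from an optional per-group SD multiplier.
* MNAR missingness: cells below a global intensity quantile are
  censored with a Bernoulli probability; cells above are never
  censored. This is the left-censoring that SampMin imputation
  presumes.
* Ig splits: selected rows become a constant-chain and a
  complete-protein code. Per cell, the split fraction is
  Uniform(0.2, 0.8); with probability 0.2 the whole value goes to one
  code (the other missing), mimicking single-code detections. The
  larger fragment is computed first so the complement v − a is exact by
  the Sterbenz lemma, making unify∘split the bit-exact identity — the
  round trip is tested cell-for-cell.

What the generator does **not** model: peptide-level structure,
retention time or instrument drift, correlated protein modules,
heavy-tailed intensity noise, or batch effects. Passing recovery tests
therefore show the pipeline's correctness under its own assumptions,
not robustness to real-data violations of them.

## Problem sizes used in validation

The validation suites run the method at reduced resampling depth —
consensus with H = 40–60 resamples and ≤ 50 restarts (5 per resample),
cohorts of 120–349 proteins — chosen so the full suite completes in
well under a minute per property while leaving the selection/recovery
behaviour unchanged (consensus frequencies at H = 50 estimate the same
co-clustering probabilities, just with ~0.07 standard error instead of
~0.02 at H = 500). Production defaults remain 5000 restarts / 500
resamples. Recovery checks: cluster-number selection on 20 planted
cohorts (K cycling 2/3/4, disjoint 24-protein blocks shifted by 3 log2
units); partition recovery on 20 study-shaped cohorts (log2FC = 2 on
20% of 349 proteins) scored by adjusted Rand index ≥ 0.9; DAP
false-positive fraction on effect-free cohorts at q < 0.05 compared to
the 0.05 + 3·√(0.05·0.95/m) binomial envelope.

## Known limitations

* The accuracy-maximising cluster→class matching is optimistic for
  many clusters and small samples; it is the evaluation the published
  tables imply, not a validated classifier.
* The Wald intervals (ci_mode="paper") use one shared n; they should
  be read as the published convention, not as correct per-metric
  uncertainty.
* PAC-based k-selection can tie at 0 for nested perfectly stable
  structures; ties resolve to the smaller k (parsimony), which may
  under-split hierarchical data.
* Affinity propagation and mean shift choose their own cluster count;
  they are comparison runs, not part of the consensus procedure.
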