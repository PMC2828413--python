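# Methods

## Scope and data model

`anchorsig` operates on two tables: a features × samples expression matrix
(continuous, log2 scale, TSV with a `feature_id` column) and a per-sample
clinical table with a progression endpoint (`time_months` > 0, `event`
0/1) and the categorical covariates standard in NMIBC prognosis research:
stage (Ta/T1), grade (low/high), tumor count (single/2to7/ge8), size
(> 3 cm yes/no) and intravesical therapy (yes/no). Missing values are not
supported anywhere; readers reject empty or non-numeric cells with the
offending line number. Duplicated identifiers are rejected at read time,
before pandas can silently mangle them.

## Preprocessing

*Quantile normalization* replaces each sample's values so that every
sample shares the across-sample mean of sorted values. Ties within a
sample receive the mean of the reference values at their tied rank
positions; this is the standard convention and makes the operation
deterministic. For tie-free input the value multiset of every sample is
identical afterwards (asserted as a property test).

*Median centering* is two single passes, features first then samples:
subtract each feature's median, then each sample's median. After the
column pass the row medians are in general no longer zero; only the final
pass's zero-median is guaranteed, and only that is asserted. An iterative
(Cluster-3.0-style) centering to convergence was considered and rejected:
a single pass in the stated order is the simplest reading of the
convention and keeps the operation idempotent on doubly-centered input.

## Signature derivation

The cohort is dichotomized at the anchor gene's median; values strictly
above the median are "high". Ties at the median go to the low group —
deterministic, and with an odd cohort (n = 103) it produces the 52/51
split that a "upper 50th percentile" rule implies.

The correlation screen computes, for every non-anchor feature, the Pearson
correlation r with the anchor across *all* samples (not within the
dichotomized groups) and a two-sided p-value via t = r·√((n−2)/(1−r²))
with n−2 df. A feature enters the signature when p < alpha (default
0.001) **and** |r| > r_threshold (default 0.3); both criteria matter — at
small n a large r can still be insignificant. Constant features have no
defined correlation and are excluded, with the count logged and reported.
No multiple-testing correction is applied: the raw p < 0.001 cut *is* the
procedure being modelled, and adding FDR control would change the object
under study. The anchor itself is never screened but always heads the
signature feature list used downstream.

## Clustering into HSC/LSC

Samples are clustered on the signature features only. Similarity is the
uncentered correlation (cosine similarity with zero-mean-assumed scaling
σ⁰ᵥ = √((1/n)Σvᵢ²)); distance is 1 − s ∈ [0, 2]. Agglomeration is UPGMA:
the recorded merge height is the average pairwise inter-cluster distance,
and exact ties are broken by the lexicographically smallest pair of
cluster indices in creation order, which makes every run reproducible.
The implementation is the textbook O(n³) algorithm — exact, and entirely
adequate at cohort scale (n ≤ a few hundred); its heights are checked
against both scipy's average linkage and a literal brute-force average in
the tests.

Two patient groups are obtained by removing the final (root) merge — no
height threshold is involved, because the procedure being modelled states
two groups without a cut criterion. The subtree with the higher mean
anchor expression is labelled HSC, the other LSC; exactly equal means are
refused rather than silently broken, since the labelling would be
arbitrary.

## Class prediction and validation

Gene selection for classification is a pooled-variance two-sample t-test
(p < 0.001 by default), consistent with the classical class-comparison
framework; Welch's test was deliberately not used. Degenerate features
(zero pooled variance) yield t = 0, p = 1 when the means agree and p = 0
with a flag when they differ.

Five classifiers share the selected feature set:

| method | fitted quantities | decision rule |
|---|---|---|
| CCP | per-feature t, threshold = midpoint of class mean scores | side of threshold; exact hit → lower-mean class |
| BCC | same score; class means + pooled variance, priors 0.5/0.5 | posterior ≥ 0.5 → class 1 |
| DLDA | per-class means, pooled per-feature variances | min standardized squared distance; tie → class 1 |
| NC | class centroids | min Euclidean distance; tie → class 1 |
| SVM | linear kernel, hinge loss, C = 1, no rescaling | sign of w·x + b; 0 → class 1 |

The diagonal (not full-covariance) LDA variant is used because with
p ≫ n the full covariance is singular; DLDA is the stable convention in
this setting and reduces analytically to NC when all pooled variances are
equal (asserted in the tests). CCP and BCC share the compound covariate
computation, asserted equal. BCC priors are equal because nothing in the
modelled procedure specifies otherwise.

LOOCV repeats the *entire* model-building procedure — selection included —
with the held-out sample removed, so that sample can influence nothing in
its own fold. This is the property that makes cross-validated error
estimates honest, and it is tested directly: corrupting the held-out
sample's values must leave the fold's selected features and fitted
parameters bit-identical, for every method. A fold whose selection comes
up empty is recorded as failed and predicted as the training majority
class. An optional alpha grid for "optimizing the number of genes" was
considered and left out of the primary path; the fixed-alpha procedure is
the object under study.

Confusion metrics (sensitivity, specificity, PPV, NPV) are reported per
class treated as positive, one block per method; undefined ratios (empty
denominator) are reported as missing, never as zero.

## Survival statistics

Kaplan–Meier estimation, the two-group log-rank test (hypergeometric
variance) and Cox regression are implemented in full rather than
delegated, because the package needs access to internals that libraries
do not expose uniformly: the score vector and information matrix (the
score test at β = 0 must equal the log-rank χ² on tie-free data, an
identity asserted to 1e-9), the exact tie rule, and the convergence
diagnostics. lifelines serves as an independent cross-check in the test
suite — estimates, standard errors and p-values agree to 1e-6 on tied
data — never as the implementation.

The Cox partial likelihood uses the Efron tie correction (follow-up in
months ties heavily; Efron is the accurate default) and is maximized by
Newton–Raphson with step-halving, converging when max |score| < 1e-9
(max 50 iterations). Standard errors come from the inverse observed
information; confidence intervals are Wald, exp(β ± 1.96·SE). A monotone
likelihood (perfect separation) cannot converge to a finite maximizer;
fits whose score vanishes only because |β| has run past 15 are flagged
non-converged with a diagnostic rather than reported as reliable. A
singular information matrix raises an error naming the collinear
columns. The design matrix fixes reference levels at stage Ta, low grade,
single tumor, size ≤ 3 cm, no therapy, LSC; covariate levels never drawn
in a given cohort are dropped from the design (they carry no contrast).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not microarray physics (no probe effects, batch structure, or platform
differences — results on synthetic data say nothing about cross-platform
transfer). Per sample j: a latent cluster z_j ~ Bernoulli(cluster_prob);
anchor a_j ~ N(anchor_means[z_j], anchor_sd²); module feature g:
x_gj = β_g·(a_j − mean(anchor_means)) + N(0, module_noise_sd²) with
|β_g| ~ U(module_loading_range) and a fixed fraction of negative signs;
background features i.i.d. N(0, 1). Progression times are exponential
with rate baseline_hazard·hazard_ratio^z (the simplest generative model
satisfying proportional hazards, so Cox recovery is well defined),
censored by an independent U(0, censor_horizon) administrative time.
Clinical covariates are drawn per cluster from configurable categorical
distributions and are, by default, independent of survival given the
cluster — the signature is deliberately the only prognostic factor.

Defaults describe the study conditions the package targets: 103 samples,
an anchor plus a 1,000-feature module among 5,000 features, cluster
probability 0.49, anchor means ±1 with SD 0.5 (a 4-SD separation), |β| ∈
[0.5, 1.5] with 35% negative loadings, unit module noise. Hazard defaults
(baseline 5.9·10⁻⁴/month, hazard ratio 5, horizon 137 months — the
maximum follow-up of such a cohort) were solved analytically so the
expected event fraction, 1 − (1 − e^{−λτ})/(λτ) mixed over clusters,
equals 0.107, the progression rate of the motivating cohort (11/103).
Module features derive from the *centered anchor signal* rather than from
the cluster directly, so the anchor-feature correlation
β·σ_a/√(β²σ_a² + σ_noise²) is controlled explicitly and checked
empirically.

Reproducibility: all draws flow from one generator seeded by `seed`, with
one deliberate refinement — gene-level structure (loadings and signs) is
drawn from a separate `structure_seed` that defaults to `seed`. A
training cohort and an independent validation cohort simulated with the
same `structure_seed` but different `seed`s then share their biology (the
same genes form the module, with the same signs) while sharing no
samples. Without this, each cohort would re-draw which genes correlate
with the anchor, and cross-cohort prediction would be meaningless — no
real pair of cohorts re-randomizes its gene regulatory structure.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at desk scale, chosen
to keep each statistical check adequately powered: oracle comparisons on
≤ 20 × 10 instances at 1e-9; hazard-ratio recovery at n = 1000; CI
coverage over 500 cohorts of n = 300 (binomial 3σ on a 95% target is
about ±3%); log-rank type-I over 1000 null cohorts of n = 103; gene
selection type-I over 80,000 feature-tests; classifier transfer with the
full default cohort (train 103, test 302). Tolerances in tests are either
exact (tie rules, determinism, leakage), agreement bounds for
independent implementations (1e-6 to 1e-12), or sampling bands (3σ
binomial, 3·SE for estimates).

## Known limitations

- Single-pass median centering and the specific quantile-norm tie rule
  are conventions; other toolchains iterate or break ties differently.
- The Cox Newton–Raphson assumes a modest covariate count; it is not
  tuned for high-dimensional regularized fits.
- The synthetic generator's clusters are well separated by construction;
  passing tests demonstrate the machinery is correct and consistent, not
  that any real cohort contains such structure.
- Small cohorts with few events routinely produce non-converged
  (separated) multivariate Cox fits; the package flags these honestly
  rather than suppressing them, and so does the README example when run
  at other seeds.
- No probe annotation, GEO parsing, pathway/network analysis, or
  cross-platform feature mapping.
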