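# Methods

This note records the models, defaults and numerical choices behind
metabokit, and what the synthetic-data generators do and do not emulate.

## Data model and processing

A `DataTable` is a samples × features matrix of concentrations with a group
factor, an optional second factor (e.g. time), and an ordered processing
log. Every transformation appends a structured descriptor to the log;
`replay(raw, log)` reproduces a processed table bit-for-bit, which is the
package's reproducibility contract and is enforced by a test.

- **Minimum group size 3.** Variance estimates (t-tests, ellipses) are
  undefined below that; the integrity check fails rather than warns.
- **Missing tokens** are the empty string, `NA`, `NaN` (case-insensitive);
  the delimiter is sniffed between comma and tab, decimal point only.
  Non-numeric cells are recorded verbatim and fail the integrity check
  instead of being coerced.
- **Imputation default is half-minimum**: a missing value is replaced by
  half of that feature's smallest positive observed value, the usual
  treatment for left-censored metabolomics data. A feature with no positive
  observation falls back to the global half-minimum with a logged warning.
  KNN imputation averages the k (default 10, capped at n−1) nearest samples
  by root-mean-square distance over co-observed features.
- **Normalization order** is row method → transform → scaling. Sum
  normalization rescales each sample to a total of 1000 — an arbitrary but
  logged constant; any positive constant gives identical statistics after
  scaling. Zeros ahead of a log10 transform are offset by half the smallest
  positive matrix value (logged). Zero-variance features under
  auto/Pareto/range scaling are left centered with a logged warning.
- **Filtering** drops the `floor(fraction × m)` lowest-dispersion features
  (IQR, SD or MAD), ties broken by feature id; the near-constant rule drops
  features identical in more than 95% of samples.

## Univariate statistics

Welch's t-test is the default (group variances in metabolomics are rarely
equal); the pooled-variance test is available and is what the ANOVA path
uses for two groups, where F = t². Fold changes are computed on
pre-scaling positive data because scaling destroys ratio interpretation.
FDR adjustment is Benjamini–Hochberg throughout. Ranks order by ascending
p-value with lexicographic feature-id tie-break. The post-hoc test after
ANOVA is Tukey HSD, run only for features significant at the FDR level —
one defensible choice among several.

## Multivariate

PCA is a column-centered SVD with a deterministic sign convention (the
largest-magnitude loading entry of each component is positive). PLS-DA is
a NIPALS fit of the one-hot group indicator with deflation on X only,
capped at 5 components; VIP scores satisfy mean(VIP²) = 1. Confidence
ellipses on 2D scores are the χ²(2) quantile contour of each group's
sample mean and covariance — a region for the group *scatter*, not the
mean; with fewer points the mean-region reading would be an alternative,
and the choice is recorded in the ellipse output. Heatmaps default to
Euclidean distance with Ward linkage and a diverging scale over symmetric
robust (1st/99th percentile) limits. The overview canvas is fixed at
900 × 720 px; the detail view grows as 120 + 12·m px so every feature row
stays legible, and above the 2000-feature cap the top-variance features
are retained (logged). Correlation maps exclude zero-variance vectors from
clustering and report their correlations as missing.

## Name mapping

Queries are normalized (lowercase, punctuation stripped, whitespace
collapsed) and resolved by exact primary name, then synonym, then direct
identifier (HMDB = `HMDB`+digits, KEGG compound = `C`+5 digits, PubChem =
all digits), then fuzzy matching. Fuzzy similarity is 1 − edit distance /
max length; a candidate is accepted at similarity ≥ 0.85 with a margin
≥ 0.02 over the runner-up, otherwise the query is reported unmatched with
its top-5 candidates. Candidate pruning (length within ±30%, at least one
shared token or 3-gram) is a speedup only; a test verifies it never
changes the accepted answer on 500 perturbed library names. The thresholds
keep false merges rare on compound vocabularies where one-character
differences can be chemically meaningful; both are configurable at module
level. The bundled library is synthetic: real metabolite names and
synonyms paired with format-valid but non-authoritative identifiers, and
is intended for tests and demonstrations, not annotation.

## Pathway analysis

ORA uses the right-tail hypergeometric test with the universe defaulting
to the union of library members; a user-supplied universe should be given
when only a measured subset of the metabolome is detectable, otherwise
enrichment is biased. Topology importance is raw betweenness (or
out-degree) normalized to sum to 1 per pathway; edgeless graphs fall back
to uniform importance. Impact is the summed importance of hit nodes.
Enrichment p and impact are reported side by side without combining them
into one score — several combination schemes exist and none is canonical.
Gene vs metabolite typing in the integrated mode uses namespace prefixes
(`G:` / `C:` in the toy libraries).

## Biomarker analysis

AUC is tie-corrected pair counting, identical to the trapezoidal area of
the empirical curve; a sub-0.5 AUC flips the score direction and records
the flip. Bootstrap CIs are percentile intervals over class-stratified
resamples (default 2000). The MCCV explorer uses stratified 2/3 : 1/3
splits (default 50 iterations), ranks features by |Welch t| on the
training split only — fast and classifier-agnostic — and reports, per
panel size: the pooled held-out ROC, the mean per-iteration AUC, its
2.5/97.5 percentile band, selection frequencies and holdout accuracy.
Classifier scores are the PLS-DA regression output for the positive class
(2 components), the SVM signed margin, and the random-forest positive
vote fraction (100 trees). The permutation test uses the mean MCCV AUC as
its statistic with the add-one estimator p = (1 + #{perm ≥ obs})/(B + 1);
resubstitution AUC would make the null dishonest. All stochastic
operations take explicit seeds and are bit-reproducible.

## Power analysis

Pilot statistics are pooled-variance t (to match the noncentral-t model
with ν = n₁+n₂−2). Diagnostics check that the central half of the ordered
statistics tracks a line against central-t quantiles (max deviation < 0.5
after a least-squares fit on that region — fitting on the central half
keeps one-sided alternatives in the tails from dragging the line) and that
the fraction of p < 0.05 exceeds 0.05 by more than two binomial standard
errors, i.e. that signal is present at all.

The effect-size distribution is a binned NNLS mixture fit: 60 equal-width
bins over the observed statistic range, components central t plus
noncentral t on a ±6 grid in steps of 0.5 (zero excluded), mass
constrained to 1 via a heavily weighted extra equation. Components with
|noncentrality| ≤ 1 are nearly collinear with the central component; a
small ridge penalty (0.1) on their weights resolves that degeneracy in
favor of the null. This keeps π₀ well calibrated (median recovery error
≈ 0.02 at π₀ = 0.8, m = 5000) and makes power predictions conservative:
effects indistinguishable from noise in the pilot are not credited.

Average power uses the marginal (expected-proportion) FDR characterization
rather than sample-path BH, standard in planning calculations; the
threshold is found by Brent root-finding (residual < 1e-6). When the
equation has no root — pure alternatives (π₀ ≈ 0), where marginal FDR is
below α everywhere — the per-test α quantile is used, which reduces to the
classical noncentral-t power; when even the most stringent threshold
cannot reach FDR ≤ α (tiny n), the threshold is infinite and power is 0.
Candidate sizes are equal per group on a log-spaced grid from 3 to 1000.

## Synthetic data

`make_two_group` draws log-normal concentrations (positive, right-skewed,
as real metabolite tables are): log-values are Gaussian with per-feature
baselines ~ N(3, 0.5) and unit SD, informative features shifted by d SDs
on the log scale in group B, and missingness completely at random. The
generators emulate effect size, dimension and censoring-style missingness;
they do **not** emulate correlated feature blocks, batch effects,
instrument drift, heteroscedastic noise or intensity-dependent missingness.
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under its stated model, not that any specific real dataset
satisfies that model. Pathway libraries are random sets over a synthetic
prefixed universe with random weakly connected digraphs; the planted
pathway's members are reserved so its designed hit lists touch no other
pathway.

## Problem sizes in the test suite

The suite exercises null calibration at m = 2000 features, π₀ recovery at
m = 5000 over 20 seeds, CI coverage over 500 simulated datasets × 2000
bootstrap resamples, power calibration over 20,000 simulated studies, and
MCCV at 50 iterations — sizes chosen so the whole suite completes in well
under a minute on a laptop while keeping Monte-Carlo standard errors
comfortably inside the asserted tolerances.

## Known limitations

- Fold change and volcano assume strictly positive pre-scaling data.
- The deconvolution reports the mixture on the prescribed grid; effects
  between grid points split across neighbors, and effects below |d| ≈
  1/√(n₁n₂/(n₁+n₂)) are deliberately absorbed into π₀.
- PLS-DA significance is not assessed per se; use the biomarker
  permutation test for model-level inference.
- The bundled compound library is a synthetic stand-in; real annotation
  requires loading an authoritative library export.
- No non-parametric univariate tests, two-way ANOVA, quantitative
  (globaltest-style) enrichment, or covariate-adjusted ROC.
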