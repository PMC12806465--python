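# Methods

This note documents the statistical models implemented in `senoconverge`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the package's known limitations.

## Marker-positive cell proportions

A cell is marker-positive when its marker expression is strictly above a
threshold (default 0, i.e. any nonzero transcript counts). Tallies
aggregate by pooling cells within each tissue/sex/age stratum. Group
comparisons use the two-sided Pearson chi-squared test on the 2x2
positive/negative table; Yates' continuity correction
`chi2 = N(|ad - bc| - N/2)^2 / (r1 r2 c1 c2)` (clamped at zero when
`|ad - bc| <= N/2`) is on by default and can be disabled. Effect sizes are
odds ratios with Wald log-odds intervals, `SE(log OR) = sqrt(sum 1/n_ij)`;
a zero cell triggers the Haldane–Anscombe 0.5 correction in the odds
computation only, never inside the chi-squared statistic.

Pooling cells ignores animal-level clustering, so p-values are
anti-conservative relative to a mixed model when per-animal variation is
large. The tally record deliberately carries no animal identifier — it
mirrors the stratum-level summaries that single-cell atlas reanalyses
usually publish — so per-animal weighting is out of reach of this data
model and is listed as a limitation rather than an option.

## Signed differential-expression score

Per gene and condition, `S = -log10(p_adj) * sgn(log2FC)` with `sgn(0) = 0`.
Adjusted p-values of exactly zero (underflow in upstream DE tools) are
clamped to 1e-300, capping |S| near 300. The score matrix is built over the
exact intersection of the input tables' genes; genes with a missing
adjusted p anywhere are dropped, not imputed. The informative-gene filter
keeps rows with `max |S| > cut` (strict; default cut 2). The sign is taken
from the input table's fold-change column as provided — whether that column
holds shrunken or unshrunken estimates is the caller's choice, since
shrinkage happens upstream of this package.

BH adjustment is the standard step-up procedure; it is delegated to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")` and verified
in the test suite against an O(m^2) definitional oracle.

## Single-sample gene-set scores

The implementation follows the gene-set variation analysis construction
with one fixed variant (documented rather than configurable, because the
alternatives change results silently):

1. Per gene, a cross-sample kernel CDF statistic: Gaussian kernel with
   bandwidth `sd/4` (constant genes get 0.5 with a warning), or the
   empirical CDF when `kernel="none"`.
2. Per sample, genes are ranked by that statistic (ties broken by input
   gene order) and weighted by the symmetric rank score `|r - (G+1)/2|`.
3. Per set, a weighted Kolmogorov–Smirnov random walk (weight exponent 1):
   hits add their normalized symmetric score, misses subtract `1/(G - m)`.
   The score is the maximum positive plus the maximum negative deviation
   (signed-difference convention), bounded in [-1, 1].

At least two samples are required (the statistic is cross-sample); set
members are intersected with the matrix and empty sets dropped.

## Preranked GSEA

Genes are sorted by the ranking statistic, descending. Ties are broken by
a random shuffle under the run seed followed by a stable sort — reproducible
without introducing a systematic ordering bias. The running sum adds
`|s|^w / sum_hits |s|^w` on hits (w = 1 by default) and subtracts
`1/(G - m)` on misses; ES is the signed maximum deviation. The null is
gene-set permutation: `nperm` random same-size sets (default 1000), chosen
because the inputs are ranked lists with no sample-level structure to
permute. The permutation p-value is two-sided with a +1 pseudocount,
`p = (1 + #{|ES_null| >= |ES|}) / (nperm + 1)`. NES divides ES by the mean
|null ES| of matching sign, the standard preranked convention. BH
adjustment runs within one collection at a time so p-values from different
gene-set databases are never pooled. Set-size window defaults (10, 500) are
the field's conventional choices. When the positive and negative walk
extrema tie exactly in magnitude the reported sign is arbitrary; this
measure-zero case only arises in adversarial inputs.

## Condition similarity and clustering

Spearman correlation with average ranks for ties and pairwise-complete
observations; constant columns yield flagged-missing coefficients that
exclude the condition from clustering. Clustering is agglomerative on the
distance `1 - rho` — not `1 - |rho|`, because the sign structure
(aging versus intervention) is the object of interest — with average
linkage by default (single/complete available). NES-level similarity first
restricts to gene sets with adjusted p below 0.1 in at least one condition
(union semantics), then correlates NES profiles. Gene-level similarity is
typically run on the informative-score matrix; the significance-based
filter (adjusted p below a cut in at least one condition) is exposed as an
independent parameter because the two filters serve different figures of
merit.

## Random-effects meta-analysis and the robust signature

Per gene, study effects y_i (log2 fold changes) with standard errors se_i
are pooled under `y_i ~ Normal(mu, se_i^2 + tau^2)`. tau^2 is the
Paule–Mandel estimate: the root of the generalized Cochran equation
`Q(tau^2) = sum w_i (y_i - mu_w)^2 = k - 1` with `w_i = 1/(se_i^2 + tau^2)`.
Q is monotone decreasing in tau^2, so the solver brackets the root by
doubling and bisects to |delta tau^2| < 1e-10; `Q(0) <= k - 1` returns
exactly 0 with no continuity correction. Inference on the pooled effect is
Wald-normal (not Knapp–Hartung), matching the default of the standard
random-effects software this analysis style is associated with.
Heterogeneity is reported as tau^2, `Q = Q(0)`, and the estimator-based
`I^2 = 100 tau^2 / (tau^2 + s^2)` with
`s^2 = (k-1) sum w0 / ((sum w0)^2 - sum w0^2)`, `w0 = 1/se^2`.

The robust signature applies two nested, strict criteria: pooled p < 0.01
(raw by default — the convention of this analysis is a raw meta p, with a
BH option off by default) and maximum leave-one-out p < 0.1, where each
leave-one-out fit re-estimates tau^2. Genes missing from any study are
dropped rather than partially pooled: the maximum-over-exclusions criterion
presupposes complete k-study data. The implementation is vectorized across
genes (array bisection), so a 2,000-gene, 3-study run with all LOO fits
takes well under a second.

## TF activity

The univariate linear model: for each TF, a predictor over the full
signature universe carrying the signed mode-of-regulation weight on targets
and zero elsewhere; OLS of the signature on the predictor (with intercept);
activity is the slope t-statistic, p from t with G-2 df. The regulon
resource is filtered to curation confidence A–C. `min_targets = 5`
(configurable) stabilizes the t-statistics. The ULM is one of several
activity-inference methods in common frameworks; it was chosen as the
simplest well-calibrated member of that family, and the null-calibration
test (significance rate ~5% under a noise signature) guards that property.
Consensus requires p below the cut in every study *and* identical activity
sign (a flag relaxes to significance-only, reporting direction "mixed").

## Transcript–protein coupling

Gene-wise Spearman across matched samples (>= 3 finite pairs; all-tied
layers excluded and counted), with exact permutation p-values for n <= 9
untied samples (the exact null distribution of rho is enumerated once per n
and cached) and the t approximation otherwise — matched-proteome designs
are often a dozen animals, where the exact path matters. Summaries
(fraction positive, fraction significant at 0.05, median rho) recompute
exactly from the per-gene table. Sample-wise coupling is Pearson across
genes per sample. The global abundance correlation averages each layer per
gene across samples (log10 first if the inputs are linear-scale) and takes
Spearman across genes. Pooling treatment groups is the default; callers can
subset columns to correlate within group.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed), with the planted
truth serialized alongside the data.

- `simulate_de_studies` — default 2,000 genes, 3 studies, 5% shared-signal
  genes (mu = 1, tau = 0.2), 2% opposed-effect genes (sign alternates
  across studies, exercising the LOO filter), 3% study-specific genes, the
  rest null; heteroscedastic SEs uniform on (0.1, 0.3); observed effects
  `y ~ N(theta, se^2)`, `theta ~ N(mu_g, tau^2)`; two-sided Wald p-values
  and per-study BH. The universe size trades stable false-discovery
  estimates against seconds-scale tests.
- `simulate_expression` — Gaussian log-scale expression with per-gene means
  and planted per-set group shifts.
- `simulate_cell_tallies` — binomial positives under a logistic prevalence
  model in age with sex and sex-by-age terms; default intercept puts young
  prevalence near 10%, the order of magnitude of marker-positive fractions
  in aging mouse tissue.
- `simulate_tf_signature` — signature = sum of activity x mode-of-regulation
  over targets, plus Gaussian noise.
- `simulate_omics_pair` — per-gene bivariate Gaussian sample deviations
  with correlation rho; per-gene abundance offsets shared between layers,
  so cross-gene abundance correlation and within-gene coupling are
  controlled independently.

What passing tests on these generators shows: the estimators recover
planted effects at their nominal error rates under their own model
assumptions. What it does not show: robustness to count noise,
normalization artifacts, batch effects, correlated genes, library-size
variation, missing-not-at-random proteomics, or mislabeled samples — none
of which the generators produce. Results on real data inherit all of those
upstream risks.

## Numerical choices

- tau^2 bisection tolerance 1e-10; bracket doubling capped at 200 steps.
- Adjusted-p floor 1e-300 before log10.
- GSEA/GSVA tie-breaking as described above; degenerate all-tied rankings
  are rejected rather than silently scored.
- Spearman pairs with fewer than 3 complete observations, or a constant
  side, are flagged missing rather than returned as 0.
- All Monte-Carlo tests fix their seeds; CLI outputs are byte-identical
  under a fixed seed (metadata sidecars carry no timestamps).

## Known limitations

- No partial pooling: genes absent from one study are excluded from the
  meta-analysis entirely.
- No phenotype-permutation GSEA, leading-edge reporting, or enrichment-map
  style set-overlap networks.
- No animal-level mixed models for proportion data (see above).
- The ULM is the only activity-inference method; multivariate or
  enrichment-based alternatives can rank TFs differently on correlated
  regulons.
- Gene identifiers are opaque strings; no cross-species or symbol/ID
  mapping.
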