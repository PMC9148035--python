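# Methods

This document records the statistical model implemented by `nutripatterns`,
the generative model behind the synthetic cohorts, the numerical
conventions chosen where textbook definitions leave freedom, and known
limitations.

## 1. Preprocessing

- **Exclusions.** Participants with implausible reported energy intake are
  removed before analysis; the default cap is 3500 kcal/d, applied strictly
  (`energy > cap` excluded, the boundary retained). The operation is
  idempotent and reports the excluded IDs.
- **Energy adjustment.** Nutrient intakes are converted to densities per
  1000 kcal: `density = intake × 1000 / energy`. Densities remove the
  gross-intake dimension so that patterns reflect dietary *composition*.
- **Ratios.** Three composition ratios enter the pattern matrix unadjusted:
  carbohydrate/fiber, animal/plant protein and
  (MUFA+PUFA)/SFA. Zero denominators raise a named error; an optional
  floor substitutes a small positive value where the caller prefers
  imputation over failure.

The default pattern matrix has 18 columns: 15 nutrient densities
(folate, magnesium, potassium, thiamin, vitamin B6, vitamin C, iron, zinc,
niacin, riboflavin, vitamin B12, protein density, SFA, MUFA, cholesterol —
see `cohort.PATTERN_VARIABLES` for the canonical list) plus the three ratios.

## 2. Nutrient patterns (PCA + varimax)

- PCA is performed on the **correlation matrix** (variables standardized),
  so each variable contributes unit variance and the total variance is *p*.
- **Explained variance** is reported as 100·λⱼ/p from the *unrotated*
  eigenvalues; after rotation, the per-factor sum of squared loadings
  replaces λⱼ. Both are exposed.
- **Varimax** uses the SVD sweep algorithm with Kaiser normalization
  (rows scaled to unit communality during rotation), tolerance 1e−6,
  maximum 100 sweeps. The rotation matrix is returned so scores and
  loadings stay consistent.
- **Sign convention:** each rotated factor is flipped so its
  largest-magnitude loading is positive. This makes labels reproducible
  across platforms (eigenvector signs are otherwise arbitrary).
- **Factor scores** use the regression (Thurstone) estimator
  `F = Z R⁻¹ Λ` on standardized data.
- **Sampling adequacy.** KMO uses anti-image partial correlations
  `q_ij = −R⁻¹_ij / √(R⁻¹_ii R⁻¹_jj)`; Bartlett's test uses
  `χ² = −(n−1−(2p+5)/6)·ln det R` with df = p(p−1)/2.
- **Retention** is a fixed `n_factors` from configuration; an
  eigenvalue > 1 table is produced as advisory output only, so the
  pipeline never silently changes dimensionality between runs.
- **Salience threshold** for labeling patterns is |loading| ≥ 0.5
  (configurable); signs are retained in the labels.

These routines are implemented in-package (and verified against
direct-formula oracles and `pingouin` in the test suite) because no
factor-analysis dependency is part of the runtime stack.

## 3. Clustering on factor scores

- **Ward's criterion** on squared-Euclidean dissimilarity via
  `scipy.cluster.hierarchy.linkage(method="ward")`; merge heights follow
  scipy's √(2·ΔSS) convention. Tie-breaking is therefore scipy's; an
  exhaustive-enumeration oracle in the tests confirms height equality on
  small inputs.
- **Cut labels** are renumbered by decreasing cluster size (ties broken by
  first member index) so that "cluster 1" is always the largest.
- **Factor discrimination** is η² = SS_between/SS_total with the usual
  one-way-ANOVA F test p-value.
- The number of clusters *k* is a configuration choice (default 6); an
  advisory table of mean silhouette widths over a small range of *k* is
  produced, not acted on.

## 4. Diet-quality indexes

- **Pregnancy-modified MedDiet Score:** 10 components scored 0–5 from
  monthly consumption frequency against configured threshold bands
  (default bands at 1, 5, 9, 13, 19 servings/month). Eight protective
  components (non-refined cereals, potatoes, fruits, vegetables, legumes,
  fish, olive oil, dairy) score upward; red/processed meat and poultry are
  reverse-scored; alcohol is excluded. Boundary consumption moves
  protective components *up* a band and adverse components *down* a score.
  Total 0–50, integer.
- **HEI-2010:** 12 components scored by linear interpolation between a
  zero-score and a maximum-score density standard, truncated to
  [0, max points]; moderation components (refined grains, sodium, empty
  calories, with the fatty-acid ratio handled by its own standards) are
  reverse-scored by construction. The configured points sum to 100 and the
  score is invariant to proportional energy scaling.
- **Dietary GI:** Σ(GIᵢ·carbᵢ)/Σcarbᵢ over consumed items, on the
  white-bread reference scale; glucose-scale inputs are converted by
  ×100/70.

All standards are data, not code: `src/nutripatterns/data/*.yaml`.

## 5. Cross-cluster statistics

- Router: Levene's test (center = mean) at α = 0.05 decides between
  classic one-way ANOVA + Tukey HSD and **Welch ANOVA** (Satterthwaite df)
  + **Games–Howell** (studentized-range reference,
  q = |Δmean|·√2/SE, Welch pairwise df).
- Non-parametric route: Kruskal–Wallis with a **Monte-Carlo permutation
  p-value** and pairwise Mann–Whitney; contingency tables use Pearson χ²
  with tables drawn conditionally on both margins
  (`scipy.stats.random_table`). Monte-Carlo p-values use the unbiased
  add-one estimator p = (b+1)/(m+1), default m = 10 000, so the smallest
  attainable p is 1/(m+1).
- Group mean orderings are summarized by compact letter display (greedy
  maximal non-significant runs).

## 6. Adequacy appraisal

- **Probability approach:** individual probability Φ((intake−EAR)/SD);
  cluster prevalence = 100 × mean probability. Default references cover 14
  nutrients with EAR and SD = CV × EAR (CV 0.10 unless stated otherwise in
  the config).
- **Cut-point method:** for fiber (AI 28 g/d), potassium (AI 2.9 g/d) and
  calcium (EAR 800 mg/d, no SD route), the percentage of individuals whose
  intake, rounded half-up to the reference's printed precision, is at or
  above the reference. Half-up rounding (with a 1e−9 tie guard against
  binary representation of decimal fractions) matches conventional
  reporting; numpy's banker's rounding would misclassify boundary intakes
  such as 2.85 g/d against a 2.9 g/d reference.
- **Uncertainty:** 95% BCa bootstrap over individuals (default B = 500).
  Bias correction z₀ uses the midrank-tied fraction of replicates below the
  point estimate, clipped to [0.5/B, 1−0.5/B]; acceleration comes from
  jackknife skewness. A constant bootstrap distribution yields a zero-width
  interval; the reported interval is clamped to bracket the point estimate.
- Percentile rows (P10/P25/P50/P75/P90) use linear interpolation of order
  statistics (`numpy.percentile`, method "linear").

## 7. Synthetic-cohort generative model

The generator emulates the *structure* of an FFQ cohort — not any real
population's intake levels:

- Participant *i* in cluster *c* draws factor scores
  `f_i ~ N(centroid_c, I₂)`; the default six centroids are placed so both
  factors discriminate the clusters strongly (observed η² ≈ 0.75–0.79).
  Default cluster sizes are (179, 33, 142, 67, 127, 60), n = 608.
- Standardized density signal `x = Λf + ε`, with a planted 18×2 loading
  matrix Λ and uniquenesses √(1−h²); densities are an affine map
  `a·(1 + 0.10·x)` around per-1000-kcal target means, clipped at 0. The
  0.10 relative scale keeps densities positive while preserving the
  correlation structure.
- Energy is lognormal(ln 1900, 0.2); raw intakes = density × energy/1000.
  Fiber is derived as carbohydrate/ratio so ratio derivation round-trips.
- Food-group energies are Dirichlet shares (cluster-tilted alphas) of 85%
  of energy; MedDiet/HEI/GI inputs and carbohydrate items are generated
  with cluster-dependent quality tilts so diet-quality gradients across
  clusters are realistic.
- All draws come from one `numpy.random.Generator` in a fixed order, so a
  seed fully determines the cohort. `inject_overconsumers` rescales chosen
  participants' energy into 3600–4500 kcal for exclusion testing.

What it does **not** model: measurement error/attenuation of FFQs,
seasonality, correlated requirement distributions, under-reporting, or any
real food-composition database; intake magnitudes are plausible but not
population-calibrated.

## 8. Numerical conventions

- Percentages in report tables are rounded to one decimal at the reporting
  boundary only; internal computation is full precision.
- Monte-Carlo exceedance counts use a 1e−12 slack (`perm ≥ obs − 1e-12`) so
  exactly-tied permutation statistics count as extreme.
- Correlation-degenerate (constant) columns are reported by name rather
  than propagating NaNs.
- Pipeline outputs are plain delimited text plus a JSON manifest; reruns
  with the same config and seed are byte-identical.

## 9. Open design decisions and limitations

- Problem sizes (n = 608, p = 18, m = 2, k = 6, B = 500, m_MC = 10 000) are
  the package's defaults, chosen to keep a full pipeline run in seconds;
  all are configurable.
- The Ward implementation inherits scipy's tie-breaking; other software may
  order tied merges differently (heights and cut partitions agree).
- The BCa jackknife is O(n) statistic evaluations per interval; for very
  large clusters a block jackknife would be preferable (not implemented).
- Games–Howell p-values rely on `scipy.stats.studentized_range`, which is
  itself numerical; agreement with `pingouin` is verified to 1e−6 in the
  tests.
- The probability approach assumes normal requirement distributions and
  uncorrelated intake/requirement; nutrients with skewed requirements
  (e.g. iron in menstruating women is often modeled log-normally) are
  approximated by the normal route unless the DRI config supplies a
  different SD.
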