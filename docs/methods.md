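# Methods

This note documents the statistical model behind `seromir`, the design
of its synthetic-data generator, and the numerical choices that were
genuinely open, in the order the pipeline runs them.

## Normalization

Size factors are median-of-ratios: s_j = median over reference features
i of k_ij / g_i, with g_i the geometric mean of feature i across
samples and the reference set restricted to features positive in every
sample (the geometric mean of anything containing a zero is zero). The
median is taken on the ratio scale, not as the exponential of a
log-scale median — the two differ whenever the reference count is even.
If no all-positive feature exists the estimator raises rather than
silently falling back; serum panels after even minimal filtering always
contain several. Normalized counts are k_ij / s_j and a feature's
*base mean* is its across-sample average of normalized counts.

## KS cost-function thresholding

Rationale: below some count level, serum small-RNA data are dominated
by sporadically expressed transcripts whose distribution differs from
sample to sample, while consistently expressed miRNAs agree. The
two-sample KS statistic D = sup|F_x − F_y| between two samples' count
distributions therefore acts as a cost: large while noise is included,
small once it is excluded.

- **Pairs.** The design has one library per animal, so there are no
  technical replicates; all within-condition sample pairs serve as the
  replicate analogue, subsampled to at most 200 pairs (seeded) and
  aggregated by the mean D. Both the pair set and the aggregation are
  configurable.
- **Scan.** For each t in an ascending grid (default integers 0–100 in
  normalized-count units), features with base mean ≥ t are retained and
  the mean pairwise D of log2(normalized + 1) values over retained
  features is recorded. Grid points retaining fewer than two features
  are marked invalid. D of the unfiltered matrix (t = 0) is reported as
  the baseline.
- **Selection.** t\* is the smallest valid t with
  D(t) ≤ min D + ε, ε = 0.01 by default — the D resolution of a
  ~100-feature comparison is about 1/100, so smaller differences are
  noise. ε is exposed; validation fixtures with 300 features use
  ε at the same 1/n scale.
- A technical remark: the KS statistic is invariant under strictly
  monotone transforms, so the log2 transform cannot change any D value;
  the `log_transform` flag exists for interface completeness only.

## Filtering

Features with base mean < t\* are removed first, then features with
zero counts in strictly more than 10% of samples. The mean-filter
boundary is inclusive (≥ t\*), the prevalence boundary strict
(> 10%). Both filters are per-feature predicates, so their composition
is order-independent; the pipeline nevertheless fixes the order
(threshold, then prevalence) and a regression test pins the
commutativity down.

## PCA sample QC

Normalized counts are variance-stabilized as log2(x + 1) — a shifted
log chosen because it reproduces the rank structure PCA consumes; it is
not the fitted dispersion-based transform of the reference DE tools,
and PCA coordinates will differ in detail from theirs. The 50 most
variable features (ties broken lexicographically by feature id) are
projected onto the first three principal components (feature-centered,
full SVD, component signs fixed by making each component's
largest-magnitude loading positive, so results are machine-stable). A
sample is excluded when, on any inspected component, its score lies
strictly more than 3 standard deviations (of that component's scores)
from the component mean; a zero-variance component flags nobody.
Removal is single-pass — the rule is a gross-corruption detector, not
an iterative trimming procedure. Which components are inspected is
configurable (default 1–3).

## Negative-binomial differential expression

Counts for one feature are modelled as NB(μ_j, α) with
Var = μ + αμ², log link, and linear predictor
offset + intercept + absorbance + family1 + family2 + condition, where
the offset is the log size factor, absorbance is the hemolysis proxy
(A414, continuous), and family1/family2 encode three mutually exclusive
cohorts. The same machinery answers two questions: testing the
condition coefficient calls DEmiRs; testing the absorbance coefficient
is the hemolysis screen. Constant covariate columns are dropped with a
warning; a tested term lying in the span of the others raises a
confounding error up front.

- **Fitting** is iteratively reweighted least squares written directly
  in numpy (converged at max|Δβ| < 1e-8, cap 100 iterations; α = 0 is
  the Poisson limit; the linear predictor is clipped at ±30 to prevent
  overflow). The designs are tiny (≤ ~80 rows, 5 columns) but the fit
  count is large — hundreds of features × two models × many simulation
  replicates — so a dedicated loop is both the natural statement of the
  model and orders of magnitude faster than a generic GLM framework.
  The test suite verifies coefficients against closed forms and an
  independent GLM library at 1e-6.
- **Dispersion** is estimated per feature by maximizing the Cox–Reid
  adjusted profile likelihood (NB likelihood at the fitted means minus
  ½ log det X'WX, the correction for degrees of freedom absorbed by the
  mean model), profiled on a log scale over [1e-8, 10] and clamped to
  that bracket; underdispersed features land on the floor. The means
  are held at the fit of the *reduced* design — nuisance parameters are
  estimated under the null, score-test style. This choice is
  deliberate: with dispersion estimated under the full design, a chance
  fluctuation along the tested covariate deflates α̂ and inflates the
  test statistic for exactly the features most at risk of being false
  positives; estimating under the reduced design routes that
  fluctuation into the dispersion instead. In null simulations at the
  pipeline's scale this is the difference between sitting exactly at
  the FDR bound and controlling it with margin.
- **Testing.** The likelihood-ratio statistic 2(ℓ_full − ℓ_reduced)
  (clipped at zero) is referred to F(1, n − p) rather than χ²₁ inside
  the pipeline: the χ² reference treats the plugged-in dispersion as
  known, and at n ≈ 70 its tail is measurably anti-conservative
  (roughly 2× at the Benjamini–Hochberg boundary in our null
  simulations) — the same z-versus-t phenomenon as in ordinary linear
  models, and the reason quasi-likelihood F-tests exist. The bare χ²₁
  version remains available (`lrt_test` default) and matches its
  textbook reference values.
- **Multiplicity.** Benjamini–Hochberg step-up across exactly the
  retained feature set, significant at adjusted p < 0.05. No shrinkage
  is applied to fold changes or dispersions — per-feature estimates are
  reported as fitted, which widens per-feature variability at small n
  relative to empirical-Bayes pipelines.
- All-zero features are reported (p = 1, log2fc = 0, flagged), never
  dropped silently, and a single pathological feature cannot abort a
  run. Hemolysis-affected features are *corrected for* via the
  covariate, not excluded.

## The synthetic-data generator

The generator produces count matrices whose structure matches what the
pipeline assumes, with ground truth for recovery testing. Defaults
describe a 71-sample serum cohort.

- **Cohort**: 34 controls + 37 cases; three family cohorts (two
  half-sib families and an unrelated group) assigned in random thirds
  and encoded as binary covariates with per-feature log2 shifts
  ~N(0, 0.2).
- **Abundance phases**: 70% noise / 24% steady / 6% high by default;
  steady means log-uniform in [20, 250], high in [500, 5000] normalized
  counts. One dominant feature is scaled to hold 63% of total expected
  counts, mirroring the single overwhelming miRNA of real serum
  libraries.
- **Noise phase** — sporadic expression: each noise feature is present
  in a sample with a sample-specific occupancy probability
  ~U(0.2, 0.8) and, when present, has a mean drawn independently per
  (feature, sample) from [0.1, 5]. Presence/absence mismatches and
  occupancy differences make the across-feature distributions of noise
  features disagree between samples — precisely the signal the KS
  procedure needs. (An iid noise model without sample-level structure
  makes the phases nearly indistinguishable to the scan: the surviving
  noise features then *agree* between samples and dilute the cost
  rather than raising it.)
- **Counts**: NB via gamma–Poisson with dispersion α = 0.1 by default.
  No published dispersion estimate exists for this material; the value
  is an assumption in the typical bulk-count range, not a paper-derived
  quantity.
- **Hemolysis**: absorbance A414 is drawn from a Beta distribution
  scaled to [0.53, 4] with the shape solved so the median is 1; an
  optional latent-Gaussian copula correlates it with the condition
  label for confounding experiments (`absorbance_condition_r`). A
  configurable fraction (29%) of steady/high features receives a signed
  per-unit-absorbance log2 coefficient with magnitude U(0.5, 1.2),
  calibrated so that the default-scale hemolysis screen flags a
  fraction of retained features comparable to published serum screens
  (roughly a quarter to a third); hemolysis-responsive erythrocyte
  miRNAs show multi-fold shifts, so the range is biologically sensible.
  Hemolysis features are preferentially chosen among condition-null
  features so confounding scenarios are expressible.
- **Condition effects**: planted on a fraction (10%) of steady/high
  features only — never on noise — with signed log2FC magnitudes
  U(0.27, 0.49), the small-effect regime reported for serum DEmiRs.
- **Technical structure**: three bounded (uniform) per-sample latent
  factors with Gaussian feature loadings (sd 0.3 × [1, 0.75, 0.5] log2)
  on the signal features, plus log-normal depth factors (sd 0.3,
  geometric mean 1). The latent factors give the matrix a realistic
  leading-PCA spectrum (top components capturing tens of percent of
  variance) instead of the implausibly flat spectrum of isotropic
  noise; because the factors are bounded, clean cohorts do not produce
  chance 3-SD score outliers. All randomness flows from a single seeded
  generator; identical configs are byte-identical.

What the generator does **not** emulate: sequence content, mapping or
quantification artifacts, count correlations between related miRNAs
(family members sharing seed sequences), dispersion varying with mean,
or batch effects correlated with condition. Passing recovery tests on
these simulations therefore demonstrates the pipeline's statistical
machinery, not robustness to every pathology of real libraries.

## Validation problem sizes

The test suite exercises the primitives against brute-force and
independent-library oracles (exact agreement), and validates the
statistical behavior at deliberately moderate scale: threshold
recovery on 20 two-phase datasets (72 samples × 300 features), FDR
calibration on 50 global-null cohorts (71 × 300, hemolysis and family
covariates active), effect recovery and confounding protection on 20
planted datasets each (71 × 200), and the outlier rule on 20 clean and
20 corrupted cohorts at default scale. `scripts/acceptance.py` re-runs
the same measurements at somewhat smaller replicate counts so a full
reproduction stays under a minute.

## Known limitations

- The F(1, n−p) reference is a pragmatic finite-sample correction, not
  an exact test; at n ≲ 25 the per-feature dispersion estimates are
  noisy enough that p-values become mildly liberal despite it.
- The log2(x+1) stand-in for a fitted variance-stabilizing transform
  compresses low-count differences slightly differently than the
  reference tools; PCA outlier calls can differ near the 3-SD boundary.
- The hemolysis screen corrects linearly in absorbance; strongly
  nonlinear hemolysis responses would be only partially absorbed.
- Median-of-ratios requires at least one feature positive everywhere;
  extremely sparse matrices need pre-filtering first.
- The threshold scan's ε-rule cannot distinguish the last one or two
  noise features from the plateau — by construction it finds the point
  where noise stops being *detectable*, which is the quantity that
  matters for downstream inference.
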