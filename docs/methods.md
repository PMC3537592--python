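# Methods

## The statistic

For a trait X and metabolite concentrations M1, M2 the p-gain is

    p-gain(M1/M2 | X) = min(p(M1|X), p(M2|X)) / p(M1/M2|X),

with all three p-values from ordinary least-squares regressions of the
quantity on X (plus optional covariates). Ratios enter as natural-log
differences log M1 − log M2; single concentrations are log-transformed by
default as well (`log_transform_single=False` disables this). Because
log(a/b) = −log(b/a) merely flips the regression slope, the two orientations
of a ratio are one hypothesis: the scan counts each unordered pair once,
which also halves the multiple-testing burden. B is the number of ratio
regressions actually completed; pairs that fail (constant trait, no valid
concentrations) are reported as skipped and do not enter B.

## Log-space p-values

Observed p-gains span sixty orders of magnitude and more, so no intermediate
quantity is ever held on the linear scale. The two-sided p-value of the slope
t-statistic is computed as a log10 value directly from the log tail of the
t-distribution. For t² > ν the regularized incomplete beta is evaluated in
log space via its hypergeometric representation,

    I_x(a, 1/2) = x^a (1−x)^{1/2} / (a B(a, 1/2)) · 2F1(a + 1/2, 1; a+1; x),
    x = ν/(ν + t²),  a = ν/2,

whose 2F1 factor is O(1) and underflow-free on that branch; for t² ≤ ν the
direct tail is accurate. The two branches agree with R's
`pt(lower.tail=FALSE, log.p=TRUE)` to about 12 digits over t ∈ [0.5, 10⁴],
ν ∈ [2, 1000] (frozen reference values in the test suite). An exact fit
(zero residual) is the one case where p is identically zero under the model
and log10 p = −∞ is returned deliberately. Linear-scale accessors
(`pgain_linear`, the `pgain_linear` output column) saturate at the largest
representable double and set an explicit flag.

## The conservative null and critical values

Under the null every p-value is Uniform(0,1). In the conservative case —
numerator metabolite uncorrelated with the ratio — the p-gain is a ratio of
two independent uniforms; the ratio-of-densities convolution gives the split
density f(g) = 1/2 (g < 1), 1/(2g²) (g ≥ 1) and CDF F(g) = g/2, 1 − 1/(2g).
Setting F(g) = 1 − α/B yields the Bonferroni critical value

    g* = B/(2α),   valid when α/B ≤ 0.5  (the quantile must sit on the
                                          upper branch; enforced).

Since min(p1, p2) ≤ p1 and any correlation between a metabolite and its
ratio pulls the two p-values together, every real correlation setting is
stochastically dominated by this null: its critical values are safe
everywhere, at the price of conservatism. Critical values and tail
probabilities are exposed in log10 as well, so B up to 10¹² never overflows.
Bonferroni is the only multiplicity scheme offered, deliberately the most
conservative choice.

## Copula simulation for correlated metabolites

The exact null for a given correlation triple
(cor(M1,M2), cor(M1,ratio), cor(M2,ratio)) has no closed form and is
simulated:

1. n_samples triples of uniform margins from a **Gaussian copula** with the
   triple's 3×3 correlation matrix;
2. each margin mapped to normal scores by the rank-based inverse normal
   transformation with Blom offsets, Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks
   for ties;
3. an independent N(0,1) predictor drawn and each of the three traits
   regressed on it — the three p-values inherit the traits' correlation;
4. p-gain per replicate; n_reps replicates.

Design choices, all open in principle:

- **Copula family**: Gaussian, the standard elliptical choice when the input
  is a correlation matrix. Monotone margins make the p-gain depend on the
  copula only through the rank structure, so this is mild.
- **Blom offsets** for the normal scores (the common default in genetic
  association practice); any offset family gives the same ranks.
- **The ratio is a free third margin** — the arithmetic identity
  ratio = M1/M2 is *not* imposed. Correlations, not algebra, link the traits;
  this is what lets the degenerate setting (cor(M1,M2)=1, both
  cor(M,ratio)=0) reproduce the analytic conservative null, which the test
  suite verifies by Kolmogorov–Smirnov distance.
- **PSD handling**: settings whose implied matrix has an eigenvalue below
  −1e-8 are rejected naming the eigenvalue; eigenvalues in [−1e-8, 0) are
  clipped to 0 and the matrix rescaled to unit diagonal, so exactly singular
  settings (perfectly correlated metabolites) work.
- **Defaults** n_samples = 1000, n_reps = 100 000, seed mandatory. Because
  the slope p-value of a fixed score vector against a spherical normal
  predictor is *exactly* Uniform(0,1) at any n, the simulated p-gain null
  depends on n_samples only through negligible joint finite-n effects; the
  heavier property tests therefore run at n_samples = 250 with no loss, and
  the degenerate-case check at the default n_samples = 1000.
- **Quantiles** are linear interpolation of order statistics (type 7) on the
  log10 scale, stated so results reproduce across implementations.
  `simulated_critical_value` refuses quantiles with fewer than 10 expected
  tail exceedances and names the replicate count that would suffice.
- The simulator runs a vectorized correlation-form slope test in fixed-size
  replicate batches; it is algebraically identical to the per-call OLS path
  (asserted to 1e-10 in the tests) and bit-for-bit reproducible for a given
  seed.

## Sample-size resampling

`pgain_vs_sample_size` draws, for each requested size, n_reps bootstrap
subsamples **with replacement** from the cohort's complete cases for the pair
and recomputes the p-gain, reporting median and quartiles of log10 p-gain
(type-7 interpolation; "first and third quantile" is read as quartiles).
Defaults — sizes {100, 500, 1000, 1500, 2000}, 1500 replicates — mirror the
standard design of this diagnostic; the acceptance-level check runs 200
replicates per size, which already pins the median to within a few percent.
A `replace=False` mode exists for the identity check (a full-size permutation
reproduces the cohort's own p-gain exactly). Replicates with a degenerate
subsample (constant trait) are skipped and counted; more than 10 % skips at a
size aborts. Note the bootstrap median at a given size tracks the parent
cohort's *realized* p-gain, not the population median: under the null it
hovers near 1 only up to that cohort-level noise.

## Synthetic cohorts

The generator emulates the regime in which ratios are informative:

    G ~ Binomial(2, maf)   (Hardy–Weinberg),   u ~ N(0, shared_sd²)
    log M1 = beta1·G + u + e1,   log M2 = beta2·G + u + e2

with concentrations returned on the linear scale and the dosage G as trait.
Defaults n = 1000, maf = 0.3, beta1 = −beta2 = 0.25, shared_sd = 1,
noise_sd = 0.5: opposite-sign effects on the logs model a substrate/product
enzyme reaction whose shared component cancels in the ratio — the
internal-normalization mechanism that motivates ratio testing. With betas and
shared_sd zero it is an independent-metabolite null for calibration. At
beta = 0 the log-concentration correlation has the closed form
shared_sd²/√((shared_sd²+noise_sd1²)(shared_sd²+noise_sd2²)), checked
empirically in the tests.

What the generator does **not** emulate: measurement batch effects,
heteroscedastic platform noise, missing-not-at-random values, linkage between
SNPs, or more than two metabolites with structured correlation. Passing tests
therefore demonstrate the statistical machinery, not robustness to every
artifact of real metabolomics data.

## Problem sizes and numerical tolerances

- Degenerate-copula agreement: n_reps = 10⁵, n_samples = 1000; KS < 0.01,
  0.95 quantile within [9, 11].
- Monotonicity and conservativeness sweeps: n_reps = 10⁵ per setting,
  n_samples = 250; decreases must exceed twice the combined bootstrap SE
  (200 bootstrap resamples of the quantile).
- Brute-force uniform-ratio oracle: 10⁶ pairs; tail fraction beyond 10 within
  ±0.001 of 0.05, KS < 0.002.
- Calibration: 200 planted and 200 null cohorts at n = 1000.
- quantile∘cdf identity to 1e-10; decade-wise numerical integration of the
  density matches the CDF to 1e-8 up to g = 10⁶.

## Known limitations

- The trait is one numeric vector per run: no VCF/PLINK parsing, imputation,
  or genome-wide SNP iteration.
- No normality testing or automatic transformation selection; the log
  transform is a fixed (toggleable) choice.
- The conservative threshold is deliberately loose for highly correlated
  pairs; use the copula simulator when a pair-specific null matters.
- Covariates default to none; when supplied they enter all three regressions
  identically.
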