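# Methods

## Model

Each feature g is observed on N samples as a non-negative abundance
Y_ig with a point mass at zero. Writing delta_ig = I{Y_ig = 0} and
X_i for the Q covariates of sample i, the two parts are

    logit Pr(Y_ig = 0)      = gamma_0g + gamma_g . X_i          (zero part)
    log(Y_ig) | Y_ig > 0    = beta_g . X_i + eps_ig             (non-zero part)

with eps_ig i.i.d. from a completely unspecified density f_g. The
non-zero part is the semi-parametric accelerated failure time model:
beta_qg is the log fold change in observed non-zero abundance per unit of
covariate q. The model deliberately has **no intercept in beta**: the
location of f_g is not identifiable alongside one, so the location is
absorbed into the error distribution. A consequence used by the tests is
scale invariance — multiplying a feature's raw abundances by any positive
constant changes nothing in the estimates or p-values.

The joint likelihood factorizes into a Bernoulli likelihood for delta, a
density term for the non-zero residuals, and the Jacobian
product of 1/Y_ig over non-zero samples. The Jacobian is parameter-free
and excluded everywhere (it cancels exactly in likelihood ratios).

## Kernel-smoothed likelihood

f_g is replaced by the Gaussian-kernel density estimate of the non-zero
residuals r_i = log(Y_i) − beta.X_i:

    loglik(beta) = sum_i log[ (1/(N+ h)) sum_j K((r_j − r_i)/h) ]

with both sums over the N+ non-zero observations. Two conventions are
fixed here and asserted by tests:

- **Kernel sum over non-zero observations only.** Residuals do not exist
  at zeros; normalizing by N+ makes the density estimate proper.
- **Leave-in self term.** The j = i term is included. With h fixed before
  optimization it contributes a parameter-free floor K(0)/(N+ h) to each
  density value and does not destabilize the fit. (A leave-one-out
  variant was evaluated during development and produced slightly worse
  null calibration under normal errors.)

The objective is smooth in beta; it is maximized by BFGS with the
analytic gradient (gradient tolerance 1e-8, at most 500 iterations) from
two warm starts — beta = 0 and the least-squares slope of log Y on
(1, X) — keeping the start with the higher likelihood, ties broken by
smaller ||beta||. On small instances the optimizer agrees with an
exhaustive 1e-4 grid search of the objective to grid resolution.

## Bandwidth

    h = 1.144 * sigma_hat * N^(−1/5)

where sigma_hat is the sample standard deviation (N−1 denominator) of the
non-zero log abundances of the feature and N is the **total** sample
count including zeros (N = 2n in a balanced two-group design). h is
computed once per feature — it does not involve beta — and shared by the
full and null fits so that the likelihood-ratio comparison is a valid
nested comparison; mismatched bandwidths raise an error. Features with
fewer than two non-zero values, or constant non-zero log values, have no
usable continuous part and fall back to the zero part alone.

The 1.144 multiplier is exposed (`bandwidth_scale`) but the default is
the rule above. Calibration of the resulting test is sensitive to this
scale at moderate N: smaller h makes the non-zero LRT anti-conservative,
larger h conservative (see Limitations).

## Zero part and separation

The logistic zero part is fitted by Newton iteration with step-halving.
When the likelihood is monotone (complete or quasi-complete separation —
e.g. one group entirely non-zero) the MLE diverges; the fit is then
recomputed under a |coefficient| <= 15 box, flagged `separated`, and its
(finite) likelihood still contributes to the LRT. Features with no zeros
at all drop the zero part entirely and are tested on 1 df; features that
are all zeros are skipped. The per-feature mode is:

| mode          | zero part | non-zero part | df |
|---------------|-----------|---------------|----|
| both_parts    | yes       | yes           | 2  |
| nonzero_only  | —         | yes           | 1  |
| zero_only     | yes       | —             | 1  |
| skipped       | —         | —             | —  |

## Test and multiplicity

LRT_g = −2 (loglik_null − loglik_full), where the null refits **both**
parts with the tested covariate removed (other covariates retained) at
the same h. Values in (−1e-6, 0) are clipped to zero; anything more
negative indicates a broken nested comparison and raises. The p-value is
the chi-square upper tail at the mode's df.

Storey q-values: pi0 is estimated from pi0(lambda) = #{p > lambda} /
(m (1 − lambda)) on the grid lambda = 0.05, 0.10, …, 0.95, smoothed by a
cubic least-squares fit (standing in for the customary df-3 smoothing
spline) evaluated at lambda = 0.95 and clipped to (0, 1]; with fewer than
10 p-values pi0 falls back to 1 (pure Benjamini–Hochberg). Skipped
features carry missing p-values, are excluded from m, and receive missing
q-values.

## Baselines

Two-part t (2T) and two-part Wilcoxon (2W): B is the pooled two-proportion
z statistic on zero counts (0 when the pooled zero fraction is 0 or 1);
the continuous statistic is a Welch t on log non-zero values (2T) or a
rank-sum z with tie-corrected variance and no continuity correction (2W);
X² = B² + T² (or Z²) is referred to chi-square with df = number of
informative parts. Welch rather than pooled-variance t, and the
no-continuity-correction z, were chosen to keep X² chi-square calibrated;
degenerate reductions mirror the main test's mode logic so the methods
are comparable feature by feature.

## Simulation engine

Per feature: a zero proportion p ~ Uniform(0, 0.8); each of the 2n
observations is zero with probability p, otherwise exp(draw) from a
log-abundance source. A configured fraction of features is differential:
the non-zero part of group 1 (coded 1) is multiplied by exp(effect),
default effect log 2, one direction for all differential features.
Scenario 2 adds detection-limit censoring: per feature, non-zero values
below the 10th percentile of the combined non-zero values are set to
zero — so pre-existing zeros (absence) are retained and low measurements
become zeros, and differential features end up with unequal zero counts
between groups.

Sources:

- `lognormal` — log-abundance N(5, 1): the normal-errors reference case.
- `skewed` — log-abundance 3 + Gamma(shape 2, scale 1) (skewness ≈ 1.4,
  mean 5): a deliberately hard right-skewed case emulating heavy-tailed
  MS features.
- `empirical_sampler(reference)` — resamples non-zero log values of a
  randomly chosen feature (≥ 20 non-zero values) from any user-supplied
  matrix, feature by feature.

The location/scale (log-abundance around 5, unit scale) are arbitrary
units; all methods in the package are invariant to them. What the
generator does **not** emulate: correlation between features, multi-level
or continuous covariate designs, batch structure, and the exact shapes of
real MS intensity distributions — passing benchmarks here demonstrates
correctness of the machinery and qualitative behavior (calibration,
ordering of methods), not performance numbers transferable to any real
dataset.

## Evaluation metrics

TPR at top-k (ties broken by stable feature order — documented because
the value depends on it), Mann–Whitney AUC with half-credit for ties,
realized-vs-reported FDR at q cutoffs (empty discovery sets record FDR 0
with a flag rather than NaN), discovery counts, and the Shapiro–Wilk
screen on per-group log non-zero values (alpha 0.01; groups with < 3
non-zero values are not flaggable).

## Problem sizes used in the shipped checks

The statistical checks run at desk scale chosen to make the suite a
routine run: single-feature null studies use 2000 replicates at n = 50
per group; effect recovery uses 200 features at n = 100; the FDR and
power comparisons use 20 replicates of 500 features at n = 50 (10%
differential, skewed source). These sizes give Monte-Carlo standard
errors small enough for the stated tolerances.

## Limitations

- At moderate sample sizes the chi-square reference for the
  kernel-smoothed LRT is approximate, and the quality of the
  approximation depends on the error distribution through the bandwidth
  rule: with h = 1.144 sigma N^(−1/5), the non-zero part is mildly
  anti-conservative under normal errors at N ≈ 100 (rejection ≈ 0.06 at
  nominal 0.05) and conservative under strongly right-skewed errors
  (≈ 0.03), where the sd-based rule over-smooths. The shipped `skewed`
  source is deliberately harder than typical MS data, where only a
  minority of features are markedly non-normal; expect overall type-I
  error near, but not exactly at, the nominal level at these sample
  sizes.
- Standard errors and confidence intervals for gamma and beta are not
  provided (the screen reports estimates and q-values).
- Independent samples only; paired designs would need random effects in
  both parts.
- Missing values distinct from zeros are not supported: a zero is data.
- Input tables are expected to be already normalized; no normalization is
  performed.
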