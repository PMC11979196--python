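# Methods

## Model and estimation

A measurement model relates `k` observed indicators to `m` latent
factors through `Sigma(theta) = Lambda Phi Lambda' + Theta`, with
`Lambda` the (simple-structure) loading matrix, `Phi` the factor
covariance matrix and `Theta` a diagonal matrix of uniquenesses.
Cross-loadings, residual covariances, regressions among latents, mean
structures and multi-group models are not supported; the parser rejects
them with explicit errors.

Two fit-equivalent identifications are offered. The default fixes all
factor variances at 1 (every loading free); `first_loading_fixed` fixes
the first loading of each factor at 1 and frees the variance. Both give
the same number of free parameters and the same minimized discrepancy.

**Continuous indicators.** The sample covariance matrix `S` uses
divisor `N` by default — the biased form that normal-theory ML assumes —
with `N-1` available. Discrepancy functions:

- ML: `F = log|Sigma| + tr(S Sigma^-1) − log|S| − k`
- GLS: `F = 1/2 tr[(I − Sigma S^-1)^2]`

**Ordered-categorical indicators** (delta parameterization): the data
are summarized by two-step polychoric moments. Thresholds come from
inverse-normal cumulative margins, `tau_c = Phi^-1(P(X <= c))`; each
pairwise correlation maximizes the bivariate-normal likelihood of the
two-way table with thresholds held fixed (bounded scalar search on
(−0.9999, 0.9999)). The assembled matrix is smoothed to the nearest
positive-semidefinite matrix (eigenvalues clipped at 1e-8) when
necessary, and smoothing is logged. The model is fitted to the moment
vector `s = (lower-triangle correlations, thresholds)` by
`F = (s − sigma(theta))' W^-1 (s − sigma(theta))` with

- ULS: `W = I`
- DWLS: `W = diag(Gamma)`
- WLS: `W = Gamma` (full; guarded to `k <= 25` because the matrix
  grows quadratically in the number of moments)

where `Gamma` is the asymptotic covariance of `sqrt(N)` times the
moment vector, estimated from per-case influence functions: the
delta-method form `(1{x<=c} − P_c) / phi(tau_c)` for thresholds, and
score-over-information with thresholds fixed for each correlation
(using the identity `dPhi2(a,b;rho)/drho = phi2(a,b;rho)` for the cell
derivatives). Uniquenesses are not free under the delta convention;
they are derived so the implied latent-response variances equal 1.
The plain ULS/DWLS/WLS test statistics are reported;
mean-and-variance-adjusted statistics (the "MV" variants) and robust ML
scaling are deliberately not implemented — requesting them is not
supported rather than silently approximated.

The chi-square statistic is `multiplier × F_min` with multiplier `N`
(default) or `N−1`. For df = 0 the statistic is reported as 0 with
p = 1. The ML log-likelihood (used only by AIC/BIC) is
`−N/2 (k log 2π + log|Sigma| + tr(S Sigma^-1))`.

**Optimization.** L-BFGS-B with analytic gradients throughout, derived
from `dF/dSigma`: for ML `Sigma^-1 (Sigma − S) Sigma^-1`, for GLS
`S^-1 (Sigma − S) S^-1`, and for weighted least squares the weighted
residual mapped back through the Jacobian of `Sigma(theta)` (thresholds
enter the moment vector identically). Start values: loadings at 0.7 of
the indicator SD, uniquenesses at 0.51 of the variance, factor
covariances at 0, thresholds at their sample values. On
non-convergence the starts are perturbed multiplicatively (seeded; up
to 5 restarts). Convergence tolerances: `ftol 1e-12`, projected-gradient
`1e-8`, 500 iterations.

**Degenerate inputs and protection.** Uniquenesses are bounded below
at `1e-4` times the indicator's sample variance (exactly `1e-4` in the
correlation metric); a binding bound is flagged as a Heywood case, and
for ordinal models the same effect is achieved by capping `|loading| <=
sqrt(1 − 1e-4)` under unit factor variances. A non-positive-definite
implied matrix during the search receives a large penalty (the search
recovers or the fit is flagged non-convergent); a singular sample
matrix is a hard error. Constant columns, single-category columns and
fewer than `k+1` complete cases are rejected with named-column errors.

## Fit indices

With baseline (independence) model `chi_B`, `df_B = k(k−1)/2`
(continuous baseline: `Sigma_B = diag(S)`, closed form
`F_B = sum log s_ii − log|S|`; GLS baseline: the diagonal solving
`(S^-1 ∘ S^-1) d = diag(S^-1)`; polychoric baseline: zero correlations
with thresholds at sample values):

- GFI (ML/GLS): `1 − tr[(Sigma^-1 S − I)^2] / tr[(Sigma^-1 S)^2]`;
  least-squares form on correlations: `1 − tr[(S − Sigma)^2] / tr[S^2]`.
  Which generalization a categorical fit should use is not settled; the
  least-squares form is used and flagged here.
- AGFI: `1 − [k(k+1)/(2 df)](1 − GFI)`, absent at df = 0.
- **CGFI**: `GFI + 2(1 − 2 df/(k(k+1)))/N`, algebraically equal to
  `GFI + 4p/(k(k+1)N)` through the identity `df = k(k+1)/2 − p`. An
  alternative typeset form of the correction circulating as
  `(k(k+1)/p)·(1/N)` is inconsistent with the published worked examples
  (it would give 0.966, not 0.950, for GFI 0.945, k 7, p 14, N 193);
  the df-based form above reproduces both examples exactly and is
  treated as normative. Values above 1 (possible for tiny N with
  near-saturated models) are capped at 1 with a logged note. For
  ordinal models the df in the correction is the model's own df in the
  correlation+threshold metric; the parameter-count convention can
  diverge from the covariance-metric count for other models, and the
  correlation+threshold convention is the one adopted.
- CFI: `1 − max(chi_T − df_T, 0)/max(chi_B − df_B, chi_T − df_T, 0)`;
  TLI: `[(chi_B/df_B) − (chi_T/df_T)]/[(chi_B/df_B) − 1]`, reported
  unclipped; when the baseline fits (`chi_B <= df_B`), CFI is 1 and TLI
  is reported absent.
- RMSEA: `sqrt(max(chi − df, 0)/(df · N))` (denominator `N`, matching
  the chi-square multiplier convention; absent at df = 0).
- SRMR: residuals standardized by the sample standard deviations
  (Bentler's convention), root mean square over the `k(k+1)/2`
  lower-triangle cells including the diagonal; in the correlation
  metric diagonal residuals are identically zero.
- AIC/BIC: `−2 loglik + 2p` and `−2 loglik + p log N`; absent (rendered
  `NA`) for every non-ML estimator.

Reports print 3 decimals; machine outputs keep full precision.

## Bootstrap

Non-parametric case resampling: each of `B` replicates draws
`n_rows_raw` rows with replacement from the raw table, applies listwise
deletion *within* the replicate (the resampling unit is the observed
case, including its missingness), recomputes moments, refits target and
baseline warm-started from the original estimates, and evaluates all
indices. Failed replicates (non-convergence, degenerate moments, too
few complete cases) are dropped from the summaries and counted; they
are not retried, because retrying would bias the distribution toward
easy resamples. If more than half fail the result is flagged unstable.
Summaries per index: mean, SD (divisor `B_success − 1`) and the 2.5th /
97.5th empirical percentiles under the median-unbiased (Hyndman–Fan
type 8) quantile definition. The upper column is labeled `CI_97.5`
(the quantile), with `CI_95` accepted as an alias naming the interval.

One master seed spawns an independent substream per replicate
(`numpy` `SeedSequence.spawn`), so results are reproducible and
independent of execution order. Percentile (not BCa or Bollen–Stine)
intervals are the only interval type offered.

## Synthetic data

The generator draws zero-mean multivariate-normal data from
`Sigma0 = Lambda Phi Lambda' + Theta` and, for ordinal designs,
discretizes at fixed thresholds into categories `1..C`; MCAR
missingness can be injected at a configurable cell rate. Two default
scenarios fix the study conditions used across the tests: a 7-item
one-factor scale with standardized loadings 0.7 at N = 193 (the
small-sample regime where the CGFI correction is visible), and a
14-item, 4-category scale with loadings 0.65, right-skewed margins
(thresholds −0.25, 0.6, 1.2) at N = 4540. The generator produces
exactly multivariate-normal latent responses with simple structure and
MCAR missingness only; real questionnaire data are non-normal,
locally dependent and rarely missing at random, so passing tests
demonstrate correctness of the machinery under the model's own
assumptions, not robustness to their violation.

Monte-Carlo problem sizes used by the test suite: 500 replicates at
N = 200 for chi-square calibration; N = 100000 for parameter-recovery
and large-sample reference fits; N = 2000 for polychoric recovery;
B = 1000 for bootstrap determinism; 100 datasets (N = 500, B = 200)
for interval-coverage calibration — sizes chosen so the whole suite
runs in a couple of minutes on one core thanks to the analytic-gradient
fits.

## Known limitations

- Robust ("MV"-adjusted) categorical test statistics and robust ML are
  not implemented; comparisons with software defaulting to WLSMV/MLR
  will differ in chi-square, CFI/TLI and RMSEA.
- Missing data are handled by listwise deletion only (no FIML); the
  deletion count is logged.
- Percentile bootstrap intervals inherit the bias of the underlying
  index: for a downward-biased index such as the GFI the interval sits
  below the large-sample value, so these intervals quantify sampling
  variability rather than delivering calibrated frequentist coverage of
  a population index; the suite's coverage check documents exactly this
  behaviour.
- The GFI generalization used under ULS/DWLS/WLS is a documented
  choice, not a standard; AGFI and CGFI inherit it.
- Standard errors of the parameter estimates are out of scope: the
  engine reports fit, and uncertainty is delivered by the bootstrap.
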