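# Methods

## Model

The package models the natural log of the total radiocesium activity
concentration (Bq/kg) in animal tissue, decay-corrected to the collection
date, as

    LnCs_c(T) = X(T) + Q − μ·T^ν + A·sin(2π(T + P)) + ε

with `X(T) = ln[exp(i134)·2^(−T/Th134) + exp(i137)·2^(−T/Th137)]` the known
environment offset from pure physical decay of the two isotopes.
Assumptions: the oscillation period is fixed at one year; both isotopes share
the ecological and seasonal dynamics; the environment intercepts (i134, i137)
are estimated separately (robust ln-linear regression of per-isotope
monitoring activities on T, per species) and treated as known during burden
fitting; errors are additive on the ln scale.

Parameters, units and defaults:

| parameter | units | meaning | notes |
|---|---|---|---|
| Q | ln[m²/Bq] | tissue burden relative to deposition | unconstrained |
| μ | 1/y | ecological loss rate | half-life = ln2/μ; ∞ reported when μ ≤ 0 |
| ν | — | power of the time dependence | fixed 1 or 2, or free in [0.1, 10] |
| A | ln[Bq/kg] | seasonal amplitude | canonical A ≥ 0 |
| P | y | seasonal phase | canonical P ∈ [0, 1); peak at (0.25 − P) mod 1 |
| Th134, Th137 | y | physical half-lives | 2.0652 / 30.08 (standard nuclide data) |

Canonicalisation: A·sin(2π(T+P)) is invariant under (A, P) → (−A, P+½) and
P → P+1; every result is reported with A ≥ 0, P ∈ [0, 1).

Two seasonal summaries are emitted, clearly labelled, because both are in
use: the **amplitude factor** exp(A) (the multiplicative swing from the
mid-line to the seasonal peak) and the **peak-to-trough fold** exp(2A).
Phase is reported as 12·P months with a plain delta-method CI; no circular
statistics machinery is used since the period is fixed and phase
uncertainties are small relative to the period.

## Estimation

**Linearisation.** For fixed ν the model is linear in (Q, −μ, a, b) on the
covariates (1, T^ν, sin 2πT, cos 2πT), with a = A·cos 2πP, b = A·sin 2πP.
Canonical estimates and their covariance follow by the smooth reparameterisation
A = √(a²+b²), P = atan2(b, a)/2π and its Jacobian. Only the free-ν variant is
genuinely nonlinear.

**OLS.** Multi-start nonlinear least squares in canonical parameters;
initial values come from the linearised solution (for free ν, a coarse
profile scan over ν), perturbed multiplicatively by N(1, 0.1²) per restart;
the minimum-RMSE restart wins. Default 2000 restarts (production profile),
reducible for exploration. For fixed ν the closed-form linearised solution is
always computed alongside and any disagreement beyond 1e-4 triggers a
warning; the validation suite requires agreement to 1e-6.

**Robust.** M-estimation by IRLS with a MAD residual scale
(median|r|/0.6745) and Huber ψ (tuning 1.345) by default; Tukey bisquare
(4.685) is available. Fixed-ν fits delegate to statsmodels' RLM on the
linearised design (identical IRLS, mature covariance estimator); the free-ν
variant uses the in-package multi-start IRLS whose restart winner is the one
with the smallest |median residual|, and the two routes are cross-checked in
the tests. Robustness weights, the robust scale, and the median residual are
reported per fit. Note the Huber ψ only *bounds* the influence of outliers;
the redescending bisquare rejects them, which matters under heavy one-sided
contamination (used for the isotope-intercept estimator for exactly that
reason).

**Quantile.** Pinball-loss fits at τ = 0.25/0.5/0.75. Fixed-ν variants are
solved with statsmodels' QuantReg on the linearised design (a convex
problem; no restarts needed). The free-ν variant minimises the pinball loss
directly (Nelder–Mead) from the robust-fit parameters. Standard errors come
from a nonparametric bootstrap (500 resamples by default; seeded), with
phase draws unwrapped to the branch nearest the point estimate before taking
moments. The 5th/95th percentiles are deliberately not offered — too little
data lives in those tails for stable fits.

**Model comparison.** AIC uses the full Gaussian least-squares form
n·(ln(2π·RSS/n)+1) + 2(k+1), counting the error variance, so deltas match
any standard statistical software.

**Mixed effects.** The ν=1 model in linearised form is fitted by maximum
likelihood (ML, not REML, so likelihoods of different random structures are
comparable) with:

* independent Gaussian district random effects on a chosen subset of
  {Q, μ, A, P}; the seasonal pair enters through its (a, b) coefficients and
  district SDs for A and P are recovered by the delta method — an
  approximation, flagged in the output;
* optionally a nested random intercept per municipality within district;
* optionally a separate residual variance multiplier per district
  (varIdent-style heteroscedasticity; the first district in alphabetical
  order is the reference).

The marginal likelihood factorises over districts; each block is evaluated
with the Woodbury identity from precomputed cross-products, so one
evaluation costs O(q³) per district independent of the number of records.
Fixed effects are profiled out by GLS; the remaining variance parameters are
optimised on the log scale by L-BFGS-B with bounds log-SD ∈ [−8, 4]. A
random term whose SD collapses to the boundary is treated as singular,
dropped with a warning, and the model is refitted. Random-effect
realisations (BLUPs) are conditional modes. R² = 1 − RSS/TSS and RMSE are
evaluated on the *full* (pre-outlier-screen) data with BLUP-inclusive
predictions; this definition is frozen in the tests. Structure comparison
reports log-likelihood, AIC, and likelihood-ratio p-values where structures
are nested; the preferred structure is the converged fit with the best AIC
among those passing a weak residual-normality screen.

**Outlier screening.** Before mixed-effects fitting, records are screened by
robust Mahalanobis distance on (T, LnCs_c) from a minimum-covariance-
determinant scatter fit, flagging squared distances above the χ²₂ 0.975
quantile. A verbatim exclusion-list mode exists for externally published
lists.

**Extrapolation scoring.** The temporal holdout places records with T at or
below the sample median in the training set (this median rule reproduces the
published split boundaries of the motivating data). The score is the ratio
of the test-set RMSE of the train-only fit to the test-set RMSE of the fit
to all data. Parameter train/full ratios carry first-order propagated SEs
that ignore the train/full covariance (the two fits share data), an
upper-bound-flavoured approximation flagged in the output. A seeded uniform
random split is available as a sensitivity variant.

**Chernobyl arm.** Zone/year summaries are analysed by weighted linear
regression of the deposition-normalised log mean burden on Time and Zone
(Alienation as reference level), with weights n/(ln max − ln min)²
normalised to mean 1 — approximately inverse-variance. All formulas obeying
marginality over {Time, Zone, Time:Zone} are ranked by AICc (k counts the
error variance; models with n ≤ k+1 are skipped with a warning) and combined
by full-model-set averaging: absent terms contribute zero, unconditional
SEs follow Burnham–Anderson (Σᵢ wᵢ√(varᵢ + (βᵢ−β̄)²)), importance is the
summed Akaike weight of models containing the term. The ecological decline
rate is defined as the negative of the Time slope; the half-life ln2/rate is
reported as ∞ whenever the rate's CI crosses zero, and a sign-agnostic
ln2/|coef| value is also emitted, labelled, for comparison with summaries
that quote only magnitudes. Conditional (subset) averaging is not the
default because full-set averaging is the convention that reconciles a
weakly supported Time term with a long averaged half-life.

## Synthetic data generator

`generate_fukushima` emulates: log-normal individual burdens spanning orders
of magnitude; district random effects (defaults: SD 0.584 on Q, 0.105 on μ,
0.256 on A — the mixed-model scale of the boar data); nested municipality
intercepts; per-district residual SDs heterogeneous around 1 (variance
homogeneity is clearly rejected in the real monitoring data); sampling times
uniform on 0.2–7.03 y; per-isotope activities split by the 1:1 release ratio
and physically decayed over uniform 0–3 month measurement delays, so the
ingest/decay-correction path is exercised end to end; below-detection
censoring at 10 Bq/kg on the linear scale; and 3% gross outliers
(the outlier screen on the real boar data removed ~3%).

Two outlier modes exist. `symmetric` (default) adds ±N(0, 3) shifts — enough
to exercise robust and quantile machinery. `late_high` plants strictly
positive gross shifts among late-time animals, emulating the persistently
contaminated individuals documented in European boar populations; this mode
is the one used in the robust-vs-OLS contamination experiments, because
symmetric contamination merely inflates OLS variance (roughly independent
zero-mean noise on the estimate, so the robust fit wins at most ~75% of
head-to-head comparisons no matter how gross the outliers), whereas
late-time one-sided contamination biases the OLS loss-rate estimate — the
failure mode robust regression exists to prevent.

What the generator does **not** emulate: age/sex structure, home-range
movement, non-sinusoidal seasonality (e.g. bear hibernation truncation),
serial correlation within municipalities over time, and reporting artefacts.
Passing recovery tests on these synthetics therefore demonstrates correctness
of the estimation machinery under the stated data-generating process, not
fidelity of that process to any particular monitoring data set.

`generate_chernobyl` draws a handful of log-normal individual burdens per
zone-year cell around zone offset − rate·time and reduces each cell to
(n, ln mean, ln min, ln max); the ground-truth Time slope of the ln-mean
response is −rate (the log-normal mean offset σ²/2 is constant across cells
and moves only the intercepts).

## Validation experiment sizes and calibration facts

The validation suite (and `scripts/acceptance.py`) uses: 50 random fixtures
of n = 200 for optimiser-oracle agreement; 200 replicates of n = 1404 for CI
coverage; 100 replicates of n = 1000 for the contamination comparison; 500
random draws for decay round trips; 100 paired seeds of n = 600 for
extrapolation; 100 seeds for the Chernobyl arm — sizes chosen so the whole
suite completes in well under a minute per experiment while keeping binomial
noise on reported fractions near ±2–5%.

For the misspecification contrast, the ν=2 truth uses μ₂ = μ₁/T_max so the
*total* decline over the observation window matches the ν=1 truth and
curvature is the only difference between the scenarios.

One calibration fact worth stating explicitly: for any estimator with
honestly calibrated standard errors, a ±1-SE band around the truth captures
the estimate with probability ≈0.68 (and the noisy range-based Chernobyl
weights push the measured rate slightly below that), while a ±2-SE band
reaches ≈0.95. The validation suite reports both rates for the Chernobyl
slope; only the 2-SE rate can be expected to approach high coverage.

## Numerical choices and degenerate inputs

* ν is bounded to [0.1, 10]; the upper bound is for conditioning only.
* Phase arithmetic is modulo 1 everywhere; `(−tiny) mod 1` is mapped to 0.
* IRLS stops when parameters move < 1e-10 or after 50 iterations (flagged,
  best iterate returned); nonlinear least squares uses xtol/ftol/gtol 1e-14.
* Quantile bootstrap failures on degenerate resamples are skipped; the
  effective resample count is reported.
* Zero ln-range in a Chernobyl record (infinite weight) is an error naming
  the record; identical values within all districts make the
  variance-homogeneity test degenerate and raise.
* The degenerate by-time split with threshold ≥ max(T) returns
  train = test = full data (ratio exactly 1), used as a self-check; all other
  empty split sides raise.
* Dates accept ISO 8601 and `YYYY/MM/DD`; anything else — in particular
  ambiguous `DD/MM/YYYY`-style strings — is an error carrying the row index.
* Time is converted at exactly 365.25 days/year from the 2011-03-11 origin.
* Decay correction prefers per-record isotope pairs; when absent, the
  134:137 split at collection is inferred from the configurable 1:1 release
  ratio decayed from the accident date. Both paths are exact inverses of
  forward decay (round trips hold to 1e-10 relative).

## Known limitations

* Robust-fit SEs assume the M-estimation asymptotics of the linearised
  design; with strong unmodelled clustering (district effects in truth but
  not in the fit) all fixed-effects SEs are optimistic — use the mixed model.
* The diagonal random-effects covariance cannot express correlation between
  district-level Q and μ deviations.
* Municipality effects are intercept-only.
* Quantile fits can cross outside the observed T range; crossing is flagged
  by the monotonicity check at the mean T only.
* The Chernobyl arm inherits everything a weighted regression on published
  summary statistics inherits: no seasonality, no within-cell information
  beyond (n, mean, min, max), and weights that are only approximately
  inverse variance.
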