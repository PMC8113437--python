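# csburden

Quantitative modelling of radiocesium (¹³⁴Cs + ¹³⁷Cs) burdens in large
omnivorous wild mammals — wild boar (*Sus scrofa*) and Asian black bear
(*Ursus thibetanus*) — after a nuclear accident.

After the 2011 Fukushima Daiichi accident, tissue activity concentrations in
hunted boar and bears were monitored for years. Burdens span orders of
magnitude between individuals, oscillate with the seasons (winter diets rely
on soil-associated, cesium-rich food), and decline over time through both
physical decay and *ecological* processes (cesium migration into deeper soil,
decontamination, changing bioavailability). This package provides the model
and estimation machinery to quantify those components — for radioecologists,
and for anyone assessing human exposure through consumption of game meat.

## The model

The decay-corrected log burden at time `T` (years since the accident) is

    LnCs_c(T) = X(T) + Q − μ·T^ν + A·sin(2π(T + P))

with the environment term driven purely by two-isotope physical decay:

    X(T) = ln[ exp(LnCs134_t0)·2^(−T/Th134) + exp(LnCs137_t0)·2^(−T/Th137) ]

* `Q` (ln[m²/Bq]) — tissue concentration relative to environmental deposition;
* `μ` (1/y) — net **ecological loss rate**; the ecological half-life is ln2/μ;
* `ν` — power of the time dependence (1 = exponential loss; also 2 and free);
* `A`, `P` — amplitude (ln Bq/kg) and phase (fraction of a year) of the
  seasonal sinusoid; `exp(A)` is the seasonal amplitude factor, `12·P` the
  phase in months.

Estimation methods, all exposed through `BurdenModel.fit()` /
`MixedBurdenModel.fit()` results objects:

* multi-start nonlinear OLS (min-RMSE restart wins; for fixed ν the
  closed-form linearised solution is the built-in oracle),
* robust M-regression (IRLS, Huber/bisquare; restart winner by smallest
  |median residual|),
* nonlinear quantile regression (pinball loss, 25th/50th/75th percentiles,
  bootstrap SEs),
* mixed-effects ML with district (and municipality) random effects and
  per-district residual variances,
* temporal-holdout extrapolation scoring (test RMSE of the train-only fit
  over test RMSE of the full fit),
* a weighted-regression + AICc multimodel-inference arm for Chernobyl-style
  zone/year summary data.

A synthetic-data generator (`generate_fukushima`, `generate_chernobyl`)
emulates the monitoring-data structure — log-normal burdens, district
effects, heteroscedastic noise, seasonality, measurement delays,
below-detection censoring, gross outliers — so the whole pipeline is testable
with known ground truth.

## Worked example

```python
import csburden as cb

cfg = cb.SimulationConfig(seed=11)          # study-scale synthetic data set
records, truth = cb.generate_fukushima(cfg)
analysis = records[~records["below_detection"]]

model = cb.BurdenModel(analysis, cfg.env, variant="nu1")
result = model.fit_robust()
print(result.summary())
```

prints

```
Burden model fit (robust, variant=nu1)
  nobs = 1402, RMSE = 1.2616 ln(Bq/kg), AIC = 4640.4
  converged = True, restarts used = 1
  parameter   estimate       se
  Q             -4.6662    0.0700
  mu             0.1878    0.0172
  A              0.6883    0.0466
  P              0.3992    0.0111
  ecological half-life = 3.690 y (95% CI 3.129, 4.496)
  seasonal amplitude exp(A) = 1.990, phase = 4.791 months
```

Reading: burdens in this synthetic population decline with an ecological
half-life of ~3.7 years on top of physical decay; seasonal swings are
~2.0-fold in amplitude (≈4-fold peak to trough), peaking in winter (phase
≈4.8 months shifts the sinusoid so its maximum falls ~10 months after the
March anniversary). The generating values were μ = 0.173 (half-life 4.0 y),
A = 0.641, P = 0.405; the realised district effects of this single draw move
the estimates within their uncertainties.

The same analyses are scriptable from the shell:

```sh
csburden simulate --seed 7 --n-samples 1404 --out runs/sim
csburden fit --input runs/sim/samples_supplementary.csv --out runs/fit
csburden mixed --input runs/sim/samples_supplementary.csv --out runs/mixed
csburden extrapolate --input runs/sim/samples_supplementary.csv --out runs/ext
csburden chernobyl --input runs/sim/chernobyl_summaries.csv --recompute-weights --out runs/ch
```

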