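"""End-to-end validation experiments on synthetic data with known truth.

Each function generates data with the :mod:`csburden.simulate` machinery,
runs the estimation pipeline, and measures how well it recovers the
generating conditions.  They back both the acceptance test suite and the
``scripts/acceptance.py`` reporting script.

Study-scale conditions are used throughout: n = 1404 records over 0.2-7 y,
ln-scale noise SD 1, truth (Q, mu, A, P) = (-4.85, 0.17, 0.64, 0.40).
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .chernobyl import ChernobylModel, compute_weights
from .extrapolate import SplitSpec, score_extrapolation
from .fixed import BurdenModel
from .mixed import MixedBurdenModel, detect_outliers
from .model import ModelParameters
from .simulate import (
    ChernobylSimConfig,
    SimulationConfig,
    generate_chernobyl,
    generate_fukushima,
)

__all__ = [
    "STUDY_TRUTH",
    "ols_oracle_gap",
    "robust_ci_coverage",
    "contamination_experiment",
    "decay_roundtrip_error",
    "extrapolation_experiment",
    "chernobyl_experiment",
    "golden_run",
]

#: Central study-scale generating parameters.
STUDY_TRUTH = ModelParameters(q=-4.85, mu=0.17, amplitude=0.64, phase=0.40)


def _clean_config(seed, n=1404, truth=STUDY_TRUTH, noise=1.0, **overrides):
    kw = dict(
        seed=seed, n_samples=n, truth=truth,
        district_sd={"Q": 0.0, "mu": 0.0, "A": 0.0, "P": 0.0},
        municipality_sd={"Q": 0.0},
        noise_sd_by_district=(noise,) * 7,
        outlier_fraction=0.0,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def _circular_gap(p1: float, p2: float) -> float:
    d = abs(p1 - p2) % 1.0
    return min(d, 1.0 - d)


def _seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(master_seed).integers(0, 2**31, size=n)


def ols_oracle_gap(n_fixtures: int = 50, n: int = 200, seed: int = 0,
                   n_restarts: int = 8) -> float:
    """Max per-parameter gap between multi-start nonlinear OLS and the
    closed-form linearised solution over random nu=1 fixtures."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        truth = ModelParameters(
            q=rng.uniform(-7, -3), mu=rng.uniform(0.05, 0.4),
            amplitude=rng.uniform(0.2, 1.0), phase=rng.uniform(0, 1),
        )
        cfg = _clean_config(int(rng.integers(2**31)), n=n, truth=truth, noise=0.5)
        rec, _ = generate_fukushima(cfg)
        res = BurdenModel(rec, cfg.env).fit_ols(
            engine="multistart", n_restarts=n_restarts, seed=int(rng.integers(2**31))
        )
        a, b = res.params, res.linearized
        gap = max(abs(a.q - b.q), abs(a.mu - b.mu),
                  abs(a.amplitude - b.amplitude), _circular_gap(a.phase, b.phase))
        worst = max(worst, gap)
    return worst


def robust_ci_coverage(n_reps: int = 200, seed: int = 0) -> dict:
    """Coverage of robust-fit 95% Wald CIs for (Q, mu, A, P) under
    study-scale clean conditions."""
    hits = np.zeros(4)
    truth_vals = STUDY_TRUTH.as_array()
    for s in _seeds(seed, n_reps):
        cfg = _clean_config(int(s))
        rec, _ = generate_fukushima(cfg)
        res = BurdenModel(rec, cfg.env).fit_robust()
        est = res.params.as_array()
        for j, name in enumerate(("Q", "mu", "A", "P")):
            err = _circular_gap(est[3], truth_vals[3]) if name == "P" else abs(est[j] - truth_vals[j])
            hits[j] += err <= 1.96 * res.se[name]
    return {name: float(h / n_reps) for name, h in zip(("Q", "mu", "A", "P"), hits)}


def contamination_experiment(n_reps: int = 100, seed: int = 0,
                             outlier_fraction: float = 0.10) -> float:
    """Fraction of replicates where the robust fit's mu error beats OLS under
    gross late-time contamination (persistently high individuals)."""
    wins = 0
    for s in _seeds(seed, n_reps):
        cfg = _clean_config(int(s), n=1000, outlier_fraction=outlier_fraction,
                            outlier_shift_sd=3.0, outlier_mode="late_high")
        rec, _ = generate_fukushima(cfg)
        m = BurdenModel(rec, cfg.env)
        err_rob = abs(m.fit_robust().params.mu - STUDY_TRUTH.mu)
        err_ols = abs(m.fit_ols().params.mu - STUDY_TRUTH.mu)
        wins += err_rob < err_ols
    return wins / n_reps


def decay_roundtrip_error(n_draws: int = 500, seed: int = 0) -> float:
    """Max relative error of forward-decay -> back-correction round trips
    over random isotope mixes and delays up to 5 years."""
    from .ingest import correct_decay, forward_decay_total

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        total = float(rng.uniform(1.0, 1e6))
        t_coll = float(rng.uniform(0.0, 7.0))
        delta = float(rng.uniform(0.0, 5.0))
        f134 = float(rng.uniform(0.0, 1.0))
        a134, a137 = forward_decay_total(total, t_coll, t_coll + delta,
                                         fraction_cs134_at_collection=f134)
        ln = correct_decay(a134 + a137, t_coll, t_coll + delta,
                           cs134=a134 or None, cs137=a137 or None)
        worst = max(worst, abs(math.exp(ln) - total) / total)
    return worst


def extrapolation_experiment(n_seeds: int = 100, seed: int = 0, n: int = 600) -> dict:
    """Temporal-holdout RMSE ratios: well-specified (nu = 1 truth, nu = 1
    fit) versus misspecified curvature (nu = 2 truth with the same total
    decline over the window, still fitted with nu = 1)."""
    t_max = 7.03
    truth_nu2 = ModelParameters(q=STUDY_TRUTH.q, mu=STUDY_TRUTH.mu / t_max,
                                amplitude=STUDY_TRUTH.amplitude,
                                phase=STUDY_TRUTH.phase, nu=2.0)
    rw, rm = [], []
    for s in _seeds(seed, n_seeds):
        cfg = _clean_config(int(s), n=n)
        rec, _ = generate_fukushima(cfg)
        rw.append(score_extrapolation(rec, SplitSpec(), cfg.env, method="robust").rmse_ratio)
        cfg2 = _clean_config(int(s), n=n, truth=truth_nu2)
        rec2, _ = generate_fukushima(cfg2)
        rm.append(score_extrapolation(rec2, SplitSpec(), cfg2.env,
                                      method="robust", variant="nu1").rmse_ratio)
    rw, rm = np.asarray(rw), np.asarray(rm)
    return {
        "frac_below_1.1_wellspec": float((rw < 1.1).mean()),
        "median_wellspec": float(np.median(rw)),
        "median_misspec": float(np.median(rm)),
        "paired_exceedance": float((rm > rw).mean()),
    }


def chernobyl_experiment(n_seeds: int = 100, seed: int = 0) -> dict:
    """Slope recovery of the weighted Time+Zone regression on synthetic
    zone/year summaries, and exactness of the MMI Akaike weights."""
    within_1se = within_2se = 0
    weight_sum_err = 0.0
    for s in _seeds(seed, n_seeds):
        cfg = ChernobylSimConfig(seed=int(s))
        df, truth = generate_chernobyl(cfg)
        model = ChernobylModel(compute_weights(df))
        fv = model.fit(("time", "zone"))
        i_t = fv.names.index("time")
        err = abs(fv.params[i_t] - truth["slope_time"])
        within_1se += err <= fv.bse[i_t]
        within_2se += err <= 2 * fv.bse[i_t]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit_all()
        weight_sum_err = max(weight_sum_err,
                             abs(res.model_table["akaike_weight"].sum() - 1.0))
    return {
        "frac_within_1se": within_1se / n_seeds,
        "frac_within_2se": within_2se / n_seeds,
        "mmi_weight_sum_max_err": weight_sum_err,
    }


def golden_run(seed: int = 20110311, n_boot: int = 100) -> dict:
    """One full pipeline pass on the default study-scale generator (district
    effects, heteroscedastic noise, 3% outliers): robust + quantile fits,
    outlier-screened mixed-effects fit, derived summaries."""
    cfg = SimulationConfig(seed=seed)
    rec, _ = generate_fukushima(cfg)
    analysis = rec[~rec["below_detection"]].reset_index(drop=True)
    m = BurdenModel(analysis, cfg.env)
    rob = m.fit_robust()
    q25 = m.fit_quantile(tau=0.25, init=rob.params, n_boot=n_boot, seed=seed % 2**31)
    q75 = m.fit_quantile(tau=0.75, init=rob.params, n_boot=n_boot, seed=seed % 2**31)
    hl, hl_ci = rob.half_life()
    seas = rob.seasonality()
    rep = detect_outliers(analysis)
    filtered = analysis.drop(analysis.index[rep.flagged_indices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed = MixedBurdenModel(filtered, cfg.env, random=("Q", "mu", "A"),
                                 variance_by_district=True, full_data=analysis).fit()
    return {
        "n_analysis": len(analysis),
        "robust_Q": rob.params.q,
        "robust_mu": rob.params.mu,
        "robust_A": rob.params.amplitude,
        "robust_P": rob.params.phase,
        "robust_rmse": rob.rmse,
        "half_life": hl,
        "half_life_lo": hl_ci[0],
        "half_life_hi": hl_ci[1],
        "amplitude_metric": seas["amplitude_metric"],
        "phase_months": seas["phase_months"],
        "interquartile_Q_gap": q75.params.q - q25.params.q,
        "n_outliers_flagged": int(rep.n_flagged),
        "mixed_r_squared": mixed.r_squared,
        "mixed_rmse_full": mixed.rmse_full,
        "mixed_random_sd_Q": mixed.random_sd.get("Q", 0.0),
    }
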