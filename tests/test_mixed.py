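"""Mixed-effects estimation, outlier screening and variance-homogeneity tests."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import csburden as cb
from tests.conftest import make_clean_config


def _grouped_config(seed, n=600, n_districts=8, sd_q=0.5, sd_mu=0.0, sd_a=0.0,
                    noise=1.0, **kw):
    return cb.SimulationConfig(
        seed=seed, n_samples=n, n_districts=n_districts,
        district_sd={"Q": sd_q, "mu": sd_mu, "A": sd_a, "P": 0.0},
        municipality_sd={"Q": kw.pop("sd_muni", 0.0)},
        noise_sd_by_district=kw.pop("noise_by_district", (noise,) * n_districts),
        outlier_fraction=0.0, **kw,
    )


def _ols_loglik(res):
    n = res.nobs
    return -0.5 * n * (np.log(2 * np.pi * res.rss / n) + 1)


class TestFitMixed:
    def test_no_random_terms_reproduces_ols_exactly(self, env):
        # all random SDs pinned at zero: GLS collapses to OLS
        cfg = make_clean_config(seed=6, n=600)
        rec, _ = cb.generate_fukushima(cfg)
        res = cb.MixedBurdenModel(rec, env, random=(), variance_by_district=False).fit()
        ols = cb.BurdenModel(rec, env).fit_ols()
        gap = np.abs(res.params.as_array() - ols.params.as_array())
        assert np.all(gap < 1e-6)

    def test_degenerate_hierarchy_shrinks_to_fixed_effects(self, env):
        # data generated with zero district variance: estimated SDs shrink
        # toward 0 (the finite-sample MLE is near, not exactly, zero) and
        # fixed effects approach the OLS solution
        cfg = make_clean_config(seed=6, n=600)
        rec, _ = cb.generate_fukushima(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cb.MixedBurdenModel(rec, env, random=("Q", "mu", "A"),
                                      variance_by_district=False).fit()
        ols = cb.BurdenModel(rec, env).fit_ols()
        gap = np.abs(res.params.as_array() - ols.params.as_array())
        assert np.all(gap < 5e-3)
        # with 7 districts of ~85 records and unit noise, pure noise puts
        # ~sigma/sqrt(n_d) ~ 0.11 of spread between district means; the
        # estimated SDs must not exceed that scale
        assert all(v < 0.15 for v in res.random_sd.values())

    def test_district_sd_recovery(self, env):
        hits = 0
        rng = np.random.default_rng(5)
        for _ in range(40):
            cfg = _grouped_config(int(rng.integers(2**31)), n_districts=20)
            rec, _ = cb.generate_fukushima(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = cb.MixedBurdenModel(rec, env, random=("Q",),
                                          variance_by_district=False).fit()
            hits += 0.35 <= res.random_sd["Q"] <= 0.65
        assert hits >= 34  # ~90% of seeds land in the +/-30% band

    def test_heteroscedastic_variances_estimated(self, env):
        cfg = _grouped_config(77, n=2000, n_districts=4, sd_q=0.3,
                              noise_by_district=(0.5, 0.5, 1.5, 1.5))
        rec, _ = cb.generate_fukushima(cfg)
        res = cb.MixedBurdenModel(rec, env, random=("Q",), variance_by_district=True).fit()
        mults = np.array([res.variance_multipliers[d] for d in sorted(res.variance_multipliers)])
        # variance ratio between the noisy and quiet districts is (1.5/0.5)^2 = 9
        assert mults[2] / mults[0] == pytest.approx(9.0, rel=0.35)
        assert mults[3] / mults[1] == pytest.approx(9.0, rel=0.35)

    def test_multipliers_invariant_to_district_relabeling(self, env):
        cfg = _grouped_config(13, n=800, n_districts=5,
                              noise_by_district=(0.6, 0.8, 1.0, 1.2, 1.4))
        rec, _ = cb.generate_fukushima(cfg)
        res = cb.MixedBurdenModel(rec, env, random=("Q",)).fit()
        relabel = {f"D{i + 1:02d}": f"Z{9 - i}" for i in range(5)}
        rec2 = rec.assign(district=rec["district"].map(relabel))
        res2 = cb.MixedBurdenModel(rec2, env, random=("Q",)).fit()
        # multipliers are relative to the first district alphabetically, so
        # compare variance ratios, which are label free
        m1 = np.array([res.variance_multipliers[d] for d in sorted(res.variance_multipliers)])
        m2 = np.array([res2.variance_multipliers[relabel[d]]
                       for d in sorted(res.variance_multipliers)])
        np.testing.assert_allclose(m1 / m1[0], m2 / m2[0], rtol=1e-4)

    def test_r_squared_definition_frozen(self, env):
        cfg = _grouped_config(21, n=500)
        rec, _ = cb.generate_fukushima(cfg)
        res = cb.MixedBurdenModel(rec, env, random=("Q",)).fit()
        # recompute 1 - RSS/TSS with BLUP-inclusive predictions
        from csburden.fixed import _design
        from csburden.model import environment_term

        t = rec["t"].to_numpy()
        X = _design(t, 1.0)
        pred = environment_term(t, env) + X @ res.beta
        u = rec["district"].map(res.blups.set_index("district")["u_Q"]).to_numpy()
        pred = pred + u
        rss = float(np.sum((rec["ln_cs_c"].to_numpy() - pred) ** 2))
        tss = float(np.sum((rec["ln_cs_c"] - rec["ln_cs_c"].mean()) ** 2))
        assert res.r_squared == pytest.approx(1 - rss / tss, abs=1e-10)
        assert res.rmse_full == pytest.approx(np.sqrt(rss / len(rec)), abs=1e-10)

    def test_metrics_computed_on_full_data_when_filtered(self, env):
        cfg = _grouped_config(22, n=500)
        rec, _ = cb.generate_fukushima(cfg)
        filtered = rec.iloc[:-50]
        res = cb.MixedBurdenModel(filtered, env, random=("Q",), full_data=rec).fit()
        assert res.nobs == len(filtered)
        res_self = cb.MixedBurdenModel(filtered, env, random=("Q",)).fit()
        assert res.r_squared != pytest.approx(res_self.r_squared)

    def test_single_district_rejected(self, env):
        cfg = _grouped_config(1, n=100, n_districts=2)
        rec, _ = cb.generate_fukushima(cfg)
        with pytest.raises(ValueError, match="at least 2 districts"):
            cb.MixedBurdenModel(rec[rec["district"] == "D01"], env)

    def test_seasonal_pair_random_effects_reported_canonically(self, env):
        cfg = _grouped_config(30, n=1200, n_districts=10, sd_q=0.3, sd_a=0.3)
        rec, _ = cb.generate_fukushima(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cb.MixedBurdenModel(rec, env, random=("Q", "A"),
                                      variance_by_district=False).fit()
        assert "A" in res.random_sd
        assert 0.05 < res.random_sd["A"] < 0.8


class TestCompareMixed:
    def test_duplicate_structures_tie(self, env):
        cfg = _grouped_config(41, n=400)
        rec, _ = cb.generate_fukushima(cfg)
        res = cb.MixedBurdenModel(rec, env, random=("Q",)).fit()
        tab, pref = cb.compare_mixed([res, res])
        assert tab["delta_aic"].max() == pytest.approx(0.0, abs=1e-9)

    def test_true_district_effects_detected_by_lr(self, env):
        rejections = 0
        rng = np.random.default_rng(6)
        for _ in range(20):
            cfg = _grouped_config(int(rng.integers(2**31)), n=400)
            rec, _ = cb.generate_fukushima(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r1 = cb.MixedBurdenModel(rec, env, random=("Q",),
                                         variance_by_district=False).fit()
            ll0 = _ols_loglik(cb.BurdenModel(rec, env).fit_ols())
            lr = 2 * (r1.loglik - ll0)
            rejections += stats.chi2.sf(lr, 1) < 0.05
        assert rejections >= 18

    def test_spurious_municipality_level_not_preferred(self, env):
        simpler = 0
        rng = np.random.default_rng(7)
        for _ in range(20):
            cfg = _grouped_config(int(rng.integers(2**31)), n=500)
            rec, _ = cb.generate_fukushima(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ra = cb.MixedBurdenModel(rec, env, random=("Q",),
                                         variance_by_district=False).fit()
                rb = cb.MixedBurdenModel(rec, env, random=("Q",),
                                         grouping="district/municipality",
                                         variance_by_district=False).fit()
            tab, pref = cb.compare_mixed([ra, rb])
            simpler += pref == 0
        assert simpler >= 14  # AIC keeps the simpler structure in >= 70%

    def test_nested_pair_gets_lr_p(self, env):
        # genuine variance in both Q and mu so the richer structure keeps
        # both terms (a singular term would be dropped, breaking nesting)
        cfg = _grouped_config(43, n=800, sd_mu=0.15)
        rec, _ = cb.generate_fukushima(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ra = cb.MixedBurdenModel(rec, env, random=("Q",), variance_by_district=False).fit()
            rb = cb.MixedBurdenModel(rec, env, random=("Q", "mu"), variance_by_district=False).fit()
        tab, _ = cb.compare_mixed([ra, rb])
        assert np.isfinite(tab.loc[0, "lr_p_vs_larger"])
        assert np.isnan(tab.loc[1, "lr_p_vs_larger"])


class TestOutlierDetection:
    def test_clean_data_flags_near_nominal_rate(self, env):
        cfg = make_clean_config(seed=51, n=1000)
        rec, _ = cb.generate_fukushima(cfg)
        rep = cb.detect_outliers(rec)
        assert rep.n_flagged / len(rec) <= 0.08  # nominal 2.5% plus MCD slack

    def test_planted_gross_outliers_all_flagged(self, env):
        cfg = make_clean_config(seed=52, n=500)
        rec, _ = cb.generate_fukushima(cfg)
        idx = [10, 100, 200, 300, 400]
        rec.loc[idx, "ln_cs_c"] += 8.0  # ~8 robust SDs
        rep = cb.detect_outliers(rec)
        assert set(idx) <= set(rep.flagged_indices.tolist())

    def test_external_list_mode(self, env, tmp_path):
        cfg = make_clean_config(seed=53, n=100)
        rec, _ = cb.generate_fukushima(cfg)
        path = tmp_path / "excl.txt"
        path.write_text("3\n17\n42\n")
        rep = cb.detect_outliers(rec, method="external_list", external_list=path)
        assert rep.flagged_indices.tolist() == [3, 17, 42]
        with pytest.raises(ValueError, match="requires a path"):
            cb.detect_outliers(rec, method="external_list")

    def test_empty_records_rejected(self, env):
        with pytest.raises(ValueError, match="nonempty"):
            cb.detect_outliers(pd.DataFrame(columns=["t", "ln_cs_c"]))


class TestVarianceHomogeneity:
    def test_equal_variances_give_uniform_p(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(60):
            df = pd.DataFrame({
                "district": np.repeat(list("ABCD"), 50),
                "ln_cs_c": rng.normal(0, 1, 200),
            })
            ps.append(cb.variance_homogeneity_test(df)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_inflated_group_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(0, 2, 200)])
            df = pd.DataFrame({"district": np.repeat(["A", "B"], 200), "ln_cs_c": vals})
            hits += cb.variance_homogeneity_test(df)[1] < 0.01
        assert hits >= 19  # 4x variance at n=200/group is essentially always seen

    def test_degenerate_data_rejected(self):
        df = pd.DataFrame({"district": np.repeat(["A", "B"], 5), "ln_cs_c": 1.0})
        with pytest.raises(ValueError, match="degenerate|spread"):
            cb.variance_homogeneity_test(df)

    def test_single_district_rejected(self):
        df = pd.DataFrame({"district": "A", "ln_cs_c": np.arange(10.0)})
        with pytest.raises(ValueError, match="at least 2"):
            cb.variance_homogeneity_test(df)
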