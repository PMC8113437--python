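"""Reading, screening, decay correction and subsetting of records."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import csburden as cb
from csburden.constants import DAYS_PER_YEAR
from csburden.ingest import forward_decay_total, years_since_accident
from csburden.simulate import write_raw_export, write_supplementary_export


def _supp_csv(tmp_path, rows, name="supp.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _supp_row(i, species="boar", t=1.0, ln=5.0, bdl=False):
    return {"species": species, "T": t, "LnCs_c": ln,
            "district": "Soso", "municipality": "M1", "below_detection": bdl}


class TestReadSamples:
    def test_all_valid_rows_kept(self, tmp_path):
        path = _supp_csv(tmp_path, [_supp_row(i, t=0.1 * i + 0.1) for i in range(100)])
        rec, rep = cb.read_samples(path)
        assert len(rec) == 100
        assert rep.n_removed == 0 and rep.fraction_removed == 0

    def test_below_detection_rows_counted_and_excluded(self, tmp_path):
        rows = [_supp_row(i, bdl=(i < 5)) for i in range(100)]
        path = _supp_csv(tmp_path, rows)
        rec, rep = cb.read_samples(path)
        assert len(rec) == 95
        assert rep.n_removed_below_detection == 5
        assert rep.n_input == rep.n_analysis + rep.n_removed

    def test_missing_values_counted(self, tmp_path):
        rows = [_supp_row(i) for i in range(10)]
        rows[3]["LnCs_c"] = None
        rows[7]["T"] = None
        rec, rep = cb.read_samples(_supp_csv(tmp_path, rows))
        assert len(rec) == 8 and rep.n_removed_missing == 2

    def test_unknown_species_rejected_not_fatal(self, tmp_path, caplog):
        rows = [_supp_row(i) for i in range(5)] + [_supp_row(5, species="tanuki")]
        rec, rep = cb.read_samples(_supp_csv(tmp_path, rows))
        assert len(rec) == 5 and rep.n_removed_invalid == 1

    def test_species_aliases_normalised(self, tmp_path):
        rows = [_supp_row(0, species="Wild Boar"), _supp_row(1, species="Asian black bear")]
        rec, _ = cb.read_samples(_supp_csv(tmp_path, rows))
        assert list(rec["species"]) == ["boar", "black_bear"]

    def test_empty_file_is_hard_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("species,T,LnCs_c,district,municipality\n")
        with pytest.raises(Exception):
            cb.read_samples(path)

    def test_missing_columns_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"species": ["boar"], "T": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            cb.read_samples(path)

    def test_raw_dialect_dates_and_t_conversion(self, tmp_path):
        path = tmp_path / "raw.csv"
        pd.DataFrame([{
            "species": "boar", "collection_date": "2012-03-10",
            "measurement_date": "2012/03/20", "cs134": 500.0, "cs137": 600.0,
            "district": "Soso", "municipality": "M1",
        }]).to_csv(path, index=False)
        rec, rep = cb.read_samples(path, dialect="raw")
        assert len(rec) == 1
        expected_t = (dt.date(2012, 3, 10) - dt.date(2011, 3, 11)).days / DAYS_PER_YEAR
        assert rec.loc[0, "t"] == pytest.approx(expected_t, abs=1e-12)
        assert rec.loc[0, "ln_cs_c"] > math.log(1100.0)  # back-correction adds activity

    def test_raw_dialect_nd_rows_below_detection(self, tmp_path):
        path = tmp_path / "raw.csv"
        pd.DataFrame([
            {"species": "boar", "collection_date": "2013-01-01", "measurement_date": "2013-01-05",
             "cs134": "ND", "cs137": "ND", "district": "D", "municipality": "M"},
            {"species": "boar", "collection_date": "2013-01-01", "measurement_date": "2013-01-05",
             "cs134": "ND", "cs137": 250.0, "district": "D", "municipality": "M"},
        ]).to_csv(path, index=False)
        rec, rep = cb.read_samples(path, dialect="raw")
        assert rep.n_removed_below_detection == 1
        assert len(rec) == 1  # one isotope measured is still a usable total

    def test_ambiguous_date_is_row_error(self, tmp_path):
        path = tmp_path / "raw.csv"
        pd.DataFrame([{
            "species": "boar", "collection_date": "05/06/2012",
            "measurement_date": "2012-06-10", "cs134": 1.0, "cs137": 1.0,
            "district": "D", "municipality": "M",
        }]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 0"):
            cb.read_samples(path, dialect="raw")

    def test_measurement_before_collection_error(self, tmp_path):
        path = tmp_path / "raw.csv"
        pd.DataFrame([{
            "species": "boar", "collection_date": "2012-06-10",
            "measurement_date": "2012-06-01", "cs134": 1.0, "cs137": 1.0,
            "district": "D", "municipality": "M",
        }]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="precedes"):
            cb.read_samples(path, dialect="raw")


class TestCorrectDecay:
    def test_zero_delay_is_plain_log(self):
        assert cb.correct_decay(1000.0, 1.0, 1.0) == pytest.approx(math.log(1000.0), rel=1e-14)

    def test_pure_cs137_one_half_life(self):
        c = cb.DEFAULT_CONSTANTS
        ln = cb.correct_decay(400.0, 0.0, c.th_cs137, cs137=400.0)
        assert ln == pytest.approx(math.log(400.0) + math.log(2.0), rel=1e-12)

    def test_nonpositive_activity_rejected(self):
        with pytest.raises(ValueError):
            cb.correct_decay(0.0, 1.0, 1.5)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            cb.correct_decay(10.0, 2.0, 1.0)

    def test_forward_then_correct_recovers_input(self):
        # ratio-path round trip at a fixed delay
        a134, a137 = forward_decay_total(1000.0, 1.2, 1.7)
        total_meas = a134 + a137
        ln = cb.correct_decay(total_meas, 1.2, 1.7)
        assert math.exp(ln) == pytest.approx(1000.0, rel=1e-12)

    @given(
        total=st.floats(1.0, 1e6),
        t_coll=st.floats(0.0, 7.0),
        delta=st.floats(0.0, 5.0),
        f134=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_any_mix_and_delay(self, total, t_coll, delta, f134):
        # per-isotope path: decay an arbitrary isotope mix forward, then
        # back-correct from the measured components
        a134, a137 = forward_decay_total(
            total, t_coll, t_coll + delta, fraction_cs134_at_collection=f134
        )
        ln = cb.correct_decay(a134 + a137, t_coll, t_coll + delta,
                              cs134=a134 or None, cs137=a137 or None)
        assert math.exp(ln) == pytest.approx(total, rel=1e-10)


class TestIsotopeIntercepts:
    @staticmethod
    def _records(n, i134, i137, slope134, slope137, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0.1, 6.0, n)
        df = pd.DataFrame({
            "t": t,
            "cs134": np.exp(i134 + slope134 * t + rng.normal(0, noise, n)),
            "cs137": np.exp(i137 + slope137 * t + rng.normal(0, noise, n)),
            "collection_date": pd.NaT, "measurement_date": pd.NaT,
        })
        return df

    def test_noiseless_series_recovered_exactly(self):
        df = self._records(40, 8.0, 7.0, -0.5, -0.1)
        env, ses = cb.estimate_isotope_intercepts(df)
        assert env.ln_cs134_t0 == pytest.approx(8.0, abs=1e-8)
        assert env.ln_cs137_t0 == pytest.approx(7.0, abs=1e-8)

    def test_constant_activity_gives_log_activity(self):
        df = self._records(20, math.log(500.0), math.log(300.0), 0.0, 0.0)
        env, _ = cb.estimate_isotope_intercepts(df)
        assert env.ln_cs134_t0 == pytest.approx(math.log(500.0), abs=1e-8)

    def test_robust_resists_gross_outliers(self):
        import statsmodels.api as sm

        df = self._records(100, 8.0, 7.0, -0.5, -0.1, noise=0.2, seed=3)
        # 10% one-sided gross contamination at early times drags a plain LS
        # intercept upward; the M-estimator should stay near the truth
        df.loc[:9, "cs137"] *= math.exp(5.0)
        env, ses = cb.estimate_isotope_intercepts(df)
        assert abs(env.ln_cs137_t0 - 7.0) < 3 * ses["cs137"]
        X = sm.add_constant(df["t"].to_numpy())
        ols = sm.OLS(np.log(df["cs137"].to_numpy()), X).fit()
        assert abs(ols.params[0] - 7.0) > 3 * ses["cs137"]

    def test_insufficient_data_names_isotope(self):
        df = self._records(5, 8.0, 7.0, -0.5, -0.1)
        with pytest.raises(ValueError, match="cs134"):
            cb.estimate_isotope_intercepts(df)


class TestSubsetRecords:
    @staticmethod
    def _records():
        rows = (
            [{"species": "boar", "district": "Soso", "municipality": "M", "t": 1.0, "ln_cs_c": 5.0}] * 30
            + [{"species": "boar", "district": "Aizu", "municipality": "M", "t": 1.0, "ln_cs_c": 5.0}] * 20
        )
        return pd.DataFrame(rows)

    def test_full_is_identity(self):
        df = self._records()
        out = cb.subset_records(df, "full", species="boar")
        assert len(out) == len(df)

    def test_high_districts_keeps_selected(self):
        out = cb.subset_records(self._records(), "high_districts", species="boar")
        assert len(out) == 30 and set(out["district"]) == {"Soso"}

    def test_sensitivity_drops_mountain_districts_and_early_times(self):
        df = pd.DataFrame([
            {"species": "boar", "district": "Soso", "municipality": "M", "t": 0.4, "ln_cs_c": 5.0},
            {"species": "boar", "district": "Soso", "municipality": "M", "t": 0.6, "ln_cs_c": 5.0},
            {"species": "boar", "district": "Minamiaizu", "municipality": "M", "t": 2.0, "ln_cs_c": 5.0},
        ])
        out = cb.subset_records(df, "sensitivity")
        assert len(out) == 1 and out.iloc[0]["t"] == 0.6

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown subset rule"):
            cb.subset_records(self._records(), "bogus")


class TestRoundTripWithGenerator:
    def test_raw_export_reingested_reproduces_ln_cs_c(self, tmp_path, clean_records):
        records, _, _ = clean_records
        path = tmp_path / "raw.csv"
        write_raw_export(records, path)
        back, rep = cb.read_samples(path, dialect="raw")
        assert rep.n_input == len(records)
        kept = records[~records["below_detection"]].reset_index(drop=True)
        assert len(back) == len(kept)
        # dates are rounded to whole days on export, so T and the correction
        # agree only to ~1 day equivalent
        assert np.max(np.abs(back["t"].to_numpy() - kept["t"].to_numpy())) < 1.5 / 365.25
        assert np.max(np.abs(back["ln_cs_c"].to_numpy() - kept["ln_cs_c"].to_numpy())) < 5e-3

    def test_supplementary_export_reingested_exact(self, tmp_path, clean_records):
        records, _, _ = clean_records
        path = tmp_path / "supp.csv"
        write_supplementary_export(records, path)
        back, rep = cb.read_samples(path)
        kept = records[~records["below_detection"]].reset_index(drop=True)
        np.testing.assert_allclose(back["ln_cs_c"], kept["ln_cs_c"], rtol=1e-12)

    def test_t_matches_collection_date_invariant(self, clean_records):
        records, _, _ = clean_records
        t_from_date = np.array([
            years_since_accident(d) for d in records["collection_date"]
        ])
        # generator rounds dates to days: agreement within one day equivalent
        assert np.max(np.abs(t_from_date - records["t"].to_numpy())) <= 1.0 / 365.25 + 1e-12
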