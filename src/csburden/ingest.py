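"""Reading, validation, filtering and decay-correction of animal records.

Two delimited-text layouts are supported (documented in
``csburden/data/schema.yaml``):

* ``supplementary`` — analysis-ready rows: species, T (years since the
  accident), decay-corrected ln total cesium ``LnCs_c``, district,
  municipality.
* ``raw`` — monitoring-style rows with per-isotope activities (Bq/kg) at the
  measurement date, plus collection and measurement dates.  ``LnCs_c`` is
  derived here by back-correcting each isotope component for physical decay
  over the collection-to-measurement delay.

Rows with missing data or total cesium below detection are excluded from the
analysis set and counted in a :class:`FilterReport`, mirroring the screening
applied to the public Fukushima Prefecture monitoring data.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DAYS_PER_YEAR, DEFAULT_CONSTANTS, IsotopeConstants
from .model import EnvironmentTerm

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "read_samples",
    "correct_decay",
    "estimate_isotope_intercepts",
    "subset_records",
    "write_analysis_table",
    "SPECIES_LABELS",
    "HIGH_BURDEN_DISTRICTS",
]

#: Canonical species labels and the aliases accepted on input.
SPECIES_LABELS = {
    "boar": "boar",
    "wild boar": "boar",
    "sus scrofa": "boar",
    "black_bear": "black_bear",
    "black bear": "black_bear",
    "asian black bear": "black_bear",
    "bear": "black_bear",
    "ursus thibetanus": "black_bear",
}

#: Districts with the highest mean burdens (and enough samples), per species.
HIGH_BURDEN_DISTRICTS = {
    "boar": {"Soso", "Kenpoku"},
    "black_bear": {"Kenpoku", "Kenchu"},
}

#: Districts separated from the plant by mountains, dropped in the
#: sensitivity subset together with samples collected within half a year of
#: the accident.
SENSITIVITY_EXCLUDED_DISTRICTS = {"Aizu", "Minamiaizu"}
SENSITIVITY_MIN_T = 0.5

_DATE_FORMATS = ("%Y-%m-%d", "%Y/%m/%d")

#: Column names of the analysis-ready table.
ANALYSIS_COLUMNS = [
    "species",
    "t",
    "ln_cs_c",
    "district",
    "municipality",
    "collection_date",
    "measurement_date",
    "cs134",
    "cs137",
    "cs_total_reported",
    "below_detection",
]


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping of rows removed while building the analysis set."""

    n_input: int
    n_removed_missing: int = 0
    n_removed_below_detection: int = 0
    n_removed_invalid: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.n_removed_missing
            + self.n_removed_below_detection
            + self.n_removed_invalid
        )

    @property
    def n_analysis(self) -> int:
        return self.n_input - self.n_removed

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def _parse_date(value, row: int) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    s = str(value).strip()
    for fmt in _DATE_FORMATS:
        try:
            return _dt.datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"row {row}: unparseable or ambiguous date {value!r} "
                     f"(accepted formats: {', '.join(_DATE_FORMATS)})")


def years_since_accident(d: _dt.date, constants: IsotopeConstants = DEFAULT_CONSTANTS) -> float:
    """Calendar date -> decimal years since the accident (365.25 d/y)."""
    return (d - constants.accident_date).days / DAYS_PER_YEAR


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _activity(value) -> tuple[float, bool]:
    """Parse one activity cell -> (Bq/kg, below_detection_marker)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan, False
    s = str(value).strip()
    if s == "":
        return math.nan, False
    if s.upper() in {"ND", "N.D.", "BDL"} or s.startswith("<"):
        return 0.0, True
    return float(s), False


def read_samples(
    path,
    dialect: str = "supplementary",
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    sep: str = ",",
):
    """Read a sample file into the analysis-ready table.

    Returns ``(records, report)`` where ``records`` is a DataFrame with the
    :data:`ANALYSIS_COLUMNS` (only the rows retained for analysis) and
    ``report`` a :class:`FilterReport` of the screening.

    Raises ``ValueError`` on an empty file, missing required columns or an
    unparseable date (with the offending row index).  Rows with an unknown
    species label are rejected and logged, not fatal.
    """
    raw = pd.read_csv(path, sep=sep)
    if raw.empty:
        raise ValueError(f"{path}: file contains no data rows")
    raw = _normalize_columns(raw)

    if dialect == "supplementary":
        required = {"species", "t", "lncs_c", "district", "municipality"}
    elif dialect == "raw":
        required = {
            "species", "collection_date", "measurement_date",
            "cs134", "cs137", "district", "municipality",
        }
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {sorted(missing_cols)}")

    n_input = len(raw)
    n_missing = n_bdl = n_invalid = 0
    rows = []
    for i, rec in raw.iterrows():
        label = str(rec["species"]).strip().lower()
        species = SPECIES_LABELS.get(label)
        if species is None:
            logger.warning("row %d: unknown species label %r, row rejected", i, rec["species"])
            n_invalid += 1
            continue
        if dialect == "supplementary":
            t, ln_cs_c = rec["t"], rec["lncs_c"]
            if pd.isna(t) or pd.isna(ln_cs_c):
                n_missing += 1
                continue
            bdl = bool(rec.get("below_detection", False))
            if bdl:
                n_bdl += 1
                continue
            rows.append({
                "species": species, "t": float(t), "ln_cs_c": float(ln_cs_c),
                "district": str(rec["district"]).strip(),
                "municipality": str(rec["municipality"]).strip(),
                "collection_date": pd.NaT, "measurement_date": pd.NaT,
                "cs134": np.nan, "cs137": np.nan, "cs_total_reported": np.nan,
                "below_detection": False,
            })
        else:
            if pd.isna(rec["collection_date"]) or pd.isna(rec["measurement_date"]):
                n_missing += 1
                continue
            coll = _parse_date(rec["collection_date"], i)
            meas = _parse_date(rec["measurement_date"], i)
            if meas < coll:
                raise ValueError(f"row {i}: measurement date {meas} precedes collection date {coll}")
            a134, bdl134 = _activity(rec["cs134"])
            a137, bdl137 = _activity(rec["cs137"])
            if math.isnan(a134) and math.isnan(a137):
                n_missing += 1
                continue
            a134 = 0.0 if math.isnan(a134) else a134
            a137 = 0.0 if math.isnan(a137) else a137
            total = a134 + a137
            if total <= 0:
                n_bdl += 1
                continue
            t = years_since_accident(coll, constants)
            ln_cs_c = correct_decay(
                total, coll, meas, constants=constants,
                cs134=a134 if a134 > 0 else None,
                cs137=a137 if a137 > 0 else None,
            )
            rows.append({
                "species": species, "t": t, "ln_cs_c": ln_cs_c,
                "district": str(rec["district"]).strip(),
                "municipality": str(rec["municipality"]).strip(),
                "collection_date": coll, "measurement_date": meas,
                "cs134": a134, "cs137": a137, "cs_total_reported": total,
                "below_detection": False,
            })

    report = FilterReport(
        n_input=n_input,
        n_removed_missing=n_missing,
        n_removed_below_detection=n_bdl,
        n_removed_invalid=n_invalid,
    )
    records = pd.DataFrame(rows, columns=ANALYSIS_COLUMNS)
    return records, report


def correct_decay(
    cs_total_reported: float,
    collection_date,
    measurement_date,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    cs134: float | None = None,
    cs137: float | None = None,
) -> float:
    """ln of the total cesium activity back-decayed to the collection date.

    ``cs_total_reported`` is the total activity (Bq/kg) observed at the
    measurement date.  When per-isotope activities at the measurement date
    are supplied, each component is multiplied by 2**(+delta/Th) with
    delta the collection-to-measurement delay in years.  Otherwise the
    134:137 activity split *at collection* is inferred from the release
    ratio decayed from the accident date to the collection date, and the
    total is scaled accordingly.

    ``collection_date``/``measurement_date`` may be calendar dates or
    decimal years since the accident.
    """
    if cs_total_reported <= 0:
        raise ValueError("cs_total_reported must be positive")

    def _to_years(d):
        if isinstance(d, (int, float)):
            return float(d)
        return years_since_accident(d, constants)

    t_coll = _to_years(collection_date)
    t_meas = _to_years(measurement_date)
    delta = t_meas - t_coll
    if delta < -1e-12:
        raise ValueError("measurement precedes collection (negative delay)")
    delta = max(delta, 0.0)

    if cs134 is not None or cs137 is not None:
        a134 = float(cs134 or 0.0)
        a137 = float(cs137 or 0.0)
        if a134 < 0 or a137 < 0 or a134 + a137 <= 0:
            raise ValueError("per-isotope activities must be non-negative with a positive total")
        corrected = a134 * 2.0 ** (delta / constants.th_cs134) + a137 * 2.0 ** (
            delta / constants.th_cs137
        )
        return math.log(corrected)

    # Infer the isotope split at collection from the source-term ratio.
    f134 = float(constants.fraction_cs134(t_coll))
    decay_factor = f134 * 2.0 ** (-delta / constants.th_cs134) + (1.0 - f134) * 2.0 ** (
        -delta / constants.th_cs137
    )
    return math.log(cs_total_reported / decay_factor)


def forward_decay_total(
    cs_total_at_collection: float,
    collection_date,
    measurement_date,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    fraction_cs134_at_collection: float | None = None,
):
    """Physically decay a collection-time total forward to the measurement
    date (inverse of :func:`correct_decay`'s ratio path); used for
    round-trip checks and by the synthetic-data generator."""

    def _to_years(d):
        if isinstance(d, (int, float)):
            return float(d)
        return years_since_accident(d, constants)

    t_coll = _to_years(collection_date)
    delta = _to_years(measurement_date) - t_coll
    if delta < 0:
        raise ValueError("negative delay")
    f134 = (
        float(constants.fraction_cs134(t_coll))
        if fraction_cs134_at_collection is None
        else fraction_cs134_at_collection
    )
    a134 = cs_total_at_collection * f134 * 2.0 ** (-delta / constants.th_cs134)
    a137 = cs_total_at_collection * (1 - f134) * 2.0 ** (-delta / constants.th_cs137)
    return a134, a137


def estimate_isotope_intercepts(
    records: pd.DataFrame,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    min_records: int = 10,
):
    """Robust ln-linear regression intercepts of each isotope at T = 0.

    Expects the analysis-ready ``raw``-dialect columns (``t``, ``cs134``,
    ``cs137``; plus dates for delay correction).  Each isotope activity is
    first back-corrected to its collection time (exact single-isotope
    correction), then ln(activity) is regressed on T with a redescending
    M-estimator (Tukey bisquare), which rejects — rather than merely
    bounds — gross outliers, so heavy one-sided contamination does not
    drag the intercepts.

    Returns ``(EnvironmentTerm, {"cs134": se, "cs137": se})``.
    """
    import statsmodels.api as sm

    out = {}
    ses = {}
    for iso, th in (("cs134", constants.th_cs134), ("cs137", constants.th_cs137)):
        sub = records[records[iso] > 0]
        if len(sub) < min_records:
            raise ValueError(
                f"insufficient data for isotope {iso}: {len(sub)} records "
                f"with positive activity (need >= {min_records})"
            )
        act = sub[iso].to_numpy(dtype=float)
        if sub["measurement_date"].notna().all() and sub["collection_date"].notna().all():
            delta = np.array([
                (m - c).days / DAYS_PER_YEAR
                for m, c in zip(sub["measurement_date"], sub["collection_date"])
            ])
            act = act * 2.0 ** (np.clip(delta, 0, None) / th)
        y = np.log(act)
        X = sm.add_constant(sub["t"].to_numpy(dtype=float))
        res = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
        out[iso] = float(res.params[0])
        ses[iso] = float(res.bse[0])
    env = EnvironmentTerm(ln_cs134_t0=out["cs134"], ln_cs137_t0=out["cs137"], constants=constants)
    return env, ses


def subset_records(records: pd.DataFrame, rule: str, species: str | None = None) -> pd.DataFrame:
    """Apply one of the named data-subset rules.

    ``full`` is the identity; ``high_districts`` keeps the two
    highest-burden districts for the species; ``sensitivity`` drops the
    mountain-separated districts (Aizu, Minamiaizu) and samples collected
    within half a year of the accident.
    """
    if species is not None:
        records = records[records["species"] == species]
    if rule == "full":
        return records.copy()
    if rule == "high_districts":
        if species is None:
            raise ValueError("high_districts rule requires a species")
        keep = HIGH_BURDEN_DISTRICTS[species]
        return records[records["district"].isin(keep)].copy()
    if rule == "sensitivity":
        mask = ~records["district"].isin(SENSITIVITY_EXCLUDED_DISTRICTS)
        mask &= records["t"] > SENSITIVITY_MIN_T
        return records[mask].copy()
    raise ValueError(f"unknown subset rule {rule!r}")


def write_analysis_table(records: pd.DataFrame, path) -> None:
    """Write the analysis-ready table as CSV (schema in data/schema.yaml)."""
    records.to_csv(path, index=False)
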