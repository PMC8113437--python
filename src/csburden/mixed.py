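"""Mixed-effects estimation of the burden model.

The ``nu = 1`` model in its linearised form (covariates 1, T, sin 2piT,
cos 2piT on the response net of the environment term) is fitted by maximum
likelihood with:

* independent Gaussian random effects by district on a chosen subset of the
  parameters — the seasonal pair (A, P) is parameterised through its
  (a, b) = (A cos 2piP, A sin 2piP) sin/cos coefficients, and district SDs
  for A and P are recovered by the delta method;
* optionally a nested random intercept per municipality within district;
* optionally a separate residual variance multiplier per district
  (varIdent-style heteroscedasticity).

Estimation is plain ML (not REML) so likelihoods of different random
structures are comparable.  The marginal likelihood is evaluated per
district block with the Woodbury identity, so each evaluation costs only
O(q^3) per district regardless of sample size.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .fixed import _canonical_jacobian, _design, _linear_to_canonical
from .model import EnvironmentTerm, ModelParameters, environment_term

logger = logging.getLogger(__name__)

__all__ = [
    "MixedBurdenModel",
    "MixedBurdenResults",
    "OutlierReport",
    "detect_outliers",
    "compare_mixed",
    "variance_homogeneity_test",
]

_TWO_PI = 2.0 * math.pi

#: map from model parameters to columns of the linearised design
_PARAM_COLS = {"Q": (0,), "mu": (1,), "A": (2, 3), "P": (2, 3)}
_COL_NAMES = {0: "Q", 1: "mu", 2: "a_sin", 3: "b_cos"}

_LOG_SD_FLOOR = -8.0  # exp(-8) ~ 3.4e-4: below this a random term is singular


@dataclass(frozen=True)
class OutlierReport:
    """Records flagged before mixed-effects fitting."""

    flagged_indices: np.ndarray
    method: str
    scores: np.ndarray
    threshold: float

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_indices)


def detect_outliers(
    records: pd.DataFrame,
    method: str = "robust_distance",
    threshold: float = 0.975,
    external_list=None,
) -> OutlierReport:
    """Flag gross outliers on the (T, LnCs_c) plane.

    ``robust_distance`` computes robust Mahalanobis distances from a
    minimum-covariance-determinant scatter estimate and flags points whose
    squared distance exceeds the chi-square(2) quantile ``threshold``.
    ``external_list`` loads a verbatim exclusion list of row indices (one
    integer per line) — the fidelity path when a published list exists.
    """
    if records.empty:
        raise ValueError("records must be nonempty")
    if method == "external_list":
        if external_list is None:
            raise ValueError("external_list method requires a path")
        idx = np.loadtxt(external_list, dtype=int, ndmin=1)
        bad = idx[(idx < 0) | (idx >= len(records))]
        if bad.size:
            raise ValueError(f"exclusion list indices out of range: {bad[:5]}")
        scores = np.zeros(len(records))
        scores[idx] = np.inf
        return OutlierReport(np.sort(idx), method, scores, math.inf)
    if method != "robust_distance":
        raise ValueError(f"unknown outlier method {method!r}")

    from sklearn.covariance import MinCovDet

    Xy = records[["t", "ln_cs_c"]].to_numpy(dtype=float)
    mcd = MinCovDet(random_state=0).fit(Xy)
    d2 = mcd.mahalanobis(Xy)
    cut = stats.chi2.ppf(threshold, df=2)
    flagged = np.flatnonzero(d2 > cut)
    return OutlierReport(flagged, method, d2, cut)


def variance_homogeneity_test(records: pd.DataFrame, value_col: str = "ln_cs_c",
                              group_col: str = "district", min_per_group: int = 3):
    """Fligner-Killeen test of variance homogeneity across districts.

    Returns ``(statistic, p_value)``.  Raises when fewer than two usable
    districts remain or when the data are degenerate (no spread anywhere).
    """
    groups = [g.to_numpy(dtype=float)
              for _, g in records.groupby(group_col)[value_col]
              if len(g) >= min_per_group]
    if len(groups) < 2:
        raise ValueError("need at least 2 districts with enough records")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("degenerate data: no within-district spread")
    res = stats.fligner(*groups)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MixedBurdenResults:
    """ML estimates for one random-effects structure."""

    model: "MixedBurdenModel"
    params: ModelParameters
    se: dict
    vcov: np.ndarray  # canonical (Q, mu, A, P)
    beta: np.ndarray  # linearised fixed effects (Q, -mu, a, b)
    random_sd: dict  # canonical per-parameter district SDs (delta method for A, P)
    random_sd_columns: dict  # raw per-column SDs on the linearised scale
    municipality_sd: Optional[float]
    variance_multipliers: dict  # per-district residual variance scale factors
    sigma: float  # residual SD of the reference district
    loglik: float
    n_params: int
    converged: bool
    dropped_terms: list
    structure: str
    blups: pd.DataFrame
    residuals: np.ndarray  # marginal residuals on the filtered fit set
    r_squared: float  # on the full (unfiltered) data, BLUPs included
    rmse_full: float  # same data, ln(Bq/kg)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def nobs(self) -> int:
        return len(self.residuals)

    def half_life(self, level: float = 0.95):
        from .model import ecological_half_life

        return ecological_half_life(self.params.mu, self.se["mu"], level=level)

    def seasonality(self, level: float = 0.95):
        from .model import seasonal_summaries

        return seasonal_summaries(self.params.amplitude, self.params.phase,
                                  self.se["A"], self.se["P"], level=level)

    def summary(self) -> str:
        lines = [
            f"Mixed-effects burden model ({self.structure})",
            f"  nobs(fit) = {self.nobs}, loglik = {self.loglik:.2f}, AIC = {self.aic:.1f}",
            f"  R^2 (full data) = {self.r_squared:.3f}, RMSE (full data) = {self.rmse_full:.3f}",
            "  parameter   fixed est.     se    random SD",
        ]
        vals = {"Q": self.params.q, "mu": self.params.mu,
                "A": self.params.amplitude, "P": self.params.phase}
        for name in ("Q", "mu", "A", "P"):
            rsd = self.random_sd.get(name)
            rtxt = f"{rsd:9.4f}" if rsd is not None else "        -"
            lines.append(f"  {name:<10} {vals[name]:9.4f}  {self.se[name]:8.4f}  {rtxt}")
        if self.municipality_sd is not None:
            lines.append(f"  municipality intercept SD = {self.municipality_sd:.4f}")
        if len(self.variance_multipliers) > 1:
            mults = ", ".join(f"{k}: {v:.2f}" for k, v in self.variance_multipliers.items())
            lines.append(f"  residual variance multipliers: {mults}")
        return "\n".join(lines)


class MixedBurdenModel:
    """Burden model with district (and municipality) random effects.

    Parameters
    ----------
    data : DataFrame
        Outlier-filtered records with ``t``, ``ln_cs_c``, ``district`` (and
        ``municipality`` for nested grouping).
    env : EnvironmentTerm
    random : sequence from {"Q", "mu", "A", "P"}
        Parameters given district-level random effects.  A and P share the
        sin/cos coefficient pair.
    grouping : {"district", "district/municipality"}
        Nested grouping adds a random intercept per municipality.
    variance_by_district : bool
        Estimate a residual variance multiplier per district.
    full_data : DataFrame, optional
        Unfiltered records on which R^2 and RMSE are evaluated (defaults to
        the fit data).
    """

    def __init__(self, data: pd.DataFrame, env: EnvironmentTerm,
                 random: Sequence[str] = ("Q", "mu", "A"),
                 grouping: str = "district",
                 variance_by_district: bool = True,
                 full_data: Optional[pd.DataFrame] = None):
        if grouping not in {"district", "district/municipality"}:
            raise ValueError(f"unknown grouping {grouping!r}")
        bad = set(random) - set(_PARAM_COLS)
        if bad:
            raise ValueError(f"unknown random terms {sorted(bad)}")
        self.data = data.reset_index(drop=True)
        self.env = env
        self.random = tuple(random)
        self.grouping = grouping
        self.variance_by_district = variance_by_district
        self.full_data = self.data if full_data is None else full_data.reset_index(drop=True)

        self.districts = sorted(self.data["district"].unique())
        if len(self.districts) < 2:
            raise ValueError("mixed-effects fit requires at least 2 districts")

        cols = sorted({c for p in random for c in _PARAM_COLS[p]})
        self.random_cols = cols
        self.nested = grouping == "district/municipality"

        t = self.data["t"].to_numpy(dtype=float)
        y = self.data["ln_cs_c"].to_numpy(dtype=float) - environment_term(t, env)
        X = _design(t, 1.0)
        self._blocks = []
        for d in self.districts:
            m = (self.data["district"] == d).to_numpy()
            Xd, yd = X[m], y[m]
            Zd = Xd[:, cols] if cols else np.empty((m.sum(), 0))
            munis = []
            if self.nested:
                mvals = self.data.loc[m, "municipality"].to_numpy()
                munis = sorted(pd.unique(mvals))
                M = np.column_stack([(mvals == mm).astype(float) for mm in munis])
                Zd = np.hstack([Zd, M])
            W = np.column_stack([Xd, yd])
            self._blocks.append({
                "district": d, "n": int(m.sum()), "munis": munis,
                "Z": Zd, "W": W, "ZtZ": Zd.T @ Zd, "ZtW": Zd.T @ W, "WtW": W.T @ W,
            })

    # -- likelihood machinery ------------------------------------------------
    def _theta_layout(self, active_cols):
        k = len(active_cols)
        layout = {"sd_cols": slice(0, k)}
        pos = k
        if self.nested:
            layout["sd_muni"] = pos
            pos += 1
        if self.variance_by_district:
            layout["log_mult"] = slice(pos, pos + len(self.districts) - 1)
            pos += len(self.districts) - 1
        layout["log_sigma"] = pos
        return layout, pos + 1

    def _unpack(self, theta, layout, active_cols):
        g_cols = np.exp(2 * np.asarray(theta[layout["sd_cols"]]))  # variances
        g_muni = math.exp(2 * theta[layout["sd_muni"]]) if self.nested else 0.0
        mult = np.ones(len(self.districts))
        if self.variance_by_district:
            mult[1:] = np.exp(np.asarray(theta[layout["log_mult"]]))
        sigma2 = math.exp(2 * theta[layout["log_sigma"]])
        return g_cols, g_muni, mult, sigma2

    def _profiled_nll(self, theta, layout, active_cols, return_fit=False):
        g_cols, g_muni, mult, sigma2 = self._unpack(theta, layout, active_cols)
        col_pos = {c: i for i, c in enumerate(self.random_cols)}
        S = np.zeros((5, 5))
        logdet = 0.0
        n_total = 0
        pieces = []
        for bi, blk in enumerate(self._blocks):
            s = sigma2 * mult[bi]
            q = blk["Z"].shape[1]
            g = np.concatenate([
                np.array([g_cols[active_cols.index(c)] if c in active_cols else 0.0
                          for c in self.random_cols]),
                np.full(len(blk["munis"]), g_muni),
            ]) if q else np.empty(0)
            n_total += blk["n"]
            if q:
                sg = np.sqrt(g)
                M = np.eye(q) + (sg[:, None] * blk["ZtZ"] * sg[None, :]) / s
                sign, ld = np.linalg.slogdet(M)
                Minv = np.linalg.inv(M)
                K = (sg[:, None] * Minv * sg[None, :])  # = G^1/2 M^-1 G^1/2
                SW = (blk["WtW"] - blk["ZtW"].T @ K @ blk["ZtW"] / s) / s
                logdet += blk["n"] * math.log(s) + ld
            else:
                SW = blk["WtW"] / s
                logdet += blk["n"] * math.log(s)
            S += SW
            if return_fit:
                pieces.append((g, s))
        A, b, yy = S[:4, :4], S[:4, 4], S[4, 4]
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return (np.inf, None) if return_fit else np.inf
        quad = yy - b @ beta
        nll = 0.5 * (n_total * math.log(2 * math.pi) + logdet + quad)
        if not np.isfinite(nll):
            return (np.inf, None) if return_fit else np.inf
        if return_fit:
            return nll, {"beta": beta, "A": A, "pieces": pieces,
                         "g_cols": g_cols, "g_muni": g_muni, "mult": mult,
                         "sigma2": sigma2}
        return nll

    def fit(self, seed: Optional[int] = None, maxiter: int = 500) -> MixedBurdenResults:
        """Maximum-likelihood fit; raises on non-convergence.

        A random term whose SD collapses to the boundary (singular
        random-effects covariance) is dropped with a warning and the model
        refitted without it.
        """
        return self._fit(list(self.random_cols), maxiter)

    def _fit(self, active_cols, maxiter, _dropped=None):
        _dropped = _dropped or []
        layout, n_theta = self._theta_layout(active_cols)
        theta0 = np.zeros(n_theta)
        theta0[layout["sd_cols"]] = math.log(0.3)
        if self.nested:
            theta0[layout["sd_muni"]] = math.log(0.2)
        resid_scale = float(np.std(self.data["ln_cs_c"])) or 1.0
        theta0[layout["log_sigma"]] = math.log(max(resid_scale / 2, 1e-2))

        bounds = [( _LOG_SD_FLOOR, 4.0)] * len(active_cols)
        if self.nested:
            bounds.append((_LOG_SD_FLOOR, 4.0))
        if self.variance_by_district:
            bounds += [(-6.0, 6.0)] * (len(self.districts) - 1)
        bounds.append((-8.0, 4.0))

        opt = minimize(self._profiled_nll, theta0, args=(layout, active_cols),
                       method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9})
        if not np.isfinite(opt.fun):
            raise RuntimeError(f"mixed-effects fit did not converge: {opt.message}")

        # boundary check: singular random terms are dropped and refitted
        sd_logs = np.asarray(opt.x[layout["sd_cols"]])
        singular = [c for c, l in zip(active_cols, sd_logs) if l <= _LOG_SD_FLOOR + 0.05]
        if singular and len(active_cols) > len(singular):
            names = [_COL_NAMES[c] for c in singular]
            warnings.warn(f"random effect(s) {names} singular; refitting without them")
            remaining = [c for c in active_cols if c not in singular]
            return self._fit(remaining, maxiter, _dropped=_dropped + names)

        nll, fitinfo = self._profiled_nll(opt.x, layout, active_cols, return_fit=True)
        beta = fitinfo["beta"]
        vcov_lin = np.linalg.inv(fitinfo["A"])
        J = _canonical_jacobian(beta)
        vcov = J @ vcov_lin @ J.T
        params = ModelParameters.from_array(_linear_to_canonical(beta), nu=1.0)
        se = {n: float(math.sqrt(max(vcov[i, i], 0.0)))
              for i, n in enumerate(("Q", "mu", "A", "P"))}

        # canonical random SDs (delta method through the (a, b) pair)
        sd_cols_map = {c: float(np.sqrt(g)) for c, g in
                       zip(active_cols, fitinfo["g_cols"][:len(active_cols)])}
        random_sd = {}
        if 0 in sd_cols_map:
            random_sd["Q"] = sd_cols_map[0]
        if 1 in sd_cols_map:
            random_sd["mu"] = sd_cols_map[1]
        if 2 in sd_cols_map or 3 in sd_cols_map:
            sa, sb = sd_cols_map.get(2, 0.0), sd_cols_map.get(3, 0.0)
            a_amp = params.amplitude
            a_lin, b_lin = beta[2], beta[3]
            if a_amp > 0:
                if "A" in self.random:
                    random_sd["A"] = math.hypot(a_lin * sa, b_lin * sb) / a_amp
                if "P" in self.random:
                    random_sd["P"] = math.hypot(b_lin * sa, a_lin * sb) / (_TWO_PI * a_amp ** 2)

        blups = self._blups(fitinfo, active_cols)
        r2, rmse_full, resid_fit = self._full_data_metrics(beta, blups)

        mult = {d: float(m) for d, m in zip(self.districts, fitinfo["mult"])}
        structure = (f"random={{{', '.join(self.random)}}} by {self.grouping}"
                     + (", varIdent(district)" if self.variance_by_district else ""))
        return MixedBurdenResults(
            model=self, params=params, se=se, vcov=vcov, beta=beta,
            random_sd=random_sd, random_sd_columns={_COL_NAMES[c]: v for c, v in sd_cols_map.items()},
            municipality_sd=(math.sqrt(fitinfo["g_muni"]) if self.nested else None),
            variance_multipliers=mult, sigma=math.sqrt(fitinfo["sigma2"]),
            loglik=-nll, n_params=4 + len(opt.x), converged=bool(opt.success),
            dropped_terms=_dropped, structure=structure, blups=blups,
            residuals=resid_fit, r_squared=r2, rmse_full=rmse_full,
        )

    def _blups(self, fitinfo, active_cols):
        """Conditional modes of the random effects, u = G Z' V^-1 r."""
        beta = fitinfo["beta"]
        rows = []
        for blk, (g, s) in zip(self._blocks, fitinfo["pieces"]):
            q = blk["Z"].shape[1]
            if q == 0:
                continue
            Ztr = blk["ZtW"][:, 4] - blk["ZtW"][:, :4] @ beta
            sg = np.sqrt(g)
            M = np.eye(q) + (sg[:, None] * blk["ZtZ"] * sg[None, :]) / s
            K = sg[:, None] * np.linalg.inv(M) * sg[None, :]
            ZtVinv_r = (Ztr - blk["ZtZ"] @ (K @ Ztr) / s) / s
            u = g * ZtVinv_r
            rec = {"district": blk["district"]}
            for i, c in enumerate(self.random_cols):
                rec[f"u_{_COL_NAMES[c]}"] = u[i]
            for j, mm in enumerate(blk["munis"]):
                rows.append(rec | {"municipality": mm,
                                   "u_muni": u[len(self.random_cols) + j]})
            if not blk["munis"]:
                rows.append(rec | {"municipality": None, "u_muni": 0.0})
        cols = (["district"] + [f"u_{_COL_NAMES[c]}" for c in self.random_cols]
                + ["municipality", "u_muni"])
        return pd.DataFrame(rows, columns=cols)

    def _full_data_metrics(self, beta, blups):
        """R^2 and RMSE on the full (unfiltered) data with BLUPs included;
        R^2 = 1 - RSS/TSS on the ln scale."""
        fd = self.full_data
        t = fd["t"].to_numpy(dtype=float)
        y = fd["ln_cs_c"].to_numpy(dtype=float)
        X = _design(t, 1.0)
        pred = environment_term(t, self.env) + X @ beta

        if not blups.empty:
            d_eff = blups.drop(columns=["municipality", "u_muni"]).drop_duplicates("district")
            d_eff = d_eff.set_index("district")
            for i, c in enumerate(self.random_cols):
                col = f"u_{_COL_NAMES[c]}"
                if col in d_eff:
                    u = fd["district"].map(d_eff[col]).fillna(0.0).to_numpy()
                    pred += u * X[:, c]
        if self.nested and "municipality" in fd.columns:
            m_eff = blups.set_index("municipality")["u_muni"]
            pred += fd["municipality"].map(m_eff).fillna(0.0).to_numpy()

        resid = y - pred
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else float("nan")
        rmse = float(np.sqrt(np.mean(resid ** 2)))

        # marginal residuals on the fit set (for diagnostics / comparison)
        tf = self.data["t"].to_numpy(dtype=float)
        yf = self.data["ln_cs_c"].to_numpy(dtype=float)
        resid_fit = yf - (environment_term(tf, self.env) + _design(tf, 1.0) @ beta)
        return r2, rmse, resid_fit


def compare_mixed(results: Sequence[MixedBurdenResults],
                  normality_p_floor: float = 1e-6) -> tuple[pd.DataFrame, int]:
    """Comparison table for mixed-effects structures fitted to the same
    records, with likelihood-ratio p-values where structures are nested
    (random terms a subset, grouping/variance flags not richer).

    Returns ``(table, preferred_index)``; the preferred structure is the
    converged fit with the best AIC among those whose residuals pass a weak
    Shapiro-Wilk normality screen (p above ``normality_p_floor``).
    """
    n0 = results[0].nobs
    for r in results[1:]:
        if r.nobs != n0:
            raise ValueError("results must come from the same filtered records")

    def _is_nested(a: MixedBurdenResults, b: MixedBurdenResults) -> bool:
        ma, mb = a.model, b.model
        return (set(ma.random) <= set(mb.random)
                and (not ma.nested or mb.nested)
                and (not ma.variance_by_district or mb.variance_by_district)
                and a.n_params < b.n_params)

    rows = []
    for i, r in enumerate(results):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_p = float(stats.shapiro(
                r.residuals if len(r.residuals) <= 5000 else r.residuals[:5000]).pvalue)
        lr_p = float("nan")
        for j, other in enumerate(results):
            if j != i and _is_nested(r, other):
                lr = 2.0 * (other.loglik - r.loglik)
                df = other.n_params - r.n_params
                lr_p = float(stats.chi2.sf(max(lr, 0.0), df))
                break
        rows.append({
            "structure": r.structure, "k": r.n_params, "loglik": r.loglik,
            "aic": r.aic, "lr_p_vs_larger": lr_p, "converged": r.converged,
            "shapiro_p": sw_p,
        })
    tab = pd.DataFrame(rows)
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    ok = tab.index[(tab["converged"]) & (tab["shapiro_p"] > normality_p_floor)]
    pool = ok if len(ok) else tab.index
    preferred = int(tab.loc[pool, "aic"].idxmin())
    return tab, preferred
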