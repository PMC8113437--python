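"""Fixed-effects estimation of the burden model.

Three estimators are exposed through :class:`BurdenModel`:

* multi-start nonlinear ordinary least squares (min-RMSE restart winner),
* robust M-regression (IRLS with a MAD scale; restart winner chosen by the
  smallest absolute median residual),
* nonlinear quantile regression (pinball loss) for the 25th/50th/75th
  percentiles, initialised from the robust fit.

For a *fixed* power ``nu`` the model is linear in (Q, mu, a, b) with
``a = A cos(2 pi P)``, ``b = A sin(2 pi P)`` on the covariates
``(1, T**nu, sin 2 pi T, cos 2 pi T)``, so closed-form / convex solvers are
used there (and serve as the oracle for the nonlinear path); only the
freely adjustable ``nu`` variant requires genuinely nonlinear optimisation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares, minimize

from .model import (
    NU_MIN,
    EnvironmentTerm,
    ModelParameters,
    environment_term,
    model_mean,
    summarize,
)

__all__ = [
    "BurdenModel",
    "BurdenFitResults",
    "RobustBurdenFitResults",
    "QuantileBurdenFitResults",
    "DiagnosticsReport",
    "compare_variants",
    "diagnose",
]

_TWO_PI = 2.0 * math.pi

VARIANT_NU = {"nu1": 1.0, "nu2": 2.0, "nu_free": None}
NU_MAX = 10.0  # conditioning bound for the freely adjustable power

#: Huber / Tukey bisquare tuning constants (95% Gaussian efficiency).
PSI_TUNING = {"huber": 1.345, "bisquare": 4.685}


# ---------------------------------------------------------------------------
# linear reparameterisation helpers

def _design(t: np.ndarray, nu: float) -> np.ndarray:
    """Covariates (1, T**nu, sin 2piT, cos 2piT) of the linearised model."""
    t = np.asarray(t, dtype=float)
    return np.column_stack([
        np.ones_like(t),
        np.power(t, nu),
        np.sin(_TWO_PI * t),
        np.cos(_TWO_PI * t),
    ])


def _linear_to_canonical(beta: np.ndarray) -> tuple[float, float, float, float]:
    """(b0, b1, b2, b3) -> (Q, mu, A, P): Q = b0, mu = -b1, A,P from (b2,b3)."""
    q, mu = beta[0], -beta[1]
    a_amp = math.hypot(beta[2], beta[3])
    phase = (math.atan2(beta[3], beta[2]) / _TWO_PI) % 1.0
    return q, mu, a_amp, phase


def _canonical_to_linear(params: ModelParameters) -> np.ndarray:
    return np.array([
        params.q,
        -params.mu,
        params.amplitude * math.cos(_TWO_PI * params.phase),
        params.amplitude * math.sin(_TWO_PI * params.phase),
    ])


def _canonical_jacobian(beta: np.ndarray) -> np.ndarray:
    """Jacobian d(Q, mu, A, P)/d(b0, b1, b2, b3) for vcov propagation."""
    b2, b3 = beta[2], beta[3]
    a = math.hypot(b2, b3)
    J = np.zeros((4, 4))
    J[0, 0] = 1.0
    J[1, 1] = -1.0
    if a > 0:
        J[2, 2] = b2 / a
        J[2, 3] = b3 / a
        J[3, 2] = -b3 / (_TWO_PI * a * a)
        J[3, 3] = b2 / (_TWO_PI * a * a)
    return J


# ---------------------------------------------------------------------------
# results objects

@dataclass
class BurdenFitResults:
    """Estimates, uncertainties and diagnostics hooks for one fit."""

    model: "BurdenModel"
    method: str
    variant: str
    params: ModelParameters
    se: dict
    vcov: np.ndarray
    param_names: list
    residuals: np.ndarray
    fittedvalues: np.ndarray
    rmse: float
    rss: float
    nobs: int
    k_params: int
    converged: bool = True
    n_restarts_used: int = 1
    objective: float = float("nan")
    linearized: Optional[ModelParameters] = None
    extra: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        """Gaussian AIC, n(ln(2 pi RSS/n) + 1) + 2(k+1); the +1 in the
        parameter count is the error variance.  Matches R's AIC for
        least-squares fits, so deltas are software independent."""
        n = self.nobs
        return n * (math.log(2 * math.pi * self.rss / n) + 1) + 2 * (self.k_params + 1)

    def predict(self, t) -> np.ndarray:
        return model_mean(t, self.params, self.model.env)

    def half_life(self, level: float = 0.95):
        from .model import ecological_half_life

        return ecological_half_life(self.params.mu, self.se["mu"], level=level)

    def seasonality(self, level: float = 0.95):
        from .model import seasonal_summaries

        return seasonal_summaries(
            self.params.amplitude, self.params.phase,
            self.se["A"], self.se["P"], level=level,
        )

    def summary_metrics(self, level: float = 0.95):
        return summarize(
            self.params.mu, self.se["mu"],
            self.params.amplitude, self.params.phase,
            self.se["A"], self.se["P"], level=level,
        )

    def diagnose(self, n_lags: int = 20) -> "DiagnosticsReport":
        return diagnose(self, n_lags=n_lags)

    def params_table(self) -> pd.DataFrame:
        vals = {"Q": self.params.q, "mu": self.params.mu,
                "A": self.params.amplitude, "P": self.params.phase}
        if "nu" in self.param_names:
            vals["nu"] = self.params.nu
        rows = [(name, vals[name], self.se.get(name, float("nan")))
                for name in self.param_names]
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"])

    def summary(self) -> str:
        lines = [
            f"Burden model fit ({self.method}, variant={self.variant})",
            f"  nobs = {self.nobs}, RMSE = {self.rmse:.4f} ln(Bq/kg), AIC = {self.aic:.1f}",
            f"  converged = {self.converged}, restarts used = {self.n_restarts_used}",
            "  parameter   estimate       se",
        ]
        for _, row in self.params_table().iterrows():
            lines.append(f"  {row['parameter']:<10}  {row['estimate']:9.4f}  {row['se']:8.4f}")
        hl, (lo, hi) = self.half_life()
        s = self.seasonality()
        lines.append(f"  ecological half-life = {hl:.3f} y (95% CI {lo:.3f}, {hi:.3f})")
        lines.append(
            f"  seasonal amplitude exp(A) = {s['amplitude_metric']:.3f}, "
            f"phase = {s['phase_months']:.3f} months"
        )
        return "\n".join(lines)


@dataclass
class RobustBurdenFitResults(BurdenFitResults):
    robustness_weights: np.ndarray = None
    scale: float = float("nan")
    median_residual: float = float("nan")


@dataclass
class QuantileBurdenFitResults(BurdenFitResults):
    tau: float = 0.5
    n_boot: int = 0


@dataclass(frozen=True)
class DiagnosticsReport:
    """Residual diagnostics for one fit (normality, shape, autocorrelation,
    time trend, and variance homogeneity across districts)."""

    shapiro_wilk_p: float
    skewness: float
    kurtosis: float  # Pearson definition; 3 for a normal distribution
    acf: np.ndarray  # lags 1..n_lags, residuals ordered by T
    acf_band: float  # +/- 1.96/sqrt(n)
    residual_trend_slope: float
    residual_trend_p: float
    fligner_killeen_p: Optional[float]


# ---------------------------------------------------------------------------
# the model object

class BurdenModel:
    """Radiocesium burden model bound to one data set.

    Parameters
    ----------
    data : DataFrame
        Must carry columns ``t`` (years since the accident) and ``ln_cs_c``
        (decay-corrected ln Bq/kg); a ``district`` column enables the
        variance-homogeneity diagnostic.
    env : EnvironmentTerm
        Two-isotope physical-decay environment term (known offset).
    variant : {"nu1", "nu2", "nu_free"}
        Treatment of the power parameter.
    """

    def __init__(self, data: pd.DataFrame, env: EnvironmentTerm, variant: str = "nu1"):
        if variant not in VARIANT_NU:
            raise ValueError(f"unknown variant {variant!r}")
        if len(data) < 10:
            raise ValueError("need at least 10 records to fit the burden model")
        self.data = data.reset_index(drop=True)
        self.env = env
        self.variant = variant
        self.t = self.data["t"].to_numpy(dtype=float)
        self.y = self.data["ln_cs_c"].to_numpy(dtype=float)
        self.x_env = environment_term(self.t, env)
        self.y_adj = self.y - self.x_env  # response net of the known offset

    @classmethod
    def from_dataframe(cls, data, env, variant="nu1", t_col="t", y_col="ln_cs_c"):
        d = data.rename(columns={t_col: "t", y_col: "ln_cs_c"})
        return cls(d, env, variant=variant)

    # -- generic dispatch --------------------------------------------------
    def fit(self, method: str = "robust", **kw):
        if method == "ols":
            return self.fit_ols(**kw)
        if method == "robust":
            return self.fit_robust(**kw)
        if method == "quantile":
            return self.fit_quantile(**kw)
        raise ValueError(f"unknown method {method!r}")

    # -- helpers -----------------------------------------------------------
    def _nu(self) -> Optional[float]:
        return VARIANT_NU[self.variant]

    def _param_names(self) -> list:
        return ["Q", "mu", "nu", "A", "P"] if self.variant == "nu_free" else ["Q", "mu", "A", "P"]

    def _residual_fn(self, theta: np.ndarray, nu: Optional[float]) -> np.ndarray:
        if nu is None:
            q, mu, nu_, a, p = theta
        else:
            q, mu, a, p = theta
            nu_ = nu
        nu_ = max(nu_, NU_MIN)
        pred = (
            self.x_env + q - mu * np.power(self.t, nu_)
            + a * np.sin(_TWO_PI * (self.t + p))
        )
        return self.y - pred

    def _linear_fit(self, nu: float, weights: Optional[np.ndarray] = None):
        """Exact (weighted) least squares on the linearised design."""
        X = _design(self.t, nu)
        y = self.y_adj
        if weights is not None:
            sw = np.sqrt(weights)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta, X

    def _start_values(self, nu: Optional[float]) -> np.ndarray:
        """Initial canonical parameters from the linearised solution (for
        nu_free: profile a coarse nu grid and keep the best)."""
        if nu is not None:
            beta, _ = self._linear_fit(nu)
            return np.array(_linear_to_canonical(beta))
        best = None
        for nu_try in np.linspace(NU_MIN, 4.0, 14):
            beta, X = self._linear_fit(nu_try)
            rss = float(np.sum((self.y_adj - X @ beta) ** 2))
            if best is None or rss < best[0]:
                best = (rss, nu_try, beta)
        _, nu0, beta = best
        q, mu, a, p = _linear_to_canonical(beta)
        return np.array([q, mu, nu0, a, p])

    def _perturbed_starts(self, theta0: np.ndarray, n_restarts: int, rng) -> np.ndarray:
        """Multiplicative N(1, 0.1^2) perturbations of the base start; the
        unperturbed start is always included."""
        starts = [theta0]
        for _ in range(max(n_restarts - 1, 0)):
            starts.append(theta0 * rng.normal(1.0, 0.1, size=theta0.size))
        return np.array(starts)

    def _ls_bounds(self, nu: Optional[float]):
        if nu is not None:
            return (-np.inf, np.inf)
        lo = np.full(5, -np.inf)
        hi = np.full(5, np.inf)
        lo[2], hi[2] = NU_MIN, NU_MAX
        return lo, hi

    # -- OLS ----------------------------------------------------------------
    def fit_ols(self, n_restarts: int = 2000, seed: Optional[int] = None,
                engine: str = "auto") -> BurdenFitResults:
        """Multi-start nonlinear least squares; min-RMSE restart wins.

        For fixed-``nu`` variants the closed-form linearised solution is
        exact, so ``engine='auto'`` uses it directly (and it is always
        recorded as ``result.linearized``); ``engine='multistart'`` forces
        the nonlinear optimiser, whose winner must agree with the closed
        form — a discrepancy beyond 1e-4 triggers a warning.
        """
        nu = self._nu()
        names = self._param_names()

        lin_params = None
        if nu is not None:
            beta, X = self._linear_fit(nu)
            lin_params = ModelParameters.from_array(_linear_to_canonical(beta), nu=nu)

        if engine == "auto" and nu is not None:
            resid = self.y_adj - X @ beta
            rss = float(resid @ resid)
            sigma2 = rss / (len(self.t) - 4)
            vcov_lin = sigma2 * np.linalg.inv(X.T @ X)
            J = _canonical_jacobian(beta)
            vcov = J @ vcov_lin @ J.T
            return self._pack(
                BurdenFitResults, "ols", lin_params, vcov, names, resid,
                converged=True, n_restarts_used=1, objective=rss,
                linearized=lin_params,
            )

        # nonlinear multi-start path
        rng = np.random.default_rng(seed)
        theta0 = self._start_values(nu)
        best = None
        n_ok = 0
        for start in self._perturbed_starts(theta0, n_restarts, rng):
            try:
                sol = least_squares(
                    self._residual_fn, start, args=(nu,),
                    bounds=self._ls_bounds(nu), xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            n_ok += 1
            rss = 2 * sol.cost
            if best is None or rss < best.cost * 2:
                best = sol
        if best is None:
            raise RuntimeError("all OLS restarts failed to converge")
        resid = self._residual_fn(best.x, nu)
        rss = float(resid @ resid)
        p = len(names)
        sigma2 = rss / (len(self.t) - p)
        Jr = best.jac  # d resid / d theta
        vcov = sigma2 * np.linalg.inv(Jr.T @ Jr)
        params = ModelParameters.from_array(best.x, nu=nu)
        if lin_params is not None:
            gap = np.max(np.abs(params.as_array() - lin_params.as_array()))
            if gap > 1e-4:
                warnings.warn(
                    f"multi-start OLS disagrees with the closed-form linearised "
                    f"solution by {gap:.2e}", RuntimeWarning,
                )
        return self._pack(
            BurdenFitResults, "ols", params, vcov, names, resid,
            converged=bool(best.success), n_restarts_used=n_ok, objective=rss,
            linearized=lin_params,
        )

    # -- robust ---------------------------------------------------------------
    def fit_robust(self, psi: str = "huber", n_restarts: int = 2000,
                   seed: Optional[int] = None, maxiter: int = 50,
                   engine: str = "auto") -> RobustBurdenFitResults:
        """M-estimation by iteratively reweighted least squares.

        For fixed-``nu`` variants the IRLS subproblem is linear, so the fit
        delegates to statsmodels' RLM (deterministic; restarts are moot).
        The freely adjustable ``nu`` variant runs the in-package multi-start
        IRLS, keeping the restart whose median residual is smallest in
        absolute value.  ``engine='irls'`` forces the in-package IRLS for
        any variant (used for cross-checking against RLM).
        """
        if psi not in PSI_TUNING:
            raise ValueError(f"unknown psi {psi!r}")
        nu = self._nu()
        names = self._param_names()

        if nu is not None and engine == "auto":
            import statsmodels.api as sm

            norm = (sm.robust.norms.HuberT(PSI_TUNING["huber"]) if psi == "huber"
                    else sm.robust.norms.TukeyBiweight(PSI_TUNING["bisquare"]))
            X = _design(self.t, nu)
            res = sm.RLM(self.y_adj, X, M=norm).fit(maxiter=maxiter)
            beta = np.asarray(res.params)
            vcov_lin = np.asarray(res.bcov_scaled)
            J = _canonical_jacobian(beta)
            vcov = J @ vcov_lin @ J.T
            params = ModelParameters.from_array(_linear_to_canonical(beta), nu=nu)
            resid = self.y_adj - X @ beta
            out = self._pack(
                RobustBurdenFitResults, "robust", params, vcov, names, resid,
                converged=True, n_restarts_used=1,
                objective=abs(float(np.median(resid))),
            )
            out.robustness_weights = np.asarray(res.weights)
            out.scale = float(res.scale)
            out.median_residual = float(np.median(resid))
            return out

        rng = np.random.default_rng(seed)
        theta0 = self._start_values(nu)
        best = None
        n_ok = 0
        for start in self._perturbed_starts(theta0, n_restarts, rng):
            fitres = self._irls_once(start, nu, psi, maxiter)
            if fitres is None:
                continue
            n_ok += 1
            if best is None or abs(fitres["median_resid"]) < abs(best["median_resid"]):
                best = fitres
        if best is None:
            raise RuntimeError("all robust restarts failed")
        params = ModelParameters.from_array(best["theta"], nu=nu)
        out = self._pack(
            RobustBurdenFitResults, "robust", params, best["vcov"], names,
            best["resid"], converged=best["converged"], n_restarts_used=n_ok,
            objective=abs(best["median_resid"]),
        )
        out.robustness_weights = best["weights"]
        out.scale = best["scale"]
        out.median_residual = best["median_resid"]
        return out

    def _irls_once(self, theta: np.ndarray, nu: Optional[float], psi: str,
                   maxiter: int):
        """One IRLS run from one start; weighted subproblems are solved in
        closed form for fixed nu, by nonlinear LS otherwise."""
        c = PSI_TUNING[psi]
        theta = theta.copy()
        converged = False
        weights = np.ones_like(self.t)
        scale = float("nan")
        for _ in range(maxiter):
            resid = self._residual_fn(theta, nu)
            scale = np.median(np.abs(resid)) / 0.6744897501960817
            if scale <= 0:
                converged = True
                break
            u = resid / scale
            if psi == "huber":
                weights = np.minimum(1.0, c / np.maximum(np.abs(u), 1e-12))
            else:
                weights = np.where(np.abs(u) < c, (1 - (u / c) ** 2) ** 2, 0.0)
            if nu is not None:
                X = _design(self.t, nu)
                sw = np.sqrt(weights)
                beta, *_ = np.linalg.lstsq(X * sw[:, None], self.y_adj * sw, rcond=None)
                new_theta = np.array(_linear_to_canonical(beta))
            else:
                sw = np.sqrt(weights)
                sol = least_squares(
                    lambda th: sw * self._residual_fn(th, nu), theta,
                    bounds=self._ls_bounds(nu), xtol=1e-12, ftol=1e-12,
                )
                if not np.all(np.isfinite(sol.x)):
                    return None
                new_theta = sol.x
            # compare on the sin/cos scale so phase wraps do not mask convergence
            if np.max(np.abs(new_theta - theta)) < 1e-10:
                theta = new_theta
                converged = True
                break
            theta = new_theta
        resid = self._residual_fn(theta, nu)
        # Huber-type asymptotic covariance on the Jacobian at the solution
        if nu is not None:
            Jr = _design(self.t, nu)
            Jc = _canonical_jacobian(_canonical_to_linear(ModelParameters.from_array(theta, nu=nu)))
        else:
            eps = np.sqrt(np.finfo(float).eps)
            Jr = np.empty((len(self.t), len(theta)))
            for j in range(len(theta)):
                dt = np.zeros_like(theta)
                dt[j] = eps * max(abs(theta[j]), 1.0)
                Jr[:, j] = (self._residual_fn(theta + dt, nu) - self._residual_fn(theta - dt, nu)) / (2 * dt[j])
            Jr = -Jr  # d mean / d theta
            Jc = np.eye(len(theta))
        u = resid / scale if scale > 0 else resid
        if psi == "huber":
            psi_u = np.clip(u, -c, c)
            dpsi = (np.abs(u) <= c).astype(float)
        else:
            inside = np.abs(u) < c
            psi_u = np.where(inside, u * (1 - (u / c) ** 2) ** 2, 0.0)
            dpsi = np.where(inside, (1 - (u / c) ** 2) * (1 - 5 * (u / c) ** 2), 0.0)
        n, p = len(resid), Jr.shape[1]
        m1 = max(np.mean(dpsi), 1e-8)
        num = scale ** 2 * np.sum(psi_u ** 2) / (n - p)
        try:
            vcov_lin = (num / m1 ** 2) * np.linalg.inv(Jr.T @ Jr)
        except np.linalg.LinAlgError:
            return None
        vcov = Jc @ vcov_lin @ Jc.T if nu is not None else vcov_lin
        return {
            "theta": theta, "resid": resid, "weights": weights, "scale": scale,
            "median_resid": float(np.median(resid)), "vcov": vcov,
            "converged": converged,
        }

    # -- quantile -------------------------------------------------------------
    def fit_quantile(self, tau: float = 0.5, init: Optional[ModelParameters] = None,
                     n_boot: int = 500, seed: Optional[int] = None) -> QuantileBurdenFitResults:
        """Quantile (pinball-loss) regression of the burden model at ``tau``.

        Fixed-``nu`` variants are solved on the linearised design with
        statsmodels' QuantReg; the free-``nu`` variant minimises the pinball
        loss directly (Nelder-Mead) from the robust-fit initial values.
        Standard errors come from a nonparametric bootstrap (``n_boot``
        resamples, seeded); phase draws are unwrapped to the branch nearest
        the point estimate before taking moments.
        """
        if not 0 < tau < 1:
            raise ValueError("tau must be in (0, 1)")
        if len(self.t) * min(tau, 1 - tau) < 5:
            raise ValueError("too few records for this quantile")
        nu = self._nu()
        names = self._param_names()
        rng = np.random.default_rng(seed)

        theta = self._quantile_point(self.t, self.y_adj, tau, nu, init)
        params = ModelParameters.from_array(theta, nu=nu)
        resid = self._residual_fn(theta, nu)
        objective = float(np.sum(resid * np.where(resid >= 0, tau, tau - 1)))

        draws = []
        n = len(self.t)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                th_b = self._quantile_point(
                    self.t[idx], self.y_adj[idx], tau, nu,
                    ModelParameters.from_array(theta, nu=nu),
                )
            except Exception:
                continue
            draws.append(th_b)
        if draws:
            D = np.array(draws)
            p_idx = names.index("P")
            # unwrap phases to the branch nearest the point estimate
            D[:, p_idx] = theta[p_idx] + ((D[:, p_idx] - theta[p_idx] + 0.5) % 1.0 - 0.5)
            vcov = np.cov(D, rowvar=False)
        else:
            vcov = np.full((len(names), len(names)), np.nan)

        out = self._pack(
            QuantileBurdenFitResults, "quantile", params, vcov, names, resid,
            converged=True, n_restarts_used=1, objective=objective,
        )
        out.tau = tau
        out.n_boot = len(draws)
        return out

    def _quantile_point(self, t, y_adj, tau, nu, init: Optional[ModelParameters]):
        if nu is not None:
            from statsmodels.regression.quantile_regression import QuantReg

            X = _design(t, nu)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = QuantReg(y_adj, X).fit(q=tau)
            return np.array(_linear_to_canonical(np.asarray(res.params)))
        if init is None:
            init = ModelParameters.from_array(self._start_values(nu))
        theta0 = init.as_array(include_nu=True)

        def loss(th):
            if not (NU_MIN <= th[2] <= NU_MAX):
                return 1e12
            q, mu, nu_, a, p = th
            pred = q - mu * np.power(t, nu_) + a * np.sin(_TWO_PI * (t + p))
            r = y_adj - pred
            return float(np.sum(r * np.where(r >= 0, tau, tau - 1)))

        sol = minimize(loss, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000})
        return sol.x

    # -- shared packing -------------------------------------------------------
    def _pack(self, cls, method, params, vcov, names, resid, **kw):
        vcov = np.asarray(vcov, dtype=float)
        se = {name: float(np.sqrt(max(vcov[i, i], 0.0))) if np.isfinite(vcov[i, i]) else float("nan")
              for i, name in enumerate(names)}
        fitted = self.y - resid
        rss = float(resid @ resid)
        return cls(
            model=self, method=method, variant=self.variant, params=params,
            se=se, vcov=vcov, param_names=list(names), residuals=np.asarray(resid),
            fittedvalues=fitted, rmse=math.sqrt(np.mean(resid ** 2)), rss=rss,
            nobs=len(resid), k_params=len(names), **kw,
        )


# ---------------------------------------------------------------------------
# model comparison and diagnostics

def compare_variants(results: dict) -> pd.DataFrame:
    """AIC table across model variants fitted to the same records.

    AIC uses the full Gaussian form (see ``BurdenFitResults.aic``), so the
    deltas — the quantity that matters — match any software using the
    standard least-squares likelihood.
    """
    items = list(results.items())
    n0 = items[0][1].nobs
    y0 = items[0][1].model.y
    for _, res in items[1:]:
        if res.nobs != n0 or not np.array_equal(res.model.y, y0):
            raise ValueError("variants must be fitted to the same records")
    rows = [
        {"variant": name, "k": res.k_params, "rss": res.rss,
         "rmse": res.rmse, "aic": res.aic}
        for name, res in items
    ]
    tab = pd.DataFrame(rows)
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    return tab.sort_values("aic").reset_index(drop=True)


def diagnose(result: BurdenFitResults, n_lags: int = 20) -> DiagnosticsReport:
    """Residual diagnostics: Shapiro-Wilk, skewness/kurtosis, time-ordered
    autocorrelations with +/-1.96/sqrt(n) bands, residual-vs-T trend, and
    (when districts are present) the Fligner-Killeen variance-homogeneity
    test of the response across districts."""
    resid = np.asarray(result.residuals)
    n = len(resid)
    if n < 3:
        raise ValueError("need at least 3 residuals for diagnostics")
    t = result.model.t
    order = np.argsort(t, kind="stable")
    r_time = resid[order]

    sw_p = float(stats.shapiro(resid if n <= 5000 else resid[:5000]).pvalue)
    skew = float(stats.skew(resid))
    kurt = float(stats.kurtosis(resid, fisher=False))

    n_lags = min(n_lags, n - 2)
    rc = r_time - r_time.mean()
    denom = float(rc @ rc)
    acf = np.array([
        float(rc[k:] @ rc[:-k]) / denom for k in range(1, n_lags + 1)
    ])

    slope, _, _, trend_p, _ = stats.linregress(t, resid)

    fk_p = None
    if "district" in result.model.data.columns:
        groups = [g.to_numpy() for _, g in result.model.data.groupby("district")["ln_cs_c"]]
        groups = [g for g in groups if len(g) >= 3]
        if len(groups) >= 2 and any(np.ptp(g) > 0 for g in groups):
            fk_p = float(stats.fligner(*groups).pvalue)

    return DiagnosticsReport(
        shapiro_wilk_p=sw_p, skewness=skew, kurtosis=kurt,
        acf=acf, acf_band=1.96 / math.sqrt(n),
        residual_trend_slope=float(slope), residual_trend_p=float(trend_p),
        fligner_killeen_p=fk_p,
    )
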