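"""Core burden model: environment term, mean function and derived summaries.

The model describes the natural log of the total radiocesium activity
concentration (Bq/kg) in animal tissue at time ``T`` years after the
accident as

    LnCs_c(T) = X(T) + Q - mu * T**nu + A * sin(2*pi*(T + P))

where ``X(T)`` is the ln of the physically decaying two-isotope environment
activity,

    X(T) = ln[ exp(i134) * 2**(-T/Th134) + exp(i137) * 2**(-T/Th137) ],

``Q`` relates tissue concentration (Bq/kg) to environmental deposition
(Bq/m^2) on the log scale, ``mu`` (1/y) is the net *ecological* loss rate
(every process except physical decay), ``nu`` a power shaping the time
course, and ``A``/``P`` the amplitude (ln Bq/kg) and phase (fraction of a
year) of a seasonal sinusoid with a fixed one-year period.

Derived summaries: the ecological half-life ln(2)/mu, the seasonal
amplitude exp(A) (and its peak-to-trough fold exp(2A)), and the phase
expressed in months, 12*P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .constants import DEFAULT_CONSTANTS, IsotopeConstants

__all__ = [
    "NU_MIN",
    "ModelParameters",
    "EnvironmentTerm",
    "SummaryMetrics",
    "environment_term",
    "model_mean",
    "canonicalize",
    "ecological_half_life",
    "seasonal_summaries",
]

#: Lower bound on the power parameter nu.
NU_MIN = 0.1

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ModelParameters:
    """Adjustable parameters (Q, mu, nu, A, P) of the burden model.

    ``A`` and ``P`` are stored in canonical form: ``A >= 0`` and
    ``P in [0, 1)``.  Use :func:`canonicalize` to normalise arbitrary
    (A, P) pairs; ``ModelParameters`` does this on construction.
    """

    q: float
    mu: float
    amplitude: float
    phase: float
    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.nu < NU_MIN:
            raise ValueError(f"nu must be >= {NU_MIN}, got {self.nu}")
        a, p = canonicalize(self.amplitude, self.phase)
        object.__setattr__(self, "amplitude", a)
        object.__setattr__(self, "phase", p)

    def as_array(self, include_nu: bool = False) -> np.ndarray:
        vals = [self.q, self.mu, self.amplitude, self.phase]
        if include_nu:
            vals.insert(2, self.nu)
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_array(cls, theta: Iterable[float], nu: float | None = None) -> "ModelParameters":
        theta = list(theta)
        if nu is None:  # theta carries nu in slot 2
            q, mu, nu_, a, p = theta
            return cls(q=q, mu=mu, nu=nu_, amplitude=a, phase=p)
        q, mu, a, p = theta
        return cls(q=q, mu=mu, nu=nu, amplitude=a, phase=p)

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class EnvironmentTerm:
    """Intercepts and physical half-lives behind the environment term X(T).

    ``ln_cs134_t0`` / ``ln_cs137_t0`` are ln-scale activity intercepts of the
    two isotopes at T = 0 (robust-regression intercepts when estimated from
    per-isotope monitoring data)."""

    ln_cs134_t0: float
    ln_cs137_t0: float
    constants: IsotopeConstants = field(default=DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ln_cs134_t0) and np.isfinite(self.ln_cs137_t0)):
            raise ValueError("environment intercepts must be finite")

    def x(self, t):
        """Evaluate X(T); vectorised over ``t`` (years, >= 0)."""
        return environment_term(t, self)


def environment_term(t, env: EnvironmentTerm):
    """ln of the summed, physically decaying two-isotope environment activity.

    X(T) = ln[exp(i134) 2^(-T/Th134) + exp(i137) 2^(-T/Th137)].  Strictly
    decreasing in T; its slope runs from a 134-weighted mixture of the two
    pure-isotope decay slopes toward -ln2/Th137 as the short-lived isotope
    dies away.
    """
    t = np.asarray(t, dtype=float)
    c = env.constants
    ln2 = math.log(2.0)
    a = env.ln_cs134_t0 - t * (ln2 / c.th_cs134)
    b = env.ln_cs137_t0 - t * (ln2 / c.th_cs137)
    return np.logaddexp(a, b)


def model_mean(t, params: ModelParameters, env: EnvironmentTerm):
    """Model-predicted LnCs_c at time ``t`` (vectorised)."""
    if params.nu < NU_MIN:
        raise ValueError(f"nu must be >= {NU_MIN}")
    t = np.asarray(t, dtype=float)
    x = environment_term(t, env)
    seasonal = params.amplitude * np.sin(_TWO_PI * (t + params.phase))
    return x + params.q - params.mu * np.power(t, params.nu) + seasonal


def canonicalize(amplitude: float, phase: float) -> tuple[float, float]:
    """Map an (A, P) pair to the canonical representative A >= 0, P in [0,1).

    A*sin(2*pi*(T+P)) is unchanged: a negative amplitude is absorbed by a
    half-period phase shift, and the phase is reduced modulo 1.
    """
    a, p = float(amplitude), float(phase)
    if a < 0:
        a, p = -a, p + 0.5
    p = p % 1.0
    if p >= 1.0:  # -tiny % 1.0 rounds up to exactly 1.0
        p = 0.0
    return a, p


@dataclass(frozen=True)
class SummaryMetrics:
    """Derived summaries of a fitted burden model (one estimation method).

    ``half_life`` is the ecological half-life ln2/mu in years; its upper
    confidence bound (and the point itself) is +inf when the uncertainty on
    mu extends to non-positive values.  ``amplitude_metric`` is exp(A) and
    ``peak_trough_fold`` exp(2A); ``phase_months`` is 12*P; the seasonal peak
    falls at ``peak_fraction_of_year`` = (0.25 - P) mod 1 of each year after
    the accident anniversary.
    """

    half_life: float
    half_life_ci: tuple[float, float]
    amplitude_metric: float
    amplitude_ci: tuple[float, float]
    peak_trough_fold: float
    phase_months: float
    phase_months_ci: tuple[float, float]
    peak_fraction_of_year: float


def ecological_half_life(mu: float, se_mu: float = 0.0, level: float = 0.95):
    """Point estimate and Wald CI for the ecological half-life ln2/mu.

    The CI maps the Wald interval for mu through the (monotone decreasing)
    transform ln2/mu.  Whenever the interval for mu reaches zero or below,
    the corresponding half-life bound is +inf; a non-positive mu itself
    yields an infinite point estimate (no net ecological decline).
    """
    if se_mu < 0:
        raise ValueError("se_mu must be >= 0")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    ln2 = math.log(2.0)
    point = ln2 / mu if mu > 0 else math.inf
    lo_mu, hi_mu = mu - z * se_mu, mu + z * se_mu
    lower = ln2 / hi_mu if hi_mu > 0 else math.inf
    upper = ln2 / lo_mu if lo_mu > 0 else math.inf
    return point, (lower, upper)


def seasonal_summaries(
    amplitude: float,
    phase: float,
    se_amplitude: float = 0.0,
    se_phase: float = 0.0,
    level: float = 0.95,
) -> dict:
    """Seasonality summaries with delta-method confidence intervals.

    amplitude_metric = exp(A) (CI exp(A +/- z*se_A), i.e. delta method on
    the log scale); peak_trough_fold = exp(2A); phase_months = 12*P with a
    plain linear CI (the oscillation period is fixed at one year, so no
    circular-statistics machinery is used).
    """
    from scipy.stats import norm

    a, p = canonicalize(amplitude, phase)
    z = norm.ppf(0.5 + level / 2.0)
    return {
        "amplitude_metric": math.exp(a),
        "amplitude_ci": (math.exp(a - z * se_amplitude), math.exp(a + z * se_amplitude)),
        "peak_trough_fold": math.exp(2 * a),
        "phase_months": 12.0 * p,
        "phase_months_ci": (12.0 * (p - z * se_phase), 12.0 * (p + z * se_phase)),
        "peak_fraction_of_year": (0.25 - p) % 1.0,
    }


def summarize(mu, se_mu, amplitude, phase, se_amplitude=0.0, se_phase=0.0, level=0.95) -> SummaryMetrics:
    """Bundle half-life and seasonality summaries into one record."""
    hl, hl_ci = ecological_half_life(mu, se_mu, level=level)
    s = seasonal_summaries(amplitude, phase, se_amplitude, se_phase, level=level)
    return SummaryMetrics(
        half_life=hl,
        half_life_ci=hl_ci,
        amplitude_metric=s["amplitude_metric"],
        amplitude_ci=s["amplitude_ci"],
        peak_trough_fold=s["peak_trough_fold"],
        phase_months=s["phase_months"],
        phase_months_ci=s["phase_months_ci"],
        peak_fraction_of_year=s["peak_fraction_of_year"],
    )
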