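"""Physical constants for the two cesium isotopes released by the accident.

The environment term of the burden model tracks the physical decay of
:sup:`134`Cs (half-life ~2.07 y) and :sup:`137`Cs (half-life ~30.1 y) from a
common release date.  Everything here is configurable so that the same
machinery can be pointed at a different source term (e.g. Chernobyl-era
ratios) if needed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

#: Days per year used everywhere a calendar date is converted to decimal years.
DAYS_PER_YEAR = 365.25

#: Date of the Fukushima Daiichi accident; T = 0 of the time axis.
FUKUSHIMA_ACCIDENT_DATE = _dt.date(2011, 3, 11)


@dataclass(frozen=True)
class IsotopeConstants:
    """Half-lives and source-term composition of the cesium pair.

    Parameters
    ----------
    th_cs134, th_cs137 : float
        Physical half-lives in years (standard nuclide data).
    accident_date : datetime.date
        Release date; origin of the time axis.
    release_activity_ratio_134_137 : float
        Activity ratio 134Cs:137Cs at the accident date.  Close to 1 for the
        Fukushima source term.  Used to split a total activity into isotope
        components when per-isotope measurements are absent.
    """

    th_cs134: float = 2.0652
    th_cs137: float = 30.08
    accident_date: _dt.date = field(default=FUKUSHIMA_ACCIDENT_DATE)
    release_activity_ratio_134_137: float = 1.0

    def __post_init__(self) -> None:
        if self.th_cs134 <= 0 or self.th_cs137 <= 0:
            raise ValueError("isotope half-lives must be positive")
        if self.release_activity_ratio_134_137 <= 0:
            raise ValueError("release activity ratio must be positive")

    def fraction_cs134(self, t_years: float) -> float:
        """Fraction of total cesium activity contributed by 134Cs at time
        ``t_years`` after the accident, given the release ratio and pure
        physical decay of each isotope."""
        import numpy as np

        r = self.release_activity_ratio_134_137
        a134 = r * np.exp2(-np.asarray(t_years, dtype=float) / self.th_cs134)
        a137 = 1.0 * np.exp2(-np.asarray(t_years, dtype=float) / self.th_cs137)
        return a134 / (a134 + a137)


#: Default constants for the Fukushima analyses.
DEFAULT_CONSTANTS = IsotopeConstants()
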