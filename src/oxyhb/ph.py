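"""pH standardization of P50 and the Bohr coefficient.

Within one (condition, temperature) group, log10 P50 is regressed on pH and
the fitted line is used to interpolate P50 at a reference pH (7.20 for adult
hemoglobins, 7.10 for prenatal isoforms). The slope of the same kind of line,
restricted to the pH window 6.9-7.8, is the Bohr coefficient
phi = dlogP50/dpH (negative for the alkaline Bohr effect).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import FitError, GroupingError
from .hill import HillFit

logger = logging.getLogger(__name__)

#: default inclusive pH window for the Bohr coefficient
BOHR_PH_RANGE = (6.9, 7.8)


@dataclasses.dataclass(frozen=True)
class PHRegression:
    """OLS line of log10 P50 against pH for one (condition, temperature)."""

    condition_label: str
    temperature: float  # kelvin
    slope: float
    intercept: float
    se_slope: float
    resid_var: float  # residual variance s^2 (0 for a saturated 2-point fit)
    n_fits: int
    ph_mean: float
    ph_sxx: float  # sum of squared pH deviations
    ph_range: tuple[float, float]

    def predict(self, ph: float) -> float:
        """Fitted log10 P50 at the given pH."""
        return self.slope * ph + self.intercept

    def se_pred(self, ph: float) -> float:
        """SE of the regression estimate (mean response) at the given pH.

        Standard OLS form s * sqrt(1/n + (ph - mean)^2 / Sxx); minimized at
        the mean pH of the inputs.
        """
        return math.sqrt(
            self.resid_var * (1.0 / self.n_fits + (ph - self.ph_mean) ** 2 / self.ph_sxx)
        )


def fit_logp50_vs_ph(
    fits: Sequence[tuple[float, HillFit]],
    condition_label: str = "",
    temperature: float = float("nan"),
    weighted: bool = False,
) -> PHRegression:
    """Regress log10 P50 on pH across Hill fits of one condition group.

    Parameters
    ----------
    fits
        (pH, HillFit) pairs sharing chemical condition and temperature.
    weighted
        If True, weight each point by 1/se_log_p50^2 (inverse variance).
        Default is the plain OLS the Hill-plot protocol implies.
    """
    if len(fits) < 2:
        raise FitError("need >= 2 Hill fits for a logP50-vs-pH regression")
    ph = np.array([p for p, _ in fits], dtype=float)
    y = np.array([f.log_p50 for _, f in fits], dtype=float)
    if np.ptp(ph) == 0.0:
        raise FitError("all pH values identical; slope undefined")

    X = sm.add_constant(ph)
    if weighted:
        se = np.array([f.se_log_p50 for _, f in fits], dtype=float)
        if np.any(se <= 0):
            raise FitError("weighted regression requires positive per-fit SEs")
        model = sm.WLS(y, X, weights=1.0 / se**2)
    else:
        model = sm.OLS(y, X)
    res = model.fit()
    intercept, slope = res.params
    dof = len(fits) - 2
    resid_var = float(res.ssr / dof) if dof > 0 else 0.0
    se_slope = float(res.bse[1]) if dof > 0 else 0.0
    sxx = float(np.sum((ph - ph.mean()) ** 2))

    return PHRegression(
        condition_label=condition_label,
        temperature=temperature,
        slope=float(slope),
        intercept=float(intercept),
        se_slope=se_slope,
        resid_var=resid_var,
        n_fits=len(fits),
        ph_mean=float(ph.mean()),
        ph_sxx=sxx,
        ph_range=(float(ph.min()), float(ph.max())),
    )


def p50_at_ph(reg: PHRegression, ph_ref: float) -> tuple[float, float]:
    """Standardized P50 (mm Hg) and its SE at a reference pH.

    The SE of the regression estimate on the log10 scale is pushed through
    the exponential link to first order: se_p50 = ln(10) * p50 * se_pred.
    """
    lo, hi = reg.ph_range
    if ph_ref < lo - 0.5 or ph_ref > hi + 0.5:
        logger.warning(
            "reference pH %.2f extrapolates > 0.5 units beyond fitted range "
            "[%.2f, %.2f] (%s)",
            ph_ref,
            lo,
            hi,
            reg.condition_label,
        )
    log_p50 = reg.predict(ph_ref)
    p50 = 10.0**log_p50
    se = math.log(10.0) * p50 * reg.se_pred(ph_ref)
    return p50, se


@dataclasses.dataclass(frozen=True)
class BohrResult:
    """Bohr coefficient phi = dlogP50/dpH over the standard pH window."""

    phi: float
    se: float
    n_used: int
    n_excluded: int
    ph_window: tuple[float, float]


def bohr_coefficient(
    fits: Sequence[tuple[float, HillFit]],
    ph_window: tuple[float, float] = BOHR_PH_RANGE,
) -> BohrResult:
    """Bohr coefficient from the OLS slope over the (inclusive) pH window."""
    lo, hi = ph_window
    inside = [(p, f) for p, f in fits if lo <= p <= hi]
    n_excluded = len(fits) - len(inside)
    if n_excluded:
        logger.info(
            "Bohr fit: excluded %d point(s) outside pH [%.2f, %.2f]",
            n_excluded,
            lo,
            hi,
        )
    distinct = {p for p, _ in inside}
    if len(distinct) < 2:
        raise FitError(
            f"Bohr coefficient needs >= 2 distinct pH values in [{lo}, {hi}]"
        )
    reg = fit_logp50_vs_ph(inside)
    return BohrResult(
        phi=reg.slope,
        se=reg.se_slope,
        n_used=len(inside),
        n_excluded=n_excluded,
        ph_window=ph_window,
    )


def check_same_temperature(regs: Sequence[PHRegression]) -> None:
    temps = {round(r.temperature, 6) for r in regs}
    if len(temps) > 1:
        raise GroupingError(f"regressions mix temperatures: {sorted(temps)}")
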