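"""Hill-plot linearization and estimation of P50 and n50.

A saturation-tension series is transformed to Hill coordinates
``y = log10[S/(1-S)]`` against ``x = log10 PO2`` and fitted by ordinary
least squares. The slope is the cooperativity coefficient n50; the
x-intercept (-intercept/slope) is log10 P50. Standard errors come from the
OLS coefficient covariance; the x-intercept SE uses a first-order
(delta-method) expansion in (intercept, slope).

Points are restricted by protocol to the 30-70% saturation band, where the
logit transform's heteroscedasticity is mild, so the fit is unweighted.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .errors import FitError
from .io import OECSeries

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class HillFit:
    """P50/n50 estimate from one Hill-plot regression.

    SEs are per-fit regression standard errors (not across-replicate SEMs)
    propagated from the 2x2 coefficient covariance.
    """

    log_p50: float
    p50: float
    n50: float
    se_log_p50: float
    se_n50: float
    r2: float
    n_points: int
    dof: int

    @property
    def se_p50(self) -> float:
        """SE of P50 on the mm Hg scale (log10 link, first order)."""
        return math.log(10.0) * self.p50 * self.se_log_p50


def hill_transform(series: OECSeries) -> list[tuple[float, float]]:
    """Map each (PO2, S) point to Hill coordinates (log10 PO2, logit10 S)."""
    out = []
    for p, s in zip(series.po2, series.saturation):
        if not (0.0 < s < 1.0):
            raise FitError(f"saturation {s} outside (0, 1); logit undefined")
        out.append((math.log10(p), math.log10(s / (1.0 - s))))
    return out


def fit_hill(series: OECSeries) -> HillFit:
    """Fit the Hill line by OLS and return P50, n50, SEs and r^2.

    Raises
    ------
    FitError
        If all tensions coincide (rank deficiency) or the fitted slope is
        non-positive (non-cooperative/degenerate series).
    """
    xy = np.asarray(hill_transform(series), dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    n = len(x)
    if np.ptp(x) == 0.0:
        raise FitError(
            f"series {series.sample_id}: all PO2 identical; Hill slope undefined"
        )
    dof = n - 2
    if dof < 1:
        raise FitError(f"series {series.sample_id}: need >= 3 points for SEs")

    design = np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    intercept, slope = coef
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)

    sigma2 = ss_res / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)

    if slope <= 0:
        raise FitError(
            f"series {series.sample_id}: non-positive Hill slope {slope:.3g}"
        )

    log_p50 = -intercept / slope
    # delta method for f(a, b) = -a/b: grad = (-1/b, a/b^2)
    grad = np.array([-1.0 / slope, intercept / slope**2])
    se_log_p50 = float(np.sqrt(grad @ cov @ grad))
    se_n50 = float(np.sqrt(cov[1, 1]))

    p50 = 10.0**log_p50
    lo, hi = series.po2_array.min(), series.po2_array.max()
    if not (lo <= p50 <= hi):
        logger.warning(
            "series %s: P50 %.3g mm Hg outside measured range [%.3g, %.3g]",
            series.sample_id,
            p50,
            lo,
            hi,
        )

    return HillFit(
        log_p50=float(log_p50),
        p50=float(p50),
        n50=float(slope),
        se_log_p50=se_log_p50,
        se_n50=se_n50,
        r2=float(r2),
        n_points=n,
        dof=dof,
    )
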