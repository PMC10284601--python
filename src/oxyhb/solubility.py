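"""Relative hemoglobin solubility from ammonium-sulfate precipitation.

Each sample's soluble signal is normalized to its own 0 M control, so the
percentage precipitated at a given salt molarity is

    100 * (1 - signal(M) / signal(0 M)),

interpolated linearly between measured molarities when needed. A
two-parameter logistic summarizes the salting-out curve: soluble fraction
= 1 / (1 + exp((M - midpoint) / slope)); a higher midpoint means a more
soluble protein.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError
from .io import SolubilitySeries

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SolubilityResult:
    """Per-sample salting-out summary."""

    sample_id: str
    percent_precipitated_at_3M: float | None
    curve: tuple[tuple[float, float], ...]  # (molarity, percent precipitated)
    midpoint_molarity: float
    slope: float
    no_transition: bool  # midpoint beyond the measured range


def _soluble_fraction(series: SolubilitySeries) -> tuple[np.ndarray, np.ndarray]:
    control = series.control_signal
    if control <= 0:
        raise ValidationError(
            f"series {series.sample_id}: 0 M control signal must be positive"
        )
    ms = np.asarray(series.ammonium_sulfate, dtype=float)
    frac = np.asarray(series.soluble_signal, dtype=float) / control
    return ms, frac


def percent_precipitated(series: SolubilitySeries, molarity: float) -> float:
    """Percent of hemoglobin precipitated at the given salt molarity.

    Small negative values (soluble signal above the control, measurement
    noise) are clamped to 0 and logged. Requests outside the measured
    molarity range are an error rather than an extrapolation.
    """
    ms, frac = _soluble_fraction(series)
    if molarity < ms.min() or molarity > ms.max():
        raise ValidationError(
            f"molarity {molarity} outside measured range "
            f"[{ms.min()}, {ms.max()}] for {series.sample_id}"
        )
    # duplicates: average fractions at equal molarity before interpolation
    uniq, inv = np.unique(ms, return_inverse=True)
    mean_frac = np.bincount(inv, weights=frac) / np.bincount(inv)
    value = 100.0 * (1.0 - float(np.interp(molarity, uniq, mean_frac)))
    if value < 0:
        logger.info(
            "series %s: %.3g%% precipitated at %.2f M clamped to 0",
            series.sample_id,
            value,
            molarity,
        )
        value = 0.0
    return min(value, 100.0)


def fit_salting_out(series: SolubilitySeries) -> tuple[float, float]:
    """Least-squares logistic fit of soluble fraction vs molarity.

    Returns (midpoint molarity, steepness). When the series never drops
    below half its control (no transition inside the measured range) the
    fitted midpoint lies beyond the data and a warning is logged.
    """
    ms, frac = _soluble_fraction(series)
    if len(np.unique(ms)) < 4:
        raise FitError(
            f"series {series.sample_id}: need >= 4 distinct molarities "
            "for the salting-out fit"
        )
    rises = np.diff(frac[np.argsort(ms, kind="stable")])
    if np.any(rises > 0.10):
        logger.warning(
            "series %s: soluble fraction rises > 10 points with molarity; "
            "fit may be unreliable",
            series.sample_id,
        )

    def logistic(m, midpoint, slope):
        return 1.0 / (1.0 + np.exp((m - midpoint) / slope))

    # midpoint guess: first molarity where the fraction crosses 0.5
    below = np.nonzero(frac <= 0.5)[0]
    mid0 = float(ms[below[0]]) if below.size else float(ms.max()) + 0.5
    try:
        popt, _ = curve_fit(
            logistic,
            ms,
            frac,
            p0=[mid0, 0.2],
            bounds=([0.0, 1e-4], [20.0, 5.0]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitError(f"salting-out fit failed for {series.sample_id}: {exc}")
    midpoint, slope = float(popt[0]), float(popt[1])
    if midpoint > ms.max():
        logger.warning(
            "series %s: no salting-out transition observed within %.2f M "
            "(fitted midpoint %.2f M)",
            series.sample_id,
            ms.max(),
            midpoint,
        )
    return midpoint, slope


def analyze_solubility(series: SolubilitySeries) -> SolubilityResult:
    """Full per-sample summary: 3 M precipitation, curve, logistic parameters."""
    ms, _ = _soluble_fraction(series)
    curve = tuple(
        (float(m), percent_precipitated(series, float(m))) for m in np.unique(ms)
    )
    midpoint, slope = fit_salting_out(series)
    pct3 = percent_precipitated(series, 3.0) if ms.max() >= 3.0 else None
    return SolubilityResult(
        sample_id=series.sample_id,
        percent_precipitated_at_3M=pct3,
        curve=curve,
        midpoint_molarity=midpoint,
        slope=slope,
        no_transition=midpoint > float(ms.max()),
    )
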