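"""Apparent enthalpy of oxygenation via the van't Hoff isochore.

From P50 measured at two temperatures,

    dH = 2.303 R (log10 P50(T1) - log10 P50(T2)) / (1/T1 - 1/T2),   T1 < T2

in kJ per mol O2. P50 rising with temperature gives dH < 0 (exothermic
oxygenation), the normal hemoglobin behaviour. Because P50 is measured as a
gas tension, the estimate includes the exothermic heat of dissolving O2 in
water; the corrected overall enthalpy adds back the solubilization heat
(+12.55 kJ mol^-1 O2 by default), moving dH toward less exothermic values.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

from .config import GAS_CONSTANT
from .errors import GroupingError, ValidationError
from .ph import PHRegression, p50_at_ph

SOLUBILIZATION_KJ = 12.55  # heat of O2 solution, kJ mol^-1 O2


@dataclasses.dataclass(frozen=True)
class ThermalResult:
    """van't Hoff enthalpy between two temperatures at one reference pH."""

    condition_label: str
    ph_ref: float
    t1: float  # kelvin, lower
    t2: float  # kelvin, higher
    dh_raw: float  # kJ mol^-1 O2, gas-tension based
    dh_corrected: float  # kJ mol^-1 O2, after solubilization correction
    se_dh: float


def vant_hoff_dh(
    p50_low_t: float,
    p50_high_t: float,
    t1: float,
    t2: float,
    gas_constant: float = GAS_CONSTANT,
) -> float:
    """Apparent enthalpy (kJ mol^-1 O2) from P50 at two temperatures (K)."""
    if t1 >= t2:
        raise ValidationError(f"need t1 < t2, got {t1} >= {t2}")
    if p50_low_t <= 0 or p50_high_t <= 0:
        raise ValidationError("P50 values must be positive")
    dlog = math.log10(p50_low_t) - math.log10(p50_high_t)
    dh_j = 2.303 * gas_constant * dlog / (1.0 / t1 - 1.0 / t2)
    return dh_j / 1000.0


def correct_solubilization(
    dh_raw: float, correction_kj: float = SOLUBILIZATION_KJ
) -> float:
    """Overall enthalpy dH' after removing the heat of O2 solubilization."""
    if not math.isfinite(dh_raw):
        raise ValidationError("dh_raw must be finite")
    return dh_raw + correction_kj


def thermal_summary(
    regs_by_temp: Mapping[float, PHRegression],
    ph_ref: float,
    condition_label: str = "",
    gas_constant: float = GAS_CONSTANT,
    correction_kj: float = SOLUBILIZATION_KJ,
) -> ThermalResult:
    """dH between exactly two temperatures from pH-standardized P50 values.

    ``regs_by_temp`` maps kelvin temperature to the condition's
    logP50-vs-pH regression at that temperature. The SE combines the two
    prediction SEs on the log10 scale (independent series).
    """
    if len(regs_by_temp) != 2:
        raise GroupingError(
            f"thermal analysis needs exactly 2 temperatures, got {len(regs_by_temp)}"
        )
    t1, t2 = sorted(regs_by_temp)
    p50_1, _ = p50_at_ph(regs_by_temp[t1], ph_ref)
    p50_2, _ = p50_at_ph(regs_by_temp[t2], ph_ref)
    dh_raw = vant_hoff_dh(p50_1, p50_2, t1, t2, gas_constant)

    se_log = math.hypot(
        regs_by_temp[t1].se_pred(ph_ref), regs_by_temp[t2].se_pred(ph_ref)
    )
    se_dh = 2.303 * gas_constant * se_log / abs(1.0 / t1 - 1.0 / t2) / 1000.0

    return ThermalResult(
        condition_label=condition_label,
        ph_ref=ph_ref,
        t1=t1,
        t2=t2,
        dh_raw=dh_raw,
        dh_corrected=correct_solubilization(dh_raw, correction_kj),
        se_dh=se_dh,
    )
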