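"""Allosteric-effector effect sizes from pH-standardized P50 values.

An effector effect is the difference of standardized log10 P50 between an
effector condition and the stripped (effector-free) protein at the same
reference pH and temperature, e.g. the DPG effect
logP50(DPG) - logP50(stripped). Being a log-ratio, it is dimensionless and
independent of the P50 scale. SEs combine the two regression-estimate SEs
assuming the condition series are independent experiments.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

from .errors import GroupingError
from .ph import PHRegression

STRIPPED = "stripped"
#: condition labels recognized by summarize_effects
DPG_LABEL = "DPG"
CL_LABEL = "KCl"
COMBINED_LABEL = "KCl+DPG"


@dataclasses.dataclass(frozen=True)
class EffectorEffects:
    """DPG, chloride and combined effects (delta log10 P50 vs stripped).

    Absent conditions give ``None`` entries, never zero.
    """

    reference_ph: float
    temperature: float
    dpg_effect: float | None = None
    se_dpg_effect: float | None = None
    cl_effect: float | None = None
    se_cl_effect: float | None = None
    combined_effect: float | None = None
    se_combined_effect: float | None = None


def effector_effect(
    reg_effector: PHRegression, reg_stripped: PHRegression, ph_ref: float
) -> tuple[float, float]:
    """Delta log10 P50 (effector minus stripped) at the reference pH, with SE."""
    if not math.isclose(
        reg_effector.temperature, reg_stripped.temperature, abs_tol=1e-6
    ):
        raise GroupingError(
            "effector and stripped regressions are at different temperatures: "
            f"{reg_effector.temperature} vs {reg_stripped.temperature} K"
        )
    delta = reg_effector.predict(ph_ref) - reg_stripped.predict(ph_ref)
    se = math.hypot(reg_effector.se_pred(ph_ref), reg_stripped.se_pred(ph_ref))
    return delta, se


def summarize_effects(
    regs: Mapping[str, PHRegression], ph_ref: float
) -> EffectorEffects:
    """Assemble all available effector effects against the stripped baseline."""
    if STRIPPED not in regs:
        raise GroupingError("no 'stripped' condition present; effects undefined")
    stripped = regs[STRIPPED]
    values: dict[str, float | None] = {}
    for label, field in (
        (DPG_LABEL, "dpg_effect"),
        (CL_LABEL, "cl_effect"),
        (COMBINED_LABEL, "combined_effect"),
    ):
        if label in regs:
            delta, se = effector_effect(regs[label], stripped, ph_ref)
            values[field] = delta
            values["se_" + field] = se
    return EffectorEffects(
        reference_ph=ph_ref, temperature=stripped.temperature, **values
    )
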