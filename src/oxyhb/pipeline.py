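"""End-to-end orchestration: fit -> standardize -> effects -> thermal -> solubility.

`run_pipeline` reads measurement tables and produces one :class:`HbSummary`
per hemoglobin. Each summary cell (standardized P50, Bohr coefficient,
effector effects, van't Hoff enthalpies, solubility) is computed
independently; a failure in one cell is recorded as a warning attributed to
(hemoglobin, condition) and leaves only that cell absent. The run is
deterministic for fixed inputs and configuration, and every summary carries
provenance (config hash, input names) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CELSIUS_OFFSET, AnalysisConfig
from .effectors import STRIPPED, EffectorEffects, summarize_effects
from .errors import OxyhbError, ValidationError
from .hill import HillFit, fit_hill
from .io import OECSeries, SolubilitySeries, read_oec_table, read_solubility_table
from .ph import PHRegression, bohr_coefficient, fit_logp50_vs_ph, p50_at_ph
from .solubility import SolubilityResult, analyze_solubility
from .thermal import ThermalResult, thermal_summary

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ConditionSummary:
    """Standardized quantities for one (condition label, temperature)."""

    condition_label: str
    temp_c: float
    reference_ph: float
    p50: float
    se_p50: float
    n50: float
    se_n50: float
    n_fits: int
    bohr: float | None = None
    se_bohr: float | None = None
    dh_raw: float | None = None
    dh_corrected: float | None = None
    se_dh: float | None = None


@dataclasses.dataclass
class HbSummary:
    """All standardized results for one hemoglobin sample."""

    hb_id: str
    prenatal: bool
    reference_ph: float
    conditions: dict[tuple[str, float], ConditionSummary]
    effects: dict[float, EffectorEffects]  # keyed by temp_c
    percent_precipitated_at_3M: float | None
    solubility: SolubilityResult | None
    provenance: dict
    warnings: list[str]

    def to_rows(self) -> list[dict]:
        """Flatten to summary-table rows, one per (condition, temperature)."""
        rows = []
        for (label, temp_c), cs in sorted(self.conditions.items()):
            eff = self.effects.get(temp_c)
            rows.append(
                {
                    "hb_id": self.hb_id,
                    "condition": label,
                    "temp_c": temp_c,
                    "reference_ph": self.reference_ph,
                    "p50_mmHg": cs.p50,
                    "se_p50_mmHg": cs.se_p50,
                    "n50": cs.n50,
                    "se_n50": cs.se_n50,
                    "bohr": cs.bohr,
                    "se_bohr": cs.se_bohr,
                    "dpg_effect": eff.dpg_effect if eff else None,
                    "se_dpg_effect": eff.se_dpg_effect if eff else None,
                    "cl_effect": eff.cl_effect if eff else None,
                    "se_cl_effect": eff.se_cl_effect if eff else None,
                    "combined_effect": eff.combined_effect if eff else None,
                    "se_combined_effect": eff.se_combined_effect if eff else None,
                    "dh_raw_kj": cs.dh_raw,
                    "dh_corrected_kj": cs.dh_corrected,
                    "se_dh_kj": cs.se_dh,
                    "percent_precipitated_3M": self.percent_precipitated_at_3M,
                }
            )
        return rows


def _mean_n50(fits: Sequence[tuple[float, HillFit]]) -> tuple[float, float]:
    """Average cooperativity across the pH fits of one condition group.

    The SE combines the per-fit regression SEs of the mean (independent
    fits): se = sqrt(sum se_i^2) / n.
    """
    n50s = np.array([f.n50 for _, f in fits])
    ses = np.array([f.se_n50 for _, f in fits])
    return float(n50s.mean()), float(np.sqrt(np.sum(ses**2)) / len(fits))


def summarize_hb(
    hb_id: str,
    series_list: Sequence[OECSeries],
    config: AnalysisConfig,
    solubility_series: SolubilitySeries | None = None,
    provenance: dict | None = None,
) -> HbSummary:
    """Run the full analysis for one hemoglobin's equilibrium series."""
    warnings: list[str] = []
    prenatal = any(s.prenatal for s in series_list)
    ph_ref = config.reference_ph(prenatal)

    # Hill fits grouped by (condition label, temperature)
    fits_by_group: dict[tuple[str, float], list[tuple[float, HillFit]]] = defaultdict(list)
    for series in series_list:
        key = (series.condition.label, series.condition.temperature)
        try:
            fits_by_group[key].append((series.condition.ph, fit_hill(series)))
        except OxyhbError as exc:
            warnings.append(f"{hb_id}/{key[0]}@{key[1] - CELSIUS_OFFSET:.0f}C: {exc}")

    # logP50-vs-pH regressions per group
    regs: dict[tuple[str, float], PHRegression] = {}
    for (label, temp_k), fits in fits_by_group.items():
        try:
            regs[(label, temp_k)] = fit_logp50_vs_ph(
                fits, label, temp_k, weighted=config.weighted_ph_regression
            )
        except OxyhbError as exc:
            warnings.append(
                f"{hb_id}/{label}@{temp_k - CELSIUS_OFFSET:.0f}C: pH regression: {exc}"
            )

    conditions: dict[tuple[str, float], ConditionSummary] = {}
    for (label, temp_k), reg in regs.items():
        temp_c = round(temp_k - CELSIUS_OFFSET, 6)
        p50, se_p50 = p50_at_ph(reg, ph_ref)
        n50, se_n50 = _mean_n50(fits_by_group[(label, temp_k)])
        bohr = se_bohr = None
        try:
            b = bohr_coefficient(fits_by_group[(label, temp_k)], config.bohr_ph_range)
            bohr, se_bohr = b.phi, b.se
        except OxyhbError as exc:
            warnings.append(f"{hb_id}/{label}@{temp_c:.0f}C: Bohr: {exc}")
        conditions[(label, temp_c)] = ConditionSummary(
            condition_label=label,
            temp_c=temp_c,
            reference_ph=ph_ref,
            p50=p50,
            se_p50=se_p50,
            n50=n50,
            se_n50=se_n50,
            n_fits=reg.n_fits,
            bohr=bohr,
            se_bohr=se_bohr,
        )

    # effector effects per temperature
    effects: dict[float, EffectorEffects] = {}
    regs_by_temp: dict[float, dict[str, PHRegression]] = defaultdict(dict)
    for (label, temp_k), reg in regs.items():
        regs_by_temp[round(temp_k - CELSIUS_OFFSET, 6)][label] = reg
    for temp_c, by_label in regs_by_temp.items():
        if STRIPPED in by_label and len(by_label) > 1:
            try:
                effects[temp_c] = summarize_effects(by_label, ph_ref)
            except OxyhbError as exc:
                warnings.append(f"{hb_id}@{temp_c:.0f}C: effects: {exc}")

    # van't Hoff enthalpy per condition label (needs exactly two temperatures)
    by_label: dict[str, dict[float, PHRegression]] = defaultdict(dict)
    for (label, temp_k), reg in regs.items():
        by_label[label][temp_k] = reg
    for label, by_temp in by_label.items():
        if len(by_temp) != 2:
            if len(by_temp) == 1:
                warnings.append(
                    f"{hb_id}/{label}: only one temperature; dH not computed"
                )
            continue
        try:
            thermal = thermal_summary(
                by_temp,
                ph_ref,
                label,
                gas_constant=config.gas_constant,
                correction_kj=config.solubilization_correction_kj,
            )
        except OxyhbError as exc:
            warnings.append(f"{hb_id}/{label}: thermal: {exc}")
            continue
        for temp_k in by_temp:
            temp_c = round(temp_k - CELSIUS_OFFSET, 6)
            cs = conditions[(label, temp_c)]
            conditions[(label, temp_c)] = dataclasses.replace(
                cs,
                dh_raw=thermal.dh_raw,
                dh_corrected=thermal.dh_corrected,
                se_dh=thermal.se_dh,
            )

    pct3 = None
    sol_result = None
    if solubility_series is not None:
        try:
            sol_result = analyze_solubility(solubility_series)
            pct3 = sol_result.percent_precipitated_at_3M
        except OxyhbError as exc:
            warnings.append(f"{hb_id}: solubility: {exc}")

    for w in warnings:
        logger.warning("%s", w)
    return HbSummary(
        hb_id=hb_id,
        prenatal=prenatal,
        reference_ph=ph_ref,
        conditions=conditions,
        effects=effects,
        percent_precipitated_at_3M=pct3,
        solubility=sol_result,
        provenance=provenance or {},
        warnings=warnings,
    )


def _config_hash(config: AnalysisConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def summarize_series(
    series: Sequence[OECSeries],
    config: AnalysisConfig | None = None,
    solubility: Sequence[SolubilitySeries] = (),
    provenance: dict | None = None,
) -> list[HbSummary]:
    """Summarize in-memory series grouped by sample id."""
    config = config or AnalysisConfig()
    prov = dict(provenance or {})
    prov["config_hash"] = _config_hash(config)
    by_sample: dict[str, list[OECSeries]] = defaultdict(list)
    for s in series:
        by_sample[s.sample_id].append(s)
    sol_by_sample = {s.sample_id: s for s in solubility}
    return [
        summarize_hb(hb_id, hb_series, config, sol_by_sample.get(hb_id), prov)
        for hb_id, hb_series in sorted(by_sample.items())
    ]


def run_pipeline(
    oec_path: str | Path,
    solubility_path: str | Path | None = None,
    config: AnalysisConfig | None = None,
) -> list[HbSummary]:
    """Read measurement tables and produce per-hemoglobin summaries."""
    config = config or AnalysisConfig()
    series = read_oec_table(oec_path, config)
    solubility = (
        read_solubility_table(solubility_path) if solubility_path is not None else ()
    )
    provenance = {
        "oec_file": str(oec_path),
        "solubility_file": str(solubility_path) if solubility_path else None,
    }
    return summarize_series(series, config, solubility, provenance)


def compare_hbs(summaries: Sequence[HbSummary], baseline_id: str) -> pd.DataFrame:
    """Per-condition P50 ratios and log-scale differences against a baseline.

    Ratio SEs use the log-space delta method on the two independent
    standardized estimates.
    """
    by_id = {s.hb_id: s for s in summaries}
    if baseline_id not in by_id:
        raise ValidationError(f"unknown baseline hemoglobin id {baseline_id!r}")
    base = by_id[baseline_id]
    ln10 = math.log(10.0)
    rows = []
    for summ in summaries:
        for key, cs in sorted(summ.conditions.items()):
            if key not in base.conditions:
                continue
            bs = base.conditions[key]
            ratio = cs.p50 / bs.p50
            se_log_a = cs.se_p50 / (ln10 * cs.p50)
            se_log_b = bs.se_p50 / (ln10 * bs.p50)
            se_dlog = math.hypot(se_log_a, se_log_b)
            rows.append(
                {
                    "hb_id": summ.hb_id,
                    "condition": key[0],
                    "temp_c": key[1],
                    "p50_ratio": ratio,
                    "se_p50_ratio": ratio * ln10 * se_dlog,
                    "dlog_p50": math.log10(ratio),
                    "se_dlog_p50": se_dlog,
                }
            )
    return pd.DataFrame(rows)
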