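"""Closed-loop validation: simulate from known truth, re-estimate, compare.

These helpers drive the package's own quality checks: a batch simulator for
Hill-fit precision statistics under the measurement protocol, and
end-to-end recovery of standardized P50 and van't Hoff enthalpy from
seeded synthetic campaigns generated by the two-state forward model.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .config import AnalysisConfig, CELSIUS_OFFSET
from .hill import HillFit, fit_hill
from .io import Condition
from .mwc import (
    DEFAULT_NOISE_SD,
    PROTOCOL_CONDITIONS,
    MWCParameters,
    simulate_oec,
    true_dh,
    true_p50,
)
from .ph import fit_logp50_vs_ph, p50_at_ph
from .pipeline import summarize_series
from .thermal import thermal_summary


@dataclasses.dataclass(frozen=True)
class QualityBatch:
    """Hill-fit quality statistics over many protocol-compliant series."""

    r2: np.ndarray
    se_p50_pct: np.ndarray  # 100 * SE(P50)/P50 per fit
    se_n50_pct: np.ndarray

    @property
    def median_r2(self) -> float:
        return float(np.median(self.r2))

    @property
    def median_se_p50_pct(self) -> float:
        return float(np.median(self.se_p50_pct))

    @property
    def median_se_n50_pct(self) -> float:
        return float(np.median(self.se_n50_pct))


def simulate_quality_batch(
    params: MWCParameters,
    n_series: int = 100,
    k_tensions: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> QualityBatch:
    """Hill-fit a batch of simulated series spanning the protocol's range.

    Each series draws a random condition (stripped/KCl/DPG/KCl+DPG, pH
    uniform in 6.8-7.9, 25 or 37 C) and is simulated with ``k_tensions``
    tensions in the 30-70% saturation band plus Gaussian read noise.
    """
    rng = np.random.default_rng(seed)
    labels = list(PROTOCOL_CONDITIONS)
    r2, sp, sn = [], [], []
    for i in range(n_series):
        kcl, dpg_fold = PROTOCOL_CONDITIONS[labels[i % len(labels)]]
        cond = Condition.from_celsius(
            ph=float(rng.uniform(6.8, 7.9)),
            temp_c=float(rng.choice([25.0, 37.0])),
            kcl=kcl,
            dpg_fold_excess=dpg_fold,
        )
        fit = fit_hill(
            simulate_oec(params, cond, k_tensions, noise_sd, rng, f"batch{i}")
        )
        r2.append(fit.r2)
        sp.append(100.0 * fit.se_p50 / fit.p50)
        sn.append(100.0 * fit.se_n50 / fit.n50)
    return QualityBatch(np.array(r2), np.array(sp), np.array(sn))


@dataclasses.dataclass(frozen=True)
class P50Recovery:
    """Pipeline-standardized P50 vs the simulator's exact value."""

    estimate: float  # mm Hg at the reference pH
    se: float
    truth: float


def recover_standardized_p50(
    params: MWCParameters,
    condition_label: str,
    ph_values: Sequence[float],
    reference_ph: float,
    seed: int,
    temp_c: float = 37.0,
    k_tensions: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> P50Recovery:
    """Full standardization loop for one condition at one temperature.

    Simulates one series per pH, Hill-fits each, regresses log10 P50 on pH
    and interpolates at the reference pH; the truth is the model's exact
    P50 under the reference-pH condition.
    """
    kcl, dpg_fold = PROTOCOL_CONDITIONS[condition_label]
    rng = np.random.default_rng(seed)
    series = []
    for ph in ph_values:
        cond = Condition.from_celsius(
            ph=ph, temp_c=temp_c, kcl=kcl, dpg_fold_excess=dpg_fold,
            label=condition_label,
        )
        series.append(
            simulate_oec(params, cond, k_tensions, noise_sd, rng, "recovery")
        )
    config = AnalysisConfig(
        reference_ph_adult=reference_ph, reference_ph_prenatal=reference_ph
    )
    (summary,) = summarize_series(series, config)
    cs = summary.conditions[(condition_label, temp_c)]
    truth_cond = Condition.from_celsius(
        ph=reference_ph, temp_c=temp_c, kcl=kcl, dpg_fold_excess=dpg_fold
    )
    return P50Recovery(
        estimate=cs.p50, se=cs.se_p50, truth=true_p50(params, truth_cond)
    )


@dataclasses.dataclass(frozen=True)
class DhRecovery:
    """Pipeline van't Hoff enthalpy vs the simulator's exact value."""

    dh_corrected: float  # kJ mol^-1 O2
    se: float
    truth: float


def recover_dh(
    params: MWCParameters,
    condition_label: str,
    ph_ref: float,
    ph_values: Sequence[float],
    seed: int,
    temps_c: tuple[float, float] = (25.0, 37.0),
    k_tensions: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> DhRecovery:
    """Recover the corrected oxygenation enthalpy between two temperatures."""
    kcl, dpg_fold = PROTOCOL_CONDITIONS[condition_label]
    rng = np.random.default_rng(seed)
    regs = {}
    for temp_c in temps_c:
        fits: list[tuple[float, HillFit]] = []
        for ph in ph_values:
            cond = Condition.from_celsius(
                ph=ph, temp_c=temp_c, kcl=kcl, dpg_fold_excess=dpg_fold,
                label=condition_label,
            )
            fits.append(
                (ph, fit_hill(simulate_oec(params, cond, k_tensions, noise_sd,
                                           rng, "recovery")))
            )
        temp_k = temp_c + CELSIUS_OFFSET
        regs[temp_k] = fit_logp50_vs_ph(fits, condition_label, temp_k)
    result = thermal_summary(regs, ph_ref, condition_label)
    truth_cond = Condition.from_celsius(
        ph=ph_ref, temp_c=temps_c[1], kcl=kcl, dpg_fold_excess=dpg_fold
    )
    truth = true_dh(
        params,
        truth_cond,
        min(temps_c) + CELSIUS_OFFSET,
        max(temps_c) + CELSIUS_OFFSET,
    )
    return DhRecovery(dh_corrected=result.dh_corrected, se=result.se_dh, truth=truth)
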