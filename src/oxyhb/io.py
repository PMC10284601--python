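"""Measurement-table I/O and the shared condition/series types.

An oxygen-equilibrium table holds one row per tonometric equilibration:
sample id, buffer pH, temperature (degrees C), KCl molarity, DPG (either an
absolute molarity ``dpg_M`` or a fold excess over tetramer
``dpg_fold_excess``), heme concentration, O2 tension (mm Hg) and fractional
saturation. Rows sharing a sample and chemical/thermal condition form one
:class:`OECSeries`.

Solubility tables hold ammonium-sulfate precipitation series: one row per
salt molarity with the soluble-hemoglobin signal (absorbance-like units),
including a mandatory 0 M control.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import CELSIUS_OFFSET, AnalysisConfig
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

HEMES_PER_TETRAMER = 4
DEFAULT_HEME_CONC = 0.25e-3  # mol heme / L, low end of the assay range

_PH_MIN, _PH_MAX = 6.0, 9.0


def condition_label(kcl: float, dpg: float) -> str:
    """Canonical label from effector content: stripped / KCl / DPG / KCl+DPG."""
    has_cl = kcl > 0
    has_dpg = dpg > 0
    if has_cl and has_dpg:
        return "KCl+DPG"
    if has_cl:
        return "KCl"
    if has_dpg:
        return "DPG"
    return "stripped"


@dataclasses.dataclass(frozen=True)
class Condition:
    """Chemical and thermal context of one equilibrium series.

    ``temperature`` is stored in kelvin; use :meth:`from_celsius` for
    protocol-style inputs. ``dpg`` is an absolute molarity; a fold excess
    over tetramer converts as ``dpg = fold * heme_conc / 4``.
    """

    ph: float
    temperature: float  # kelvin
    kcl: float = 0.0
    dpg: float = 0.0
    heme_conc: float = DEFAULT_HEME_CONC
    label: str = ""

    def __post_init__(self):
        if not (self.temperature > 0):
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if not (_PH_MIN <= self.ph <= _PH_MAX):
            raise ValidationError(
                f"pH {self.ph} outside accepted range [{_PH_MIN}, {_PH_MAX}]"
            )
        if self.kcl < 0 or self.dpg < 0:
            raise ValidationError("effector concentrations must be non-negative")
        if not (self.heme_conc > 0):
            raise ValidationError("heme concentration must be positive")
        if not self.label:
            object.__setattr__(self, "label", condition_label(self.kcl, self.dpg))

    @classmethod
    def from_celsius(
        cls,
        ph: float,
        temp_c: float,
        kcl: float = 0.0,
        dpg: float | None = None,
        dpg_fold_excess: float | None = None,
        heme_conc: float = DEFAULT_HEME_CONC,
        label: str = "",
    ) -> "Condition":
        """Build a condition from protocol units (degrees C, fold-excess DPG)."""
        if dpg is not None and dpg_fold_excess is not None:
            raise ValidationError("give either dpg molarity or fold excess, not both")
        if dpg is None:
            dpg = resolve_dpg_fold_excess(dpg_fold_excess or 0.0, heme_conc)
        return cls(
            ph=ph,
            temperature=temp_c + CELSIUS_OFFSET,
            kcl=kcl,
            dpg=dpg,
            heme_conc=heme_conc,
            label=label,
        )

    @property
    def temp_celsius(self) -> float:
        return self.temperature - CELSIUS_OFFSET

    def key(self) -> tuple:
        """Grouping key: chemical identity + temperature (label excluded)."""
        return (self.ph, self.temperature, self.kcl, self.dpg, self.heme_conc)


def resolve_dpg_fold_excess(fold_excess: float, heme_conc: float) -> float:
    """DPG molarity from a fold excess over tetramer (4 hemes per tetramer)."""
    if fold_excess < 0:
        raise ValidationError("DPG fold excess must be non-negative")
    if heme_conc <= 0:
        raise ValidationError("heme concentration must be positive")
    return fold_excess * heme_conc / HEMES_PER_TETRAMER


@dataclasses.dataclass(frozen=True)
class OECSeries:
    """One oxygen-equilibrium series: (PO2, saturation) points under one condition."""

    sample_id: str
    condition: Condition
    po2: tuple[float, ...]
    saturation: tuple[float, ...]
    prenatal: bool = False

    def __post_init__(self):
        if len(self.po2) != len(self.saturation):
            raise ValidationError("po2 and saturation lengths differ")
        if len(self.po2) < 3:
            raise ValidationError(
                f"series {self.sample_id}: need >= 3 equilibration points, "
                f"got {len(self.po2)}"
            )
        for p, s in zip(self.po2, self.saturation):
            if not p > 0:
                raise ValidationError(f"series {self.sample_id}: PO2 {p} must be > 0")
            if not (0.0 < s < 1.0):
                raise ValidationError(
                    f"series {self.sample_id}: saturation {s} must lie strictly "
                    "in (0, 1)"
                )

    def __len__(self) -> int:
        return len(self.po2)

    @property
    def po2_array(self) -> np.ndarray:
        return np.asarray(self.po2, dtype=float)

    @property
    def saturation_array(self) -> np.ndarray:
        return np.asarray(self.saturation, dtype=float)


@dataclasses.dataclass(frozen=True)
class SolubilitySeries:
    """Ammonium-sulfate precipitation series for one hemoglobin sample."""

    sample_id: str
    ammonium_sulfate: tuple[float, ...]
    soluble_signal: tuple[float, ...]

    def __post_init__(self):
        if len(self.ammonium_sulfate) != len(self.soluble_signal):
            raise ValidationError("molarity and signal lengths differ")
        ms = np.asarray(self.ammonium_sulfate, dtype=float)
        sig = np.asarray(self.soluble_signal, dtype=float)
        if not np.any(ms == 0.0):
            raise ValidationError(
                f"solubility series {self.sample_id}: no 0 M control row"
            )
        if np.any(sig < 0):
            raise ValidationError(
                f"solubility series {self.sample_id}: negative soluble signal"
            )
        if np.any(ms < 0) or np.any(ms > 3.5):
            raise ValidationError(
                f"solubility series {self.sample_id}: molarities must lie in [0, 3.5]"
            )
        order = np.argsort(ms, kind="stable")
        object.__setattr__(self, "ammonium_sulfate", tuple(ms[order]))
        object.__setattr__(self, "soluble_signal", tuple(sig[order]))

    @property
    def control_signal(self) -> float:
        i = self.ammonium_sulfate.index(0.0)
        return self.soluble_signal[i]


# ---------------------------------------------------------------------------
# readers

_OEC_REQUIRED = ["sample", "ph", "temp_c", "kcl_M", "po2_mmHg", "saturation"]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_oec_table(
    path: str | Path, config: AnalysisConfig | None = None
) -> list[OECSeries]:
    """Read an oxygen-equilibrium CSV/TSV into grouped, validated series.

    The DPG specification may be an absolute molarity column ``dpg_M`` or a
    ``dpg_fold_excess`` column together with ``heme_M`` (defaulting to
    0.25 mM when absent). An optional boolean ``prenatal`` column selects the
    prenatal reference pH downstream.
    """
    df = _read_table(path)
    missing = [c for c in _OEC_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    has_dpg_m = "dpg_M" in df.columns
    has_fold = "dpg_fold_excess" in df.columns
    if not has_dpg_m and not has_fold:
        raise FormatError(
            "missing DPG specification: provide column dpg_M or dpg_fold_excess"
        )

    series: list[OECSeries] = []
    heme = df["heme_M"] if "heme_M" in df.columns else pd.Series(
        DEFAULT_HEME_CONC, index=df.index
    )
    prenatal_col = df["prenatal"].astype(bool) if "prenatal" in df.columns else None

    for row_i, (_, row) in enumerate(df.iterrows(), start=2):  # 1-based + header
        s = float(row["saturation"])
        p = float(row["po2_mmHg"])
        if not (0.0 < s < 1.0):
            raise ValidationError(
                f"{path} line {row_i}: saturation {s} outside (0, 1)"
            )
        if not p > 0:
            raise ValidationError(f"{path} line {row_i}: PO2 {p} must be > 0")

    def _condition(row, h) -> Condition:
        dpg = float(row["dpg_M"]) if has_dpg_m and not pd.isna(row.get("dpg_M")) else None
        fold = (
            float(row["dpg_fold_excess"])
            if has_fold and not pd.isna(row.get("dpg_fold_excess"))
            else None
        )
        return Condition.from_celsius(
            ph=float(row["ph"]),
            temp_c=float(row["temp_c"]),
            kcl=float(row["kcl_M"]),
            dpg=dpg,
            dpg_fold_excess=fold,
            heme_conc=float(h),
        )

    df = df.assign(_heme=heme)
    keyed: dict[tuple, dict] = {}
    for idx, row in df.iterrows():
        cond = _condition(row, row["_heme"])
        key = (str(row["sample"]), cond.key())
        entry = keyed.setdefault(
            key,
            {
                "condition": cond,
                "po2": [],
                "sat": [],
                "prenatal": bool(prenatal_col.loc[idx]) if prenatal_col is not None else False,
            },
        )
        entry["po2"].append(float(row["po2_mmHg"]))
        entry["sat"].append(float(row["saturation"]))

    for (sample, _), entry in keyed.items():
        series.append(
            OECSeries(
                sample_id=sample,
                condition=entry["condition"],
                po2=tuple(entry["po2"]),
                saturation=tuple(entry["sat"]),
                prenatal=entry["prenatal"],
            )
        )
    return series


def read_solubility_table(path: str | Path) -> list[SolubilitySeries]:
    """Read a solubility CSV/TSV into per-sample series sorted by molarity."""
    df = _read_table(path)
    required = ["sample", "ammonium_sulfate_M", "soluble_signal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    out = []
    for sample, grp in df.groupby("sample", sort=True):
        ms = grp["ammonium_sulfate_M"].to_numpy(dtype=float)
        dup = pd.Series(ms).duplicated()
        if dup.any():
            logger.info(
                "solubility series %s: %d duplicate molarity row(s) retained",
                sample,
                int(dup.sum()),
            )
        out.append(
            SolubilitySeries(
                sample_id=str(sample),
                ammonium_sulfate=tuple(ms),
                soluble_signal=tuple(grp["soluble_signal"].to_numpy(dtype=float)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers

#: column order of the summary table; one row per (hemoglobin, condition,
#: temperature). Missing quantities are left empty, never written as zero.
SUMMARY_COLUMNS = [
    "hb_id",
    "condition",
    "temp_c",
    "reference_ph",
    "p50_mmHg",
    "se_p50_mmHg",
    "n50",
    "se_n50",
    "bohr",
    "se_bohr",
    "dpg_effect",
    "se_dpg_effect",
    "cl_effect",
    "se_cl_effect",
    "combined_effect",
    "se_combined_effect",
    "dh_raw_kj",
    "dh_corrected_kj",
    "se_dh_kj",
    "percent_precipitated_3M",
]


def write_summary_table(summaries: Sequence, path: str | Path) -> None:
    """Write HbSummary objects to CSV, one row per (hemoglobin, condition).

    Values are emitted with 12 significant digits so a read-back reproduces
    them to within decimal formatting precision.
    """
    if not summaries:
        raise ValidationError("refusing to write an empty summary table")
    rows = []
    for summ in summaries:
        rows.extend(summ.to_rows())
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def write_oec_table(series: Iterable[OECSeries], path: str | Path) -> None:
    """Write series back to the CSV schema ``read_oec_table`` accepts.

    Numeric fields are emitted with 12 significant digits so a read-back
    reproduces them to within decimal formatting precision.
    """
    rows = []
    for s in series:
        for p, sat in zip(s.po2, s.saturation):
            rows.append(
                {
                    "sample": s.sample_id,
                    "ph": s.condition.ph,
                    "temp_c": s.condition.temp_celsius,
                    "kcl_M": s.condition.kcl,
                    "dpg_M": s.condition.dpg,
                    "heme_M": s.condition.heme_conc,
                    "po2_mmHg": p,
                    "saturation": sat,
                    "prenatal": int(s.prenatal),
                }
            )
    if not rows:
        raise ValidationError("refusing to write an empty measurement table")
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def write_fits_json(payload: dict, path: str | Path) -> None:
    """Write the machine-readable fit record (all fits + provenance) as JSON."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
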