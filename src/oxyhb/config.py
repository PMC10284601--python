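"""Run configuration for the oxygen-equilibrium analysis pipeline.

The defaults encode the measurement protocol the package targets: adult
hemoglobins standardized at pH 7.20 and prenatal isoforms at pH 7.10, the
Bohr coefficient fitted over pH 6.9-7.8, equilibrium curves recorded at 25
and 37 degrees C, and van't Hoff enthalpies corrected for the heat of O2
solubilization (12.55 kJ per mol O2).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .errors import FormatError

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
CELSIUS_OFFSET = 273.15


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the analysis pipeline.

    Attributes
    ----------
    reference_ph_adult : float
        pH at which adult-hemoglobin P50 values are standardized.
    reference_ph_prenatal : float
        pH used for embryonic/fetal isoforms (prenatal blood is more acidic).
    bohr_ph_range : tuple of float
        Inclusive pH window over which the Bohr coefficient is fitted.
    temperatures : tuple of float
        Measurement temperatures in degrees C used for the thermal analysis.
    gas_constant : float
        J mol^-1 K^-1.
    solubilization_correction_kj : float
        Heat of O2 solubilization removed from gas-tension-based van't Hoff
        enthalpies, kJ mol^-1 O2. Applied with positive sign (toward less
        exothermic); configurable because only its magnitude is conventional.
    weighted_ph_regression : bool
        If True, the logP50-vs-pH regression is inverse-variance weighted by
        the per-fit SE of logP50. Default off (plain OLS).
    """

    reference_ph_adult: float = 7.2
    reference_ph_prenatal: float = 7.1
    bohr_ph_range: tuple[float, float] = (6.9, 7.8)
    temperatures: tuple[float, float] = (25.0, 37.0)
    gas_constant: float = GAS_CONSTANT
    solubilization_correction_kj: float = 12.55
    weighted_ph_regression: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from YAML or JSON; unknown keys are rejected."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(
                f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}"
            )
        for key in ("bohr_ph_range", "temperatures"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bohr_ph_range"] = list(d["bohr_ph_range"])
        d["temperatures"] = list(d["temperatures"])
        return d

    def reference_ph(self, prenatal: bool) -> float:
        return self.reference_ph_prenatal if prenatal else self.reference_ph_adult
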