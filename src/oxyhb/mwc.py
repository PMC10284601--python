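"""Two-state (MWC) allosteric forward model of hemoglobin oxygenation.

The tetramer is in equilibrium between a low-affinity T state and a
high-affinity R state. Deoxy protein favours T by the allosteric constant L;
each of the four hemes binds O2 with dissociation constant kT (T state) or
kR (R state), kT > kR. Heterotropic effectors (protons at Bohr groups,
chloride, 2,3-DPG) bind the two quaternary states with different affinities
and therefore shift the effective allosteric constant

    L_eff = L0 * prod_e [ (1 + [e]/K_Te) / (1 + [e]/K_Re) ]^m_e,

with [H+] = 10^-pH and K = 10^-pKa for the proton factor. Preferential
T-state binding (K_Te < K_Re) stabilizes the deoxy conformation and lowers
O2 affinity, which is how DPG, Cl- and the alkaline Bohr effect act.

Every equilibrium carries a van't Hoff enthalpy: dissociation constants are
scaled to temperature T as K(T) = K(t_ref) * exp[(dH/R)(1/T - 1/t_ref)], so
exothermic binding (dH < 0) weakens with warming; L0 scales the same way
with the T->R transition enthalpy. In the stripped, proton-balanced limit at
t_ref the model is the classical three-parameter (L0, kR, c = kR/kT) form.

Fractional saturation is

    Y = [a(1+a)^3 + L c a (1+c a)^3] / [(1+a)^4 + L (1+c a)^4],  a = PO2/kR.

The experiment emulator reproduces the tonometric protocol: three to five
tensions placed so the true saturations fall inside the 30-70% band, with
additive Gaussian read noise on saturation.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .config import GAS_CONSTANT
from .errors import CalibrationError, ValidationError
from .io import Condition, OECSeries, SolubilitySeries
from .thermal import SOLUBILIZATION_KJ, correct_solubilization, vant_hoff_dh

T_REF = 310.15  # kelvin (37 C), reference temperature for all constants


@dataclasses.dataclass(frozen=True)
class MWCParameters:
    """Ground-truth parameter set of the two-state forward model.

    Dissociation constants are at ``t_ref``; enthalpies are kJ mol^-1 and
    refer to the binding direction (negative = exothermic binding), except
    ``dh_l`` which is the heat of the T->R conformational change.
    """

    l0: float  # T/R equilibrium of deoxy Hb (stripped, t_ref, no protons bound)
    kr: float  # R-state O2 dissociation constant, mm Hg
    kt: float  # T-state O2 dissociation constant, mm Hg (kt > kr)
    dpg_kt: float = 2.0e-5  # DPG dissociation constants, mol/L
    dpg_kr: float = 2.0e-3
    cl_kt: float = 0.04  # chloride dissociation constants, mol/L
    cl_kr: float = 0.12
    pka_t: float = 7.5  # Bohr-group pKa in T and R states
    pka_r: float = 6.6
    m_dpg: int = 1  # binding sites per tetramer
    m_cl: int = 4
    m_h: int = 2
    dh_o2: float = -59.0  # heme oxygenation enthalpy, kJ mol^-1 O2
    dh_l: float = 0.0  # T->R transition enthalpy
    dh_dpg: float = 0.0  # effector binding enthalpies
    dh_cl: float = 0.0
    dh_h: float = 0.0
    dh_sol: float = SOLUBILIZATION_KJ  # heat of O2 solution (magnitude)
    t_ref: float = T_REF

    def __post_init__(self):
        if not (self.kt > self.kr > 0):
            raise ValidationError(f"need kt > kr > 0, got kt={self.kt}, kr={self.kr}")
        if self.l0 < 0:
            raise ValidationError("L0 must be non-negative")
        for name in ("dpg_kt", "dpg_kr", "cl_kt", "cl_kr"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("m_dpg", "m_cl", "m_h"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def replace(self, **kwargs) -> "MWCParameters":
        return dataclasses.replace(self, **kwargs)


def _vant_hoff_scale(dh_kj: float, temperature: float, t_ref: float) -> float:
    """Temperature factor for a dissociation constant with binding enthalpy dh."""
    return math.exp(
        (dh_kj * 1000.0 / GAS_CONSTANT) * (1.0 / temperature - 1.0 / t_ref)
    )


def o2_constants(params: MWCParameters, temperature: float) -> tuple[float, float]:
    """(kR, kT) at the given temperature, scaled by the oxygenation enthalpy."""
    scale = _vant_hoff_scale(params.dh_o2, temperature, params.t_ref)
    return params.kr * scale, params.kt * scale


def _effector_factor(
    conc: float, k_t: float, k_r: float, m: int, dh: float, temperature: float, t_ref: float
) -> float:
    if m == 0 or conc == 0.0:
        return 1.0
    scale = _vant_hoff_scale(dh, temperature, t_ref)
    kt_T = k_t * scale
    kr_T = k_r * scale
    return ((1.0 + conc / kt_T) / (1.0 + conc / kr_T)) ** m


def allosteric_L(params: MWCParameters, condition: Condition) -> float:
    """Effective allosteric constant under the condition's effectors and T."""
    T = condition.temperature
    # L is the R->T equilibrium constant, so its van't Hoff enthalpy is the
    # negative of the T->R transition heat.
    l_eff = params.l0 * _vant_hoff_scale(-params.dh_l, T, params.t_ref)
    l_eff *= _effector_factor(
        condition.dpg, params.dpg_kt, params.dpg_kr, params.m_dpg,
        params.dh_dpg, T, params.t_ref,
    )
    l_eff *= _effector_factor(
        condition.kcl, params.cl_kt, params.cl_kr, params.m_cl,
        params.dh_cl, T, params.t_ref,
    )
    h_conc = 10.0 ** (-condition.ph)
    l_eff *= _effector_factor(
        h_conc, 10.0**-params.pka_t, 10.0**-params.pka_r, params.m_h,
        params.dh_h, T, params.t_ref,
    )
    return l_eff


def mwc_saturation(
    params: MWCParameters, po2, condition: Condition
) -> float | np.ndarray:
    """Fractional saturation Y at oxygen tension(s) ``po2`` (mm Hg)."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValidationError("PO2 must be non-negative")
    kr, kt = o2_constants(params, condition.temperature)
    c = kr / kt
    l_eff = allosteric_L(params, condition)
    a = po2 / kr
    num = a * (1.0 + a) ** 3 + l_eff * c * a * (1.0 + c * a) ** 3
    den = (1.0 + a) ** 4 + l_eff * (1.0 + c * a) ** 4
    y = num / den
    return float(y) if y.ndim == 0 else y


_P50_BRACKET = (1e-6, 1e4)  # mm Hg


def true_p50(params: MWCParameters, condition: Condition) -> float:
    """Exact half-saturation tension by bisection (relative tolerance 1e-9)."""
    lo, hi = _P50_BRACKET
    f = lambda p: mwc_saturation(params, p, condition) - 0.5
    if f(lo) > 0 or f(hi) < 0:
        raise ValidationError("P50 outside the physical bracket; absurd parameters")
    return float(brentq(f, lo, hi, rtol=1e-9))


def po2_at_saturation(
    params: MWCParameters, saturation: float, condition: Condition
) -> float:
    """Inverse of the saturation curve (used to place protocol tensions)."""
    if not (0.0 < saturation < 1.0):
        raise ValidationError("target saturation must lie in (0, 1)")
    lo, hi = _P50_BRACKET
    f = lambda p: mwc_saturation(params, p, condition) - saturation
    return float(brentq(f, lo, hi, rtol=1e-9))


def true_n50(params: MWCParameters, condition: Condition) -> float:
    """Analytic Hill slope at half saturation via centered finite difference."""
    p50 = true_p50(params, condition)
    dlog = 1e-4
    y1 = mwc_saturation(params, p50 * 10.0**-dlog, condition)
    y2 = mwc_saturation(params, p50 * 10.0**dlog, condition)
    logit = lambda y: math.log10(y / (1.0 - y))
    return (logit(y2) - logit(y1)) / (2.0 * dlog)


def true_bohr(
    params: MWCParameters,
    condition: Condition,
    ph_center: float = 7.35,
    dph: float = 0.05,
) -> float:
    """True Bohr slope dlog10 P50/dpH by centered finite difference."""
    lo = dataclasses.replace(condition, ph=ph_center - dph, label=condition.label)
    hi = dataclasses.replace(condition, ph=ph_center + dph, label=condition.label)
    return (
        math.log10(true_p50(params, hi)) - math.log10(true_p50(params, lo))
    ) / (2.0 * dph)


def true_dh(
    params: MWCParameters,
    condition: Condition,
    t1: float,
    t2: float,
    corrected: bool = True,
) -> float:
    """True van't Hoff enthalpy (kJ mol^-1 O2) between two temperatures.

    Evaluates the model's exact P50 at each temperature and applies the same
    isochore the analysis pipeline uses; with ``corrected`` the O2
    solubilization heat is added back.
    """
    c1 = dataclasses.replace(condition, temperature=t1, label=condition.label)
    c2 = dataclasses.replace(condition, temperature=t2, label=condition.label)
    dh = vant_hoff_dh(true_p50(params, c1), true_p50(params, c2), t1, t2)
    return correct_solubilization(dh, params.dh_sol) if corrected else dh


# ---------------------------------------------------------------------------
# experiment emulation

DEFAULT_NOISE_SD = 0.005  # saturation units; thin-film read precision
_SAT_BAND = (0.30, 0.70)  # protocol saturation band


def simulate_oec(
    params: MWCParameters,
    condition: Condition,
    k_tensions: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sim",
) -> OECSeries:
    """Simulate one tonometric series under the measurement protocol.

    Target saturations are placed evenly inside the 30-70% band; the
    corresponding tensions come from inverting the true saturation curve.
    Observed saturations add Gaussian noise (sd ``noise_sd``), redrawn when
    outside (0.01, 0.99) so the Hill logit stays finite. Deterministic for a
    fixed seed.
    """
    if k_tensions not in (3, 4, 5):
        raise ValidationError("protocol uses three to five oxygen tensions")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lo, hi = _SAT_BAND
    targets = np.linspace(lo, hi, k_tensions + 2)[1:-1]
    po2 = [po2_at_saturation(params, s, condition) for s in targets]
    truth = np.array([mwc_saturation(params, p, condition) for p in po2])
    obs = []
    for y in truth:
        val = y + rng.normal(0.0, noise_sd) if noise_sd > 0 else y
        while not (0.01 < val < 0.99):
            val = y + rng.normal(0.0, noise_sd)
        obs.append(float(val))
    return OECSeries(
        sample_id=sample_id,
        condition=condition,
        po2=tuple(float(p) for p in po2),
        saturation=tuple(obs),
    )


#: standard condition labels and their (KCl molarity, DPG fold excess)
PROTOCOL_CONDITIONS = {
    "stripped": (0.0, 0.0),
    "KCl": (0.1, 0.0),
    "DPG": (0.0, 2.0),
    "KCl+DPG": (0.1, 2.0),
}


def simulate_protocol(
    params: MWCParameters,
    sample_id: str,
    ph_values: Sequence[float],
    temps_c: Sequence[float] = (25.0, 37.0),
    conditions: Sequence[str] = ("stripped", "KCl", "DPG", "KCl+DPG"),
    heme_conc: float = 2.5e-4,
    k_tensions: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | np.random.Generator = 0,
    prenatal: bool = False,
) -> list[OECSeries]:
    """Simulate a full measurement campaign for one hemoglobin.

    One series per (condition label, temperature, pH), in deterministic
    order, all drawn from a single seeded generator.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = []
    for label in conditions:
        if label not in PROTOCOL_CONDITIONS:
            raise ValidationError(
                f"unknown condition {label!r}; choose from {sorted(PROTOCOL_CONDITIONS)}"
            )
        kcl, dpg_fold = PROTOCOL_CONDITIONS[label]
        for temp_c in temps_c:
            for ph in ph_values:
                cond = Condition.from_celsius(
                    ph=ph,
                    temp_c=temp_c,
                    kcl=kcl,
                    dpg_fold_excess=dpg_fold,
                    heme_conc=heme_conc,
                    label=label,
                )
                series = simulate_oec(
                    params, cond, k_tensions, noise_sd, rng, sample_id
                )
                if prenatal:
                    series = dataclasses.replace(series, prenatal=True)
                out.append(series)
    return out


def simulate_solubility(
    midpoint: float,
    slope: float,
    molarities: Sequence[float],
    noise_sd: float = 0.01,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sim",
    control_signal: float = 1.0,
) -> SolubilitySeries:
    """Simulate an ammonium-sulfate series from a logistic salting-out curve."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ms = np.asarray(sorted(set(float(m) for m in molarities)), dtype=float)
    if 0.0 not in ms:
        ms = np.concatenate([[0.0], ms])
    frac = 1.0 / (1.0 + np.exp((ms - midpoint) / slope))
    if noise_sd > 0:
        frac = frac + rng.normal(0.0, noise_sd, size=frac.shape)
    frac = np.clip(frac, 0.0, 1.05)
    frac[ms == 0.0] = 1.0  # normalization is to the sample's own control
    return SolubilitySeries(
        sample_id=sample_id,
        ammonium_sulfate=tuple(ms),
        soluble_signal=tuple(control_signal * frac),
    )


# ---------------------------------------------------------------------------
# calibration to published summaries


@dataclasses.dataclass(frozen=True)
class DhTarget:
    """A corrected dH' target between two temperatures under one condition.

    The condition's own temperature field is ignored; ``t1 < t2`` in kelvin.
    """

    condition: Condition
    t1: float
    t2: float
    value: float  # kJ mol^-1 O2, corrected


#: parameters optimized on a log scale (positivity-constrained)
_LOG_PARAMS = {"l0", "kr", "kt", "dpg_kt", "dpg_kr", "cl_kt", "cl_kr"}


def calibrate_to_targets(
    base: MWCParameters,
    p50_targets: Sequence[tuple[Condition, float]],
    free: Sequence[str],
    dh_targets: Sequence[DhTarget] = (),
    bohr_targets: Sequence[tuple[Condition, float]] = (),
    p50_rtol: float = 0.005,
    dh_atol: float = 0.5,
    seed: int = 0,
    n_starts: int = 4,
) -> MWCParameters:
    """Adjust the free parameters so the model's true summaries hit targets.

    Bounded least squares over log-transformed positive parameters, with a
    deterministic multi-start (perturbed initial guesses from a seeded
    generator). Residuals are relative for P50 (log scale), absolute/5 kJ for
    dH' and absolute/0.05 for Bohr slopes. The returned parameter set is
    verified to reproduce every P50 target within ``p50_rtol`` and every dH'
    target within ``dh_atol`` kJ mol^-1; otherwise a CalibrationError lists
    the worst residual.
    """
    free = list(free)
    n_targets = len(p50_targets) + len(dh_targets) + len(bohr_targets)
    if n_targets < len(free):
        raise CalibrationError(
            f"{len(free)} free parameters but only {n_targets} targets"
        )
    for name in free:
        if not hasattr(base, name):
            raise CalibrationError(f"unknown parameter {name!r}")

    def pack(params: MWCParameters) -> np.ndarray:
        vals = []
        for name in free:
            v = getattr(params, name)
            vals.append(math.log(v) if name in _LOG_PARAMS else v)
        return np.asarray(vals, dtype=float)

    def unpack(x: np.ndarray) -> MWCParameters:
        kwargs = {}
        for name, v in zip(free, x):
            if name in _LOG_PARAMS:
                kwargs[name] = math.exp(float(np.clip(v, -60.0, 60.0)))
            else:
                kwargs[name] = float(v)
        return base.replace(**kwargs)

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            params = unpack(x)
        except (ValidationError, OverflowError):
            return np.full(max(n_targets, 1), 1e3)
        res = []
        try:
            for cond, target in p50_targets:
                res.append(math.log(true_p50(params, cond) / target))
            for t in dh_targets:
                res.append(
                    (true_dh(params, t.condition, t.t1, t.t2) - t.value) / 5.0
                )
            for cond, target in bohr_targets:
                res.append((true_bohr(params, cond) - target) / 0.05)
        except (ValidationError, ValueError, OverflowError):
            return np.full(max(n_targets, 1), 1e3)
        return np.asarray(res)

    rng = np.random.default_rng(seed)
    x0 = pack(base)
    best = None
    for start in range(n_starts):
        x_init = x0 if start == 0 else x0 + rng.normal(0.0, 0.5, size=x0.shape)
        sol = least_squares(residuals, x_init, method="lm" if len(free) == n_targets else "trf")
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-18:
            break
    fitted = unpack(best.x)

    # verification against the stated tolerances
    for cond, target in p50_targets:
        try:
            rel = abs(true_p50(fitted, cond) / target - 1.0)
        except (ValidationError, OverflowError) as exc:
            raise CalibrationError(f"calibration diverged: {exc}") from exc
        if rel > p50_rtol:
            raise CalibrationError(
                f"calibration failed: P50 target {target} mm Hg ({cond.label}) "
                f"missed by {rel:.2%} (tolerance {p50_rtol:.2%})"
            )
    for t in dh_targets:
        try:
            err = abs(true_dh(fitted, t.condition, t.t1, t.t2) - t.value)
        except (ValidationError, OverflowError) as exc:
            raise CalibrationError(f"calibration diverged: {exc}") from exc
        if err > dh_atol:
            raise CalibrationError(
                f"calibration failed: dH' target {t.value} kJ ({t.condition.label}) "
                f"missed by {err:.2f} kJ (tolerance {dh_atol})"
            )
    return fitted
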