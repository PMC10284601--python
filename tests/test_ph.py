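"""pH standardization: regression identities, interpolation, Bohr window."""

import math

import numpy as np
import pytest

from oxyhb.errors import FitError
from oxyhb.hill import HillFit
from oxyhb.io import Condition
from oxyhb.mwc import simulate_protocol, true_bohr
from oxyhb.ph import bohr_coefficient, fit_logp50_vs_ph, p50_at_ph
from oxyhb.pipeline import summarize_series


def _fit(log_p50, se=0.01, n50=2.5):
    return HillFit(
        log_p50=log_p50, p50=10.0**log_p50, n50=n50,
        se_log_p50=se, se_n50=0.05, r2=0.999, n_points=4, dof=2,
    )


class TestFitLogP50VsPH:
    def test_two_point_line(self):
        reg = fit_logp50_vs_ph([(7.0, _fit(1.0)), (7.4, _fit(0.8))])
        assert reg.slope == pytest.approx(-0.5)
        assert reg.intercept == pytest.approx(4.5)

    def test_collinear_points_zero_se(self):
        pts = [(ph, _fit(3.0 - 0.4 * ph)) for ph in (6.9, 7.3, 7.7)]
        reg = fit_logp50_vs_ph(pts)
        assert reg.slope == pytest.approx(-0.4, abs=1e-12)
        assert reg.se_slope == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        ph = np.array([6.9, 7.2, 7.5, 7.8])
        y = 4.2 - 0.45 * ph + rng.normal(0, 0.02, size=4)
        reg = fit_logp50_vs_ph([(p, _fit(v)) for p, v in zip(ph, y)])
        # closed-form OLS
        sxx = np.sum((ph - ph.mean()) ** 2)
        slope = np.sum((ph - ph.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * ph.mean()
        assert reg.slope == pytest.approx(slope, rel=1e-12)
        assert reg.intercept == pytest.approx(intercept, rel=1e-12)
        resid = y - (intercept + slope * ph)
        se_slope = math.sqrt(resid @ resid / 2 / sxx)
        assert reg.se_slope == pytest.approx(se_slope, rel=1e-9)

    def test_single_ph_rejected(self):
        with pytest.raises(FitError):
            fit_logp50_vs_ph([(7.2, _fit(1.0)), (7.2, _fit(1.01))])

    def test_se_pred_minimized_at_mean_ph(self):
        rng = np.random.default_rng(8)
        pts = [(p, _fit(4.0 - 0.5 * p + rng.normal(0, 0.03)))
               for p in (6.9, 7.2, 7.5, 7.8)]
        reg = fit_logp50_vs_ph(pts)
        grid = np.linspace(6.5, 8.2, 171)
        ses = [reg.se_pred(p) for p in grid]
        assert grid[int(np.argmin(ses))] == pytest.approx(reg.ph_mean, abs=0.01)


class TestP50AtPH:
    def test_midpoint_of_two_point_line(self):
        reg = fit_logp50_vs_ph([(7.0, _fit(1.0)), (7.4, _fit(0.8))])
        p50, _ = p50_at_ph(reg, 7.2)
        assert p50 == pytest.approx(10.0**0.9, abs=1e-3)

    def test_zero_slope_independent_of_ph(self):
        reg = fit_logp50_vs_ph([(7.0, _fit(1.0)), (7.4, _fit(1.0))])
        assert p50_at_ph(reg, 6.9)[0] == pytest.approx(p50_at_ph(reg, 7.8)[0])

    def test_prediction_at_mean_ph_equals_mean_logp50(self):
        """OLS passes through (mean x, mean y) exactly."""
        rng = np.random.default_rng(2)
        logs = [1.0 + rng.normal(0, 0.05) for _ in range(4)]
        pts = list(zip((6.9, 7.2, 7.5, 7.8), map(_fit, logs)))
        reg = fit_logp50_vs_ph(pts)
        p50, _ = p50_at_ph(reg, reg.ph_mean)
        assert math.log10(p50) == pytest.approx(np.mean(logs), rel=1e-12)

    def test_se_transforms_through_log_link(self):
        reg = fit_logp50_vs_ph(
            [(p, _fit(4.0 - 0.5 * p + dy)) for p, dy in
             zip((6.9, 7.2, 7.5, 7.8), (0.01, -0.02, 0.015, -0.005))]
        )
        p50, se = p50_at_ph(reg, 7.2)
        assert se == pytest.approx(math.log(10) * p50 * reg.se_pred(7.2))


class TestBohrCoefficient:
    def test_points_outside_window_excluded(self):
        inside = [(p, _fit(4.0 - 0.5 * p)) for p in (6.9, 7.3, 7.8)]
        outside = [(6.5, _fit(10.0)), (8.2, _fit(-10.0))]
        res = bohr_coefficient(inside + outside)
        assert res.phi == pytest.approx(-0.5, abs=1e-10)
        assert res.n_used == 3
        assert res.n_excluded == 2

    def test_window_endpoints_inclusive(self):
        pts = [(6.9, _fit(1.0)), (7.8, _fit(0.55))]
        res = bohr_coefficient(pts)
        assert res.n_used == 2
        assert res.phi == pytest.approx(-0.5, abs=1e-9)

    def test_no_points_in_window_raises(self):
        with pytest.raises(FitError):
            bohr_coefficient([(6.5, _fit(1.0)), (8.4, _fit(0.8))])

    def test_phi_invariant_under_p50_scaling(self):
        pts = [(p, _fit(4.0 - 0.5 * p)) for p in (6.9, 7.2, 7.5, 7.8)]
        shifted = [(p, _fit(f.log_p50 + math.log10(3.7))) for p, f in pts]
        assert bohr_coefficient(shifted).phi == pytest.approx(
            bohr_coefficient(pts).phi, abs=1e-10
        )

    def test_proton_insensitive_model_has_zero_bohr(self, adult_params):
        params = adult_params.replace(pka_t=7.0, pka_r=7.0)
        series = simulate_protocol(
            params, "flat", ph_values=[6.9, 7.2, 7.5, 7.8],
            temps_c=[37.0], conditions=["stripped"], noise_sd=0.0,
        )
        (summ,) = summarize_series(series)
        assert summ.conditions[("stripped", 37.0)].bohr == pytest.approx(0.0, abs=1e-6)

    def test_pipeline_bohr_matches_finite_difference_oracle(self, adult_params):
        cond = Condition.from_celsius(ph=7.35, temp_c=37.0)
        phi_true = true_bohr(adult_params, cond)
        series = simulate_protocol(
            adult_params, "hb", ph_values=[6.9, 7.2, 7.5, 7.8],
            temps_c=[37.0], conditions=["stripped"], noise_sd=0.005, seed=19,
        )
        (summ,) = summarize_series(series)
        est = summ.conditions[("stripped", 37.0)]
        # secant over the window vs derivative at its center: agree within
        # combined regression SE + curvature allowance
        assert est.bohr == pytest.approx(phi_true, abs=3 * est.se_bohr + 0.02)
        assert est.bohr < 0  # alkaline Bohr effect
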