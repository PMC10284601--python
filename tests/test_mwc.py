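"""Two-state forward model vs partition-function oracle; emulator contracts."""

import math

import numpy as np
import pytest

from oxyhb.errors import CalibrationError, ValidationError
from oxyhb.hill import fit_hill
from oxyhb.io import Condition
from oxyhb.mwc import (
    MWCParameters,
    allosteric_L,
    calibrate_to_targets,
    mwc_saturation,
    o2_constants,
    simulate_oec,
    true_n50,
    true_p50,
)


def partition_saturation(params, po2, condition):
    """Oracle: 5-term ligation-state sum with binomial weights for T and R."""
    kr, kt = o2_constants(params, condition.temperature)
    L = allosteric_L(params, condition)
    a, ca = po2 / kr, po2 / kt
    zr = sum(math.comb(4, i) * a**i for i in range(5))
    zt = sum(math.comb(4, i) * ca**i for i in range(5))
    yr = sum(i / 4 * math.comb(4, i) * a**i for i in range(5))
    yt = sum(i / 4 * math.comb(4, i) * ca**i for i in range(5))
    return (yr + L * yt) / (zr + L * zt)


def random_params(rng):
    kr = rng.uniform(0.05, 1.0)
    return MWCParameters(
        l0=10.0 ** rng.uniform(2, 6),
        kr=kr,
        kt=kr * 10.0 ** rng.uniform(1.0, 3.0),
        dpg_kt=10.0 ** rng.uniform(-5, -3),
        dpg_kr=10.0 ** rng.uniform(-3.5, -2),
        cl_kt=10.0 ** rng.uniform(-2, -1),
        cl_kr=10.0 ** rng.uniform(-1.2, -0.5),
        pka_t=rng.uniform(7.2, 7.8),
        pka_r=rng.uniform(6.3, 7.0),
        m_dpg=int(rng.integers(0, 3)),
        m_cl=int(rng.integers(0, 5)),
        m_h=int(rng.integers(0, 4)),
    )


def random_condition(rng):
    return Condition.from_celsius(
        ph=rng.uniform(6.8, 7.9),
        temp_c=rng.choice([25.0, 37.0]),
        kcl=rng.choice([0.0, 0.1]),
        dpg_fold_excess=rng.choice([0.0, 2.0]),
    )


class TestSaturationFunction:
    def test_matches_partition_oracle_on_random_draws(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            params = random_params(rng)
            cond = random_condition(rng)
            po2 = 10.0 ** rng.uniform(-1.5, 2.5)
            assert mwc_saturation(params, po2, cond) == pytest.approx(
                partition_saturation(params, po2, cond), abs=1e-10
            )

    def test_pure_r_state_hyperbola(self, cond37):
        p = MWCParameters(l0=0.0, kr=0.3, kt=30.0)
        for po2 in (0.1, 0.3, 1.0, 10.0):
            assert mwc_saturation(p, po2, cond37) == pytest.approx(
                po2 / (po2 + 0.3), rel=1e-12
            )
        assert true_p50(p, cond37) == pytest.approx(0.3, rel=1e-8)

    def test_identical_states_lose_cooperativity(self, cond37):
        # c -> 1: saturation collapses to a hyperbola regardless of L
        p = MWCParameters(l0=1e5, kr=1.0, kt=1.0 + 1e-9)
        assert true_n50(p, cond37) == pytest.approx(1.0, abs=1e-6)
        assert mwc_saturation(p, 1.0, cond37) == pytest.approx(0.5, abs=1e-8)

    def test_monotone_increasing_with_limits(self, adult_params, cond37):
        po2 = np.logspace(-3, 4, 200)
        y = mwc_saturation(adult_params, po2, cond37)
        assert np.all(np.diff(y) > 0)
        assert mwc_saturation(adult_params, 0.0, cond37) == 0.0
        assert y[-1] > 0.999


class TestAllostericL:
    def test_no_effectors_at_reference_temperature(self, adult_params):
        cond = Condition.from_celsius(ph=7.2, temp_c=37.0)
        neutral = adult_params.replace(m_h=0)
        assert allosteric_L(neutral, cond) == pytest.approx(neutral.l0, rel=1e-12)

    def test_equal_state_constants_make_factor_one(self, adult_params):
        blind = adult_params.replace(dpg_kt=1e-3, dpg_kr=1e-3, m_h=0)
        with_dpg = Condition.from_celsius(ph=7.2, temp_c=37.0, dpg_fold_excess=2.0)
        without = Condition.from_celsius(ph=7.2, temp_c=37.0)
        assert allosteric_L(blind, with_dpg) == pytest.approx(
            allosteric_L(blind, without), rel=1e-12
        )

    def test_saturating_t_state_only_effector_limit(self, adult_params):
        """[e] >> K_T with K_R -> inf: the factor tends to ([e]/K_T)^m,
        checked against the explicit (1 + [e]/K)-ratio partition factor."""
        params = adult_params.replace(
            cl_kt=1e-6, cl_kr=1e12, m_cl=2, m_h=0, m_dpg=0
        )
        cond = Condition.from_celsius(ph=7.2, temp_c=37.0, kcl=0.1)
        expected = ((1 + 0.1 / 1e-6) / (1 + 0.1 / 1e12)) ** 2
        got = allosteric_L(params, cond) / params.l0
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx((0.1 / 1e-6) ** 2, rel=1e-4)

    def test_effector_monotonicity_of_p50(self, adult_params):
        """T-state-preferential binding never decreases P50."""
        p50s = []
        for kcl in (0.0, 0.02, 0.05, 0.1, 0.2):
            cond = Condition.from_celsius(ph=7.2, temp_c=37.0, kcl=kcl)
            p50s.append(true_p50(adult_params, cond))
        assert all(b >= a for a, b in zip(p50s, p50s[1:]))
        p50s = []
        for fold in (0.0, 0.5, 1.0, 2.0, 4.0):
            cond = Condition.from_celsius(ph=7.2, temp_c=37.0, dpg_fold_excess=fold)
            p50s.append(true_p50(adult_params, cond))
        assert all(b >= a for a, b in zip(p50s, p50s[1:]))


class TestTrueP50AndN50:
    def test_increasing_l0_increases_p50(self, cond37):
        p50s = [
            true_p50(MWCParameters(l0=l0, kr=0.3, kt=30.0), cond37)
            for l0 in (1e3, 1e4, 1e5, 1e6)
        ]
        assert all(b > a for a, b in zip(p50s, p50s[1:]))

    def test_agrees_with_dense_grid_argmin(self, adult_params, cond37):
        grid = np.logspace(-2, 3, 200001)
        y = mwc_saturation(adult_params, grid, cond37)
        p_grid = grid[np.argmin(np.abs(y - 0.5))]
        assert true_p50(adult_params, cond37) == pytest.approx(p_grid, rel=1e-4)

    def test_n50_within_tetramer_bounds_on_random_draws(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            params = random_params(rng)
            cond = random_condition(rng)
            n = true_n50(params, cond)
            assert 1.0 - 1e-6 <= n <= 4.0 + 1e-6

    def test_n50_matches_hill_fit_on_noiseless_points(self, adult_params, cond37):
        """The fitted slope is a secant average over the 30-70% band, the
        true n50 the tangent at half saturation; they agree to ~1%."""
        series = simulate_oec(adult_params, cond37, k_tensions=5, noise_sd=0.0)
        fit = fit_hill(series)
        assert fit.n50 == pytest.approx(true_n50(adult_params, cond37), abs=0.01)


class TestSimulateOEC:
    def test_noiseless_recovery(self, adult_params, cond37):
        """Noiseless points: P50 to ~0.1% (band-averaged slope curvature
        displaces n50 slightly more)."""
        series = simulate_oec(adult_params, cond37, noise_sd=0.0)
        fit = fit_hill(series)
        assert fit.p50 == pytest.approx(true_p50(adult_params, cond37), rel=1e-3)
        assert fit.n50 == pytest.approx(true_n50(adult_params, cond37), rel=5e-3)

    def test_saturations_inside_protocol_band(self, adult_params, cond37):
        series = simulate_oec(adult_params, cond37, k_tensions=5, noise_sd=0.0)
        assert all(0.30 < s < 0.70 for s in series.saturation)

    def test_fixed_seed_bit_identical(self, adult_params, cond37):
        a = simulate_oec(adult_params, cond37, seed=99)
        b = simulate_oec(adult_params, cond37, seed=99)
        assert a == b

    def test_invalid_tension_count_rejected(self, adult_params, cond37):
        with pytest.raises(ValidationError):
            simulate_oec(adult_params, cond37, k_tensions=6)

    def test_monte_carlo_precision_bound(self, adult_params, cond37):
        """At protocol noise (sigma=0.005, 4 tensions) the relative SE of
        P50 stays under 3% in at least 95% of 1000 replicates."""
        rng = np.random.default_rng(101)
        ok = 0
        for _ in range(1000):
            series = simulate_oec(adult_params, cond37, seed=rng)
            fit = fit_hill(series)
            if fit.se_p50 / fit.p50 < 0.03:
                ok += 1
        assert ok >= 950


class TestCalibration:
    def test_single_target_solved_exactly(self, adult_params, cond37):
        """One P50 target, kR free: the optimizer drives the residual to
        zero; the solution is close to the pure scaling kr*target/current
        (exact scaling would also move kT to keep c fixed)."""
        target = 8.8
        current = true_p50(adult_params, cond37)
        fitted = calibrate_to_targets(
            adult_params, p50_targets=[(cond37, target)], free=["kr"]
        )
        assert true_p50(fitted, cond37) == pytest.approx(target, rel=1e-6)
        assert fitted.kr == pytest.approx(
            adult_params.kr * target / current, rel=0.3
        )

    def test_four_condition_set_reproduced(self, adult_params):
        conds = {
            "stripped": Condition.from_celsius(ph=7.2, temp_c=37.0),
            "KCl": Condition.from_celsius(ph=7.2, temp_c=37.0, kcl=0.1),
            "DPG": Condition.from_celsius(ph=7.2, temp_c=37.0, dpg_fold_excess=2.0),
            "KCl+DPG": Condition.from_celsius(
                ph=7.2, temp_c=37.0, kcl=0.1, dpg_fold_excess=2.0
            ),
        }
        targets = [
            (conds["stripped"], 5.4),
            (conds["KCl"], 8.0),
            (conds["DPG"], 7.4),
            (conds["KCl+DPG"], 10.9),
        ]
        fitted = calibrate_to_targets(
            adult_params, p50_targets=targets,
            free=["kr", "cl_kt", "dpg_kt", "l0"],
        )
        for cond, target in targets:
            assert true_p50(fitted, cond) == pytest.approx(target, rel=0.005)

    def test_underdetermined_request_rejected(self, adult_params, cond37):
        with pytest.raises(CalibrationError):
            calibrate_to_targets(
                adult_params, p50_targets=[(cond37, 8.8)], free=["kr", "l0"]
            )

    def test_impossible_target_reported(self, adult_params, cond37):
        with pytest.raises(CalibrationError, match="missed|diverged"):
            calibrate_to_targets(
                adult_params,
                p50_targets=[(cond37, 5.0), (cond37, 50.0)],  # contradictory
                free=["kr", "kt"],
            )
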