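"""Local rules: growth, death, attachment, detachment, hydration, nutrient."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surfcol import (
    SimulationParams, StrategySpec,
    wetness, grow_mass, hourly_death_prob, per_step_prob,
    attachment_prob_step, detachment_prob_step, update_nutrient,
    equivalent_constant_stress,
)


class TestWetness:
    @pytest.mark.parametrize("t,H,mode,expected", [
        (3, 12, "periodic", 1),
        (15, 12, "periodic", 0),
        (12, 12, "periodic", 1),     # boundary hour still counts as wet
        (27, 12, "periodic", 1),     # second diel cycle
        (3, 12, "constant", 0),      # constant stress: never wet
        (0, 0, "periodic", 1),       # mod(0,24)=0 <= 0
    ])
    def test_schedule(self, t, H, mode, expected):
        assert wetness(t, H, mode) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            wetness(-1.0, 12)

    def test_float_accumulated_time_stays_wet_at_boundary(self):
        # 240 steps of 0.05 h land exactly on the wet/dry boundary
        t = sum([0.05] * 240)
        assert wetness(t, 12.0) == 1


class TestGrowth:
    def test_saturating_nutrient_planktonic(self, params):
        m = grow_mass(1e-12, 0.0, 1e6, params)
        assert m == pytest.approx(1e-12 * math.exp(0.4 * 0.05), rel=1e-9)

    def test_full_eps_investment_freezes_growth(self, params):
        assert grow_mass(1e-12, 1.0, 50.0, params) == pytest.approx(1e-12)

    def test_half_eps_investment(self, params):
        expected = 0.5e-12 * math.exp(0.02) + 0.5e-12
        assert grow_mass(1e-12, 0.5, 1e6, params) == pytest.approx(expected, rel=1e-9)

    def test_half_saturation(self, params):
        m = grow_mass(1e-12, 0.0, params.K_s, params)
        assert m == pytest.approx(1e-12 * math.exp(0.2 * 0.05), rel=1e-9)

    def test_zero_nutrient_stalls(self, params):
        assert grow_mass(2e-12, 0.0, 0.0, params) == pytest.approx(2e-12)


class TestDeath:
    @pytest.mark.parametrize("Q,W,expected", [
        (5, 1, 0.025),     # protected-by-wetness, background only
        (5, 0, 0.425),     # unprotected and dry: desiccation + background
        (50, 0, 0.025),    # inside a protected aggregate, dry
        (50, 1, 0.025),
        (80, 1, 0.325),    # overcrowded, regardless of hydration
        (80, 0, 0.325),
        (39, 0, 0.425),    # one below the protection threshold
        (40, 0, 0.025),    # exactly at Q_L: protected
        (75, 1, 0.325),    # exactly at Q_H: overcrowded
    ])
    def test_branches(self, params, Q, W, expected):
        assert hourly_death_prob(Q, W, params) == pytest.approx(expected)

    def test_exhaustive_branch_table(self, params):
        """Every (Q, W) on a dense grid falls in exactly one of the three
        regimes and matches the piecewise definition."""
        for Q in range(0, 121):
            for W in (0, 1):
                p = hourly_death_prob(Q, W, params)
                if Q >= params.Q_H:
                    assert p == params.S_H + params.S_B
                elif Q < params.Q_L:
                    assert p == (1 - W) * params.S_L + params.S_B
                else:
                    assert p == params.S_B
                assert 0.0 <= p <= 1.0

    def test_negative_density_rejected(self, params):
        with pytest.raises(ValueError):
            hourly_death_prob(-1, 1, params)


class TestPerStepProb:
    @pytest.mark.parametrize("p,dt,expected", [
        (1.0, 0.05, 1.0),
        (0.0, 0.05, 0.0),
        (0.01, 0.05, 1 - 0.99 ** 0.05),
    ])
    def test_values(self, p, dt, expected):
        assert per_step_prob(p, dt) == pytest.approx(expected, rel=1e-12)

    @given(p=st.floats(0.0, 0.999), dt=st.floats(0.001, 1.0))
    @settings(max_examples=200, derandomize=True)
    def test_composition_recovers_hourly(self, p, dt):
        """Compounding the per-step probability over 1/dt steps gives back
        the hourly probability."""
        step = per_step_prob(p, dt)
        hourly = 1 - (1 - step) ** (1 / dt)
        assert hourly == pytest.approx(p, abs=1e-12, rel=1e-9)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=100, derandomize=True)
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert per_step_prob(lo, 0.05) <= per_step_prob(hi, 0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            per_step_prob(1.5, 0.05)
        with pytest.raises(ValueError):
            per_step_prob(-0.1, 0.05)


class TestAttachment:
    def a_ra_step(self, strat, dt=0.05):
        return per_step_prob(strat.A_RA, dt)

    def test_vacant_site_gives_baseline(self):
        s = StrategySpec.preferential(12)
        assert attachment_prob_step(0, s, 0.05) == pytest.approx(
            self.a_ra_step(s), rel=1e-12)

    def test_halfway_point_at_threshold(self):
        s = StrategySpec.preferential(12)
        a = self.a_ra_step(s)
        assert attachment_prob_step(12, s, 0.05) == pytest.approx(
            (0.5 - a) / 2 + a, rel=1e-9)

    def test_upper_asymptote(self):
        s = StrategySpec.preferential(12)
        assert attachment_prob_step(1e9, s, 0.05) == pytest.approx(0.5, rel=1e-6)

    def test_ra_constant_in_density(self):
        s = StrategySpec.random_attachment(0.01)
        probs = attachment_prob_step(np.arange(0, 200), s, 0.05)
        assert np.allclose(probs, self.a_ra_step(s))

    @given(qpa=st.floats(1, 60), n=st.floats(1, 12),
           a_ra=st.floats(0.0001, 0.5))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_bounded(self, qpa, n, a_ra):
        """The density response is non-decreasing and bounded between the
        baseline and the ceiling for any threshold and steepness."""
        s = StrategySpec(kind="PA", A_PA=0.5, A_RA=a_ra, Q_PA=qpa, n_hill=n)
        q = np.linspace(0, 200, 400)
        p = attachment_prob_step(q, s, 0.05)
        a = self.a_ra_step(s)
        assert np.all(np.diff(p) >= -1e-15)
        assert np.all(p >= a - 1e-12)
        assert np.all(p <= 0.5 + 1e-12)

    def test_pa_degenerates_to_ra_when_ceiling_equals_baseline(self):
        a_step = per_step_prob(0.01, 0.05)
        s = StrategySpec(kind="PA", A_PA=a_step, A_RA=0.01, Q_PA=12, n_hill=10)
        p = attachment_prob_step(np.arange(0, 300), s, 0.05)
        assert np.allclose(p, a_step, rtol=0, atol=1e-15)


class TestDetachment:
    @pytest.mark.parametrize("D,expected", [
        (0.01, 1 - 0.99 ** 0.05),
        (0.0, 0.0),
        (1.0, 1.0),
    ])
    def test_values(self, D, expected):
        p = SimulationParams(D=D)
        assert detachment_prob_step(p) == pytest.approx(expected, rel=1e-12)


class TestNutrient:
    def test_equilibrium_with_source(self, params):
        assert update_nutrient(30.0, 0, params) == pytest.approx(30.0)

    def test_one_division_consumes(self, params):
        # C_div / V_water = 3e-13 g / 1e-10 m^3 = 3e-3 g m^-3
        assert update_nutrient(30.0, 1, params) == pytest.approx(29.997)

    def test_replenishment_from_empty(self, params):
        # k_perm * N_c * dt = 0.1 * 30 * 0.05
        assert update_nutrient(0.0, 0, params) == pytest.approx(0.15)

    def test_floor_at_zero(self, params):
        assert update_nutrient(0.001, 10**6, params) == 0.0


class TestConstantStressEquivalence:
    def test_default_dry_rate_maps_to_026(self):
        s = equivalent_constant_stress(0.45, 12, 24)
        assert s == pytest.approx(1 - math.sqrt(0.55), rel=1e-12)
        assert round(s, 2) == 0.26

    def test_zero_and_identity(self):
        assert equivalent_constant_stress(0.0, 12, 24) == 0.0
        assert equivalent_constant_stress(0.37, 24, 24) == pytest.approx(0.37)

    @given(s=st.floats(0.0, 0.99), h=st.floats(0.1, 24.0))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip(self, s, h):
        """The inverse transform recovers the periodic rate."""
        sc = equivalent_constant_stress(s, h, 24.0)
        back = 1 - (1 - sc) ** (24.0 / h)
        assert back == pytest.approx(s, abs=1e-12, rel=1e-9)

    def test_survival_equivalence_property(self):
        s = equivalent_constant_stress(0.45, 12, 24)
        assert (1 - s) ** 24 == pytest.approx((1 - 0.45) ** 12, rel=1e-12)


class TestParamsValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimulationParams(S_L=1.5)

    def test_threshold_order(self):
        with pytest.raises(ValueError):
            SimulationParams(Q_L=80, Q_H=75)

    def test_strategy_validation(self):
        with pytest.raises(ValueError):
            StrategySpec(kind="PA", n_hill=0.5)
        with pytest.raises(ValueError):
            StrategySpec(kind="XX")

    def test_n_steps(self, params):
        assert params.n_steps == 2400
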