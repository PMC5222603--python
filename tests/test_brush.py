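"""Unit and property tests for the brush free energy and its minimisation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dcbg import (
    BrushParameters,
    equilibrium_height,
    free_energy_curve,
    free_energy_per_chain,
    free_energy_terms,
    max_opening_under_binding,
    opening_diameter,
    scan_epsilon,
)

H_STRATEGY = st.floats(min_value=0.1, max_value=21.4, allow_nan=False)


class TestParameters:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"R": 0.0},
            {"d": -1.0},
            {"a": 0.0},
            {"N": 0.5},
            {"delta": 0.0},
            {"delta_s": -2.0},
            {"R_s": 0.0},
            {"R_s": 30.0},
            {"epsilon": -0.1},
            {"epsilon_s": -1.0},
            {"delta": 25.0},
            {"H_floor": 30.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BrushParameters(**kwargs)

    def test_admissible_range_endpoint_is_R_minus_delta(self, params):
        assert params.H_max == params.R - params.delta == 21.4


class TestFreeEnergy:
    @pytest.mark.parametrize("H", [0.0, 25.0, 21.5, -1.0, 0.0999])
    def test_heights_outside_range_rejected(self, params, H):
        with pytest.raises(ValueError):
            free_energy_per_chain(H, params)

    def test_cohesion_off_leaves_polymer_terms_only(self, params):
        p = params.with_(epsilon=0.0, epsilon_s=0.0)
        H = np.linspace(0.5, 21.4, 40)
        stretch, excluded, tip_tip, tip_shrub = free_energy_terms(H, p)
        assert np.all(tip_tip == 0.0)
        assert np.all(tip_shrub == 0.0)
        np.testing.assert_allclose(
            free_energy_per_chain(H, p), stretch + excluded, rtol=1e-12
        )

    @given(H=H_STRATEGY)
    def test_terms_sum_to_total(self, H):
        p = BrushParameters(epsilon=3.0)
        total = free_energy_per_chain(H, p)
        assert total == pytest.approx(sum(free_energy_terms(H, p)), rel=1e-12)

    def test_frozen_value_at_H10_eps3(self, params):
        # independent term-by-term arithmetic (exact rationals):
        # (10/0.76)^{5/2} 198^{-3/2}                  = 0.2254074334
        # 0.76^{5/2} 198^{3/2} 25 / (sqrt(10) 100 40) = 2.7727568281
        # -3 * 3.6^2 * 25 / (100 * 15)                = -0.6480000000
        # tip-shrub term zero (H >= delta_s)
        F = free_energy_per_chain(10.0, params.with_(epsilon=3.0))
        assert F == pytest.approx(2.3501642614, abs=1e-9)

    @given(H=st.floats(min_value=4.0, max_value=21.4, allow_nan=False))
    def test_heaviside_support_above_delta_s(self, H):
        """Shrub term vanishes for H >= delta_s, including exactly at the kink."""
        on = BrushParameters(shrubs_present=True)
        off = BrushParameters(shrubs_present=False)
        assert free_energy_per_chain(H, on) == free_energy_per_chain(H, off)

    def test_shrub_term_negative_below_delta_s(self, params):
        H = np.linspace(0.2, 3.9, 20)
        *_, tip_shrub = free_energy_terms(H, params)
        assert np.all(tip_shrub < 0.0)


class TestCurve:
    def test_grid_structure(self, params):
        curve = free_energy_curve(params, n_grid=200)
        assert np.all(np.diff(curve.H_grid) > 0)
        assert curve.H_grid[0] == params.H_floor
        assert curve.H_grid[-1] == params.H_max
        assert params.delta_s in curve.H_grid
        np.testing.assert_allclose(
            curve.F_total,
            curve.F_stretching + curve.F_excluded_volume
            + curve.F_tip_tip + curve.F_tip_shrub,
            rtol=1e-12,
        )

    def test_tip_terms_nonpositive(self, params):
        curve = free_energy_curve(params.with_(epsilon=2.0))
        assert np.all(curve.F_tip_tip <= 0.0)
        assert np.all(curve.F_tip_shrub <= 0.0)
        assert np.all(curve.F_tip_shrub[curve.H_grid >= params.delta_s] == 0.0)

    def test_small_grid_rejected(self, params):
        with pytest.raises(ValueError):
            free_energy_curve(params, n_grid=49)

    def test_curves_identical_above_delta_s_with_and_without_shrubs(self, params):
        on = free_energy_curve(params, n_grid=300)
        off = free_energy_curve(params.with_(shrubs_present=False), n_grid=300)
        sel = on.H_grid >= params.delta_s
        np.testing.assert_array_equal(on.F_total[sel], off.F_total[sel])


class TestEquilibrium:
    def test_open_state_below_half_radius_at_zero_cohesion(self, params):
        state = equilibrium_height(params.with_(epsilon=0.0, shrubs_present=False))
        assert state.H_eq < params.R / 2

    def test_closed_at_reference_cohesion(self, params):
        state = equilibrium_height(params.with_(epsilon=4.7))
        grid_step = (params.H_max - params.H_floor) / 1999
        assert abs(state.H_eq - params.H_max) <= grid_step
        assert state.label == "closed"

    def test_matches_exhaustive_grid_argmin(self):
        """Solver agrees with a 1e5-point argmin on randomised parameter sets."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            R = rng.uniform(15, 40)
            delta = rng.uniform(1, 0.3 * R)
            p = BrushParameters(
                R=R,
                d=rng.uniform(5, 20),
                a=rng.uniform(0.4, 1.4),
                N=rng.uniform(50, 400),
                delta=delta,
                delta_s=rng.uniform(2, 6),
                R_s=R,
                epsilon=rng.uniform(0, 5),
                epsilon_s=rng.uniform(0, 8),
                shrubs_present=bool(rng.integers(2)),
            )
            n_fine = 100_000
            H = np.linspace(p.H_floor, p.H_max, n_fine)
            step = H[1] - H[0]
            H_oracle = H[np.argmin(free_energy_per_chain(H, p))]
            state = equilibrium_height(p)
            assert abs(state.H_eq - H_oracle) <= step, p

    def test_monotone_gating(self, params):
        """More tip cohesion never opens the pore."""
        heights = [
            equilibrium_height(params.with_(epsilon=e), n_grid=800).H_eq
            for e in np.linspace(0, 5, 11)
        ]
        assert np.all(np.diff(heights) >= -1e-6)


class TestOpening:
    def test_opening_convention(self, params):
        assert opening_diameter(params.R, params) == 0.0
        assert opening_diameter(5.0, params) == 40.0
        assert opening_diameter(params.R / 2, params) == params.R


class TestScan:
    def test_grid_validation(self, params):
        with pytest.raises(ValueError):
            scan_epsilon(params, [])
        with pytest.raises(ValueError):
            scan_epsilon(params, [2.0, 1.0])
        with pytest.raises(ValueError):
            scan_epsilon(params, [-1.0, 1.0])

    def test_transition_detected_and_refined(self, params):
        scan = scan_epsilon(
            params.with_(shrubs_present=False), np.arange(0.0, 5.01, 0.5), n_grid=1200
        )
        assert scan.transition is not None
        assert 0.0 < scan.transition < 5.0
        assert scan.transition_jump > 5.0
        # bisection refines the coarse-grid bracket to ~1e-3 kT
        fine = scan_epsilon(
            params.with_(shrubs_present=False), np.arange(1.5, 2.01, 0.1), n_grid=1200
        )
        assert fine.transition == pytest.approx(scan.transition, abs=5e-3)

    def test_no_jump_reports_absent(self, params):
        scan = scan_epsilon(params, np.array([3.0, 4.0, 5.0]), n_grid=600)
        assert scan.transition is None
        assert np.all(scan.H_eq_series > params.H_max - 1.0)


class TestBindingBudget:
    def test_zero_budget_returns_equilibrium(self, params):
        p = params.with_(epsilon=3.0)
        eq = equilibrium_height(p)
        state = max_opening_under_binding(p, 0.0)
        assert state == eq

    def test_negative_budget_rejected(self, params):
        with pytest.raises(ValueError):
            max_opening_under_binding(params, -1.0)

    def test_monotone_in_budget_and_matches_grid_oracle(self, params):
        """Opening never shrinks with budget; agrees with a fine-grid sweep."""
        p = params.with_(epsilon=3.0)
        H = np.linspace(p.H_floor, p.H_max, 50_000)
        F = free_energy_per_chain(H, p)
        F_eq = equilibrium_height(p).F_eq
        step = H[1] - H[0]
        previous = -np.inf
        for E in [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0]:
            state = max_opening_under_binding(p, E)
            assert state.opening_diameter >= previous - 1e-9
            previous = state.opening_diameter
            H_oracle = H[F <= F_eq + E][0] if E > 0 else equilibrium_height(p).H_eq
            assert abs(state.H_eq - H_oracle) <= step + 1e-4
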