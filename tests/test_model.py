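"""Core model: right-hand sides, conservation, closed-form equilibria, bounds."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from ifxsim import (
    ModelParams,
    ModelState,
    conserved_total,
    drug_free_equilibria,
    equilibrium_bound_fraction,
    production_rate_at_equilibrium,
    rhs_constant_production,
    rhs_full,
    rhs_reduced,
    theoretical_bounds,
)
from ifxsim.model import jac_constant_production, jac_full, jac_reduced

state_strategy = st.tuples(
    st.floats(1e-14, 1e-9),   # L
    st.floats(0.0, 1.0),      # r
    st.floats(0.0, 1e-5),     # A
    st.floats(0.0, 1e-9),     # C
)


class TestRhsFull:
    def test_empty_system_is_stationary(self, params):
        d = rhs_full(0.0, (0.0, 0.0, 0.0, 0.0), params)
        assert np.all(d == 0.0)

    def test_cd_equilibrium_is_stationary(self, params, cd_init):
        eq = drug_free_equilibria(params, cd_init.tnf, cd_init.r, cd_init.cx)
        d = rhs_full(0.0, (eq.L_star, eq.r_star, 0.0, 0.0), params)
        assert np.all(np.abs(d) < 1e-18)

    @given(state=state_strategy, w=st.floats(0.0, 1e-9))
    def test_weighted_derivative_sum_vanishes(self, state, w):
        """dL + r_tot*dr + dC == 0 for any state and any drug input."""
        p = ModelParams()
        d = rhs_full(0.0, state, p, drug_input_rate=w)
        assert abs(d[0] + p.r_tot * d[1] + d[3]) < 1e-22

    def test_rejects_non_finite_state(self, params):
        with pytest.raises(ValueError):
            rhs_full(0.0, (np.nan, 0.1, 0.0, 0.0), params)
        with pytest.raises(ValueError):
            rhs_full(0.0, (1e-11, 0.1, 0.0, 0.0), params, drug_input_rate=-1.0)


class TestRhsConstantProduction:
    def test_calibrated_production_is_stationary_at_equilibrium(self, params, cd_init):
        eq = drug_free_equilibria(params, cd_init.tnf, cd_init.r)
        w1 = production_rate_at_equilibrium(params, eq.L_star, eq.r_star)
        d = rhs_constant_production(0.0, (eq.L_star, eq.r_star, 0.0, 0.0), params, w1)
        assert np.all(np.abs(d) < 1e-18)

    def test_zero_production_leaves_only_loss_terms(self, params):
        L = 1e-11
        d = rhs_constant_production(0.0, (L, 0.0, 0.0, 0.0), params, 0.0)
        expected = -params.k_on * params.r_tot * L - params.k_el_tnf * L
        assert d[0] == pytest.approx(expected, rel=1e-14)

    @given(state=state_strategy)
    def test_production_difference_identity(self, state):
        """The two systems differ only by the production/clearance closure of L."""
        p = ModelParams()
        w1 = 2.0e-14
        L, r, A, C = state
        diff = rhs_constant_production(0.0, state, p, w1) - rhs_full(0.0, state, p)
        expected = w1 - (p.k_int * r * p.r_tot + p.k_el_cx * C + p.k_el_tnf * L)
        assert diff[0] == pytest.approx(expected, rel=1e-10, abs=1e-25)
        assert np.all(diff[1:] == 0.0)


class TestRhsReduced:
    def test_zero_pool_is_stationary(self, params):
        assert np.all(rhs_reduced(0.0, (0.0, 0.0, 0.0), params, 0.0) == 0.0)

    def test_matches_full_system_through_conservation(self, params, cd_init):
        P0 = conserved_total(cd_init, params)
        state = (cd_init.tnf, cd_init.r, 1e-6, 5e-12)
        P0s = state[0] + params.r_tot * state[1] + state[3]
        d_full = rhs_full(0.0, state, params, 1e-10)
        d_red = rhs_reduced(0.0, (state[1], state[2], state[3]), params, P0s, 1e-10)
        assert d_red == pytest.approx(d_full[1:], rel=1e-15)
        assert P0 > 0  # CD pool sanity

    def test_saturated_complex_decays_without_association(self, params):
        P0 = 5e-11
        d = rhs_reduced(0.0, (0.0, 1e-6, P0), params, P0)
        assert d[2] == pytest.approx(-(params.k_off_ab + params.k_el_cx) * P0, rel=1e-14)

    def test_conservation_violation_raises(self, params):
        with pytest.raises(ValueError, match="conservation"):
            rhs_reduced(0.0, (0.9, 0.0, 1e-9), params, 1e-12)


class TestJacobians:
    @pytest.mark.parametrize("system", ["full", "constant_production", "reduced"])
    def test_matches_finite_differences(self, params, system):
        rng = np.random.default_rng(7)
        y = np.array([3e-11, 0.2, 1e-7, 2e-11])
        w = 1e-10
        if system == "full":
            f = lambda y_: rhs_full(0.0, y_, params, w)
            J = jac_full(0.0, y, params, w)
        elif system == "constant_production":
            f = lambda y_: rhs_constant_production(0.0, y_, params, 2e-14, w)
            J = jac_constant_production(0.0, y, params, 2e-14, w)
        else:
            y = y[1:]
            f = lambda y_: rhs_reduced(0.0, y_, params, 8e-11, w)
            J = jac_reduced(0.0, y, params, 8e-11, w)
        # the RHS is bilinear in the states, so central differences are exact
        # up to roundoff; a generous step keeps the roundoff negligible
        for j in range(len(y)):
            h = max(abs(y[j]), 1e-12) * 1e-3
            e = np.zeros(len(y))
            e[j] = h
            fd = (f(y + e) - f(y - e)) / (2 * h)
            assert J[:, j] == pytest.approx(fd, rel=1e-5, abs=1e-20)
        assert rng is not None


class TestConservedTotal:
    def test_cd_pool(self, params, cd_init):
        assert conserved_total(cd_init, params) == pytest.approx(5.5905e-11, rel=1e-12)

    def test_uc_pool(self, params, uc_init):
        assert conserved_total(uc_init, params) == pytest.approx(3.9905e-11, rel=1e-12)

    def test_zero_state(self, params):
        assert conserved_total((0.0, 0.0, 0.0, 0.0), params) == 0.0


class TestDrugFreeEquilibria:
    def test_cd_equilibrium_matches_reported_value(self, params, cd_init):
        eq = drug_free_equilibria(params, cd_init.tnf, cd_init.r)
        assert eq.meaningful_root == 2
        assert eq.L_star == pytest.approx(2.07e-11, rel=5e-3)

    def test_uc_equilibrium_matches_reported_value(self, params, uc_init):
        eq = drug_free_equilibria(params, uc_init.tnf, uc_init.r)
        assert eq.L_star == pytest.approx(1.40e-11, rel=5e-3)

    def test_roots_satisfy_quadratic(self, params, cd_init):
        eq = drug_free_equilibria(params, cd_init.tnf, cd_init.r)
        for r in (eq.r1_star, eq.r2_star):
            resid = eq.a * r * r + eq.b * r + eq.c
            assert abs(resid) <= 1e-12 * max(abs(eq.a * r * r), abs(eq.b * r), abs(eq.c))

    def test_empty_pool_gives_zero_equilibrium(self, params):
        eq = drug_free_equilibria(params, 0.0, 0.0)
        assert eq.r_star == pytest.approx(0.0, abs=1e-15)
        assert eq.L_star == pytest.approx(0.0, abs=1e-25)

    def test_admissible_pair_within_bounds(self, params, cd_init):
        eq = drug_free_equilibria(params, cd_init.tnf, cd_init.r)
        assert 0.0 <= eq.r_star <= 1.0
        assert 0.0 <= eq.L_star <= eq.total_pool

    def test_closed_form_agrees_with_root_finder_oracle(self):
        """Closed form vs independent brentq root-find on the drug-free slice.

        With A = C = 0 and the conserved pool fixed, equilibria solve the
        scalar occupancy balance k_on(1-r)(P0 - r_tot r) = (k_off + k_int) r.
        """
        rng = np.random.default_rng(2024)
        for _ in range(50):
            p = ModelParams(
                k_on=10 ** rng.uniform(6, 8),
                k_off=10 ** rng.uniform(-4.5, -3),
                r_tot=10 ** rng.uniform(-11, -9),
                k_int=10 ** rng.uniform(-4.5, -3),
            )
            L0 = 10 ** rng.uniform(-12, -10)
            r0 = rng.uniform(0.01, 0.5)
            eq = drug_free_equilibria(p, L0, r0)
            P0 = eq.total_pool

            def balance(r):
                return p.k_on * (1 - r) * (P0 - p.r_tot * r) - (p.k_off + p.k_int) * r

            r_oracle = brentq(balance, 0.0, min(1.0, P0 / p.r_tot), xtol=1e-18, rtol=1e-14)
            assert eq.r_star == pytest.approx(r_oracle, rel=1e-10)

    def test_meaningful_equilibrium_stationary_for_calibrated_production(self, params, cd_init):
        """Eq-consistency: the production calibrated at an equilibrium of the
        dynamic system also holds the constant-production system stationary."""
        eq = drug_free_equilibria(params, cd_init.tnf, cd_init.r)
        w1 = production_rate_at_equilibrium(params, eq.L_star, eq.r_star)
        d = rhs_constant_production(0.0, (eq.L_star, eq.r_star, 0.0, 0.0), params, w1)
        assert np.all(np.abs(d) < 1e-18)


class TestBoundFraction:
    def test_limits(self, params):
        assert equilibrium_bound_fraction(0.0, params) == 0.0
        assert equilibrium_bound_fraction(math.inf, params) == 1.0

    def test_matches_quadratic_root_at_cd_equilibrium(self, params, cd_init):
        eq = drug_free_equilibria(params, cd_init.tnf, cd_init.r)
        r = equilibrium_bound_fraction(eq.L_star, params)
        assert r == pytest.approx(0.2345, abs=1e-4)
        assert r == pytest.approx(eq.r_star, rel=1e-10)

    @given(st.floats(0, 1e-6), st.floats(1e-12, 1e-3))
    def test_monotone_and_bounded(self, L, dL):
        p = ModelParams()
        lo, hi = equilibrium_bound_fraction(L, p), equilibrium_bound_fraction(L + dL, p)
        assert 0.0 <= lo < 1.0
        assert hi >= lo


class TestProductionRate:
    def test_cd_value_matches_reported(self, params, cd_init):
        eq = drug_free_equilibria(params, cd_init.tnf, cd_init.r)
        w1 = production_rate_at_equilibrium(params, eq.L_star, eq.r_star)
        assert w1 == pytest.approx(2.1315e-14, rel=5e-5)

    def test_uc_value(self, params, uc_init):
        eq = drug_free_equilibria(params, uc_init.tnf, uc_init.r)
        w1 = production_rate_at_equilibrium(params, eq.L_star, eq.r_star)
        assert w1 == pytest.approx(1.564e-14, rel=1e-3)

    def test_zero_equilibrium(self, params):
        assert production_rate_at_equilibrium(params, 0.0, 0.0, 0.0) == 0.0


class TestTheoreticalBounds:
    def test_no_input_no_drug(self, params):
        b = theoretical_bounds(ModelState(1e-11, 0.1), params, 0.0)
        assert b.ab_cx_max == 0.0
        assert b.r_max == 1.0

    def test_infusion_bound_uses_smaller_clearance(self, params, cd_init):
        b = theoretical_bounds(cd_init, params, 3.3713e-10)
        assert b.ab_cx_max == pytest.approx(3.3713e-10 / 8.5e-7, rel=1e-12)

    def test_tnf_bound_is_conserved_pool(self, params, cd_init):
        b = theoretical_bounds(cd_init, params, 0.0)
        assert b.tnf_max == pytest.approx(5.5905e-11, rel=1e-12)


class TestValidation:
    def test_params_reject_nonpositive(self):
        with pytest.raises(ValueError):
            ModelParams(k_on=0.0)
        with pytest.raises(ValueError):
            ModelParams(r_tot=-1e-10)

    def test_clearance_outside_window_warns(self):
        with pytest.warns(UserWarning, match="literature range"):
            ModelParams(k_el_ab=1e-6)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            ModelState(tnf=-1e-9, r=0.1)
        with pytest.raises(ValueError):
            ModelState(tnf=1e-11, r=1.5)
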