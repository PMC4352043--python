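"""Core PDE, solvers, Keiding integral and algebraic inversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from illnessdeath import (
    DomainError,
    RateSet,
    RateSurface,
    SingularInversionError,
    general_mortality,
    invert_incidence,
    invert_remission,
    keiding_prevalence,
    pde_rhs,
    pde_rhs_relative,
    solve_prevalence_cohort,
    solve_prevalence_surface,
    solve_SC_system,
)
from conftest import constant_rates

hazards = st.floats(min_value=0.0, max_value=1.0)
hazards_pos = st.floats(min_value=1e-6, max_value=1.0)
probs = st.floats(min_value=0.001, max_value=0.999)


class TestRightHandSides:
    @pytest.mark.parametrize(
        "p,i,r,mA,mB,expected",
        [
            (0.0, 0.1, 0.5, 0.02, 0.02, 0.1),  # at p=0 the rhs reduces to i
            (1.0, 0.3, 0.2, 0.05, 0.9, -0.2),  # at p=1 the rhs reduces to -r
            (0.2, 0.05, 0.01, 0.01, 0.02, 0.0364),  # hand-evaluated
        ],
    )
    def test_state_specific_form(self, p, i, r, mA, mB, expected):
        assert pde_rhs(p, i, r, mA, mB) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "p,i,r,m,R,expected",
        [
            (0.3, 0.1, 0.0, 0.5, 1.0, 0.07),  # R=1 kills the mortality term
            (0.0, 0.07, 0.4, 0.3, 3.0, 0.07),  # at p=0 the rhs is i
            (0.2, 0.05, 0.01, 0.012, 2.0, 0.0364),  # m, R from mA=0.01, mB=0.02
        ],
    )
    def test_relative_form(self, p, i, r, m, R, expected):
        assert pde_rhs_relative(p, i, r, m, R) == pytest.approx(expected, abs=1e-12)

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            pde_rhs(1.2, 0.1, 0.0, 0.0, 0.0)
        with pytest.raises(DomainError):
            pde_rhs_relative(-0.1, 0.1, 0.0, 0.0, 1.0)

    @given(p=probs, i=hazards, r=hazards, mA=hazards_pos, mB=hazards_pos)
    @settings(derandomize=True, max_examples=200)
    def test_parameterization_equivalence(self, p, i, r, mA, mB):
        """Both mortality forms agree when (m, R) are computed from (p, mA, mB)."""
        m = general_mortality(p, mA, mB)
        R = mB / mA
        lhs = pde_rhs(p, i, r, mA, mB)
        rhs = pde_rhs_relative(p, i, r, m, R)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    @pytest.mark.parametrize("p,expected", [(0.0, 0.01), (1.0, 0.02), (0.2, 0.012)])
    def test_general_mortality_convex_combination(self, p, expected):
        m = general_mortality(p, 0.01, 0.02)
        assert m == pytest.approx(expected, abs=1e-15)
        assert 0.01 <= m <= 0.02


class TestCohortSolver:
    def test_zero_rates_keep_prevalence_constant(self):
        traj = solve_prevalence_cohort(constant_rates(), 0.0, 0.0, 0.4, 20.0)
        assert np.allclose(traj.p_values, 0.4)

    def test_constant_incidence_closed_form(self):
        # r=0, mA=mB: p(a) = 1 - exp(-i a)
        traj = solve_prevalence_cohort(constant_rates(i=0.1, mA=0.02, mB=0.02), 0.0, 0.0, 0.0, 10.0)
        assert traj.final_p() == pytest.approx(1 - np.exp(-1), abs=1e-8)

    def test_equilibrium_is_a_fixed_point(self):
        # p* = i/(i+r) solves (1-p) i - r p = 0 when mA = mB
        rs = constant_rates(i=0.02, r=0.08, mA=0.01, mB=0.01)
        traj = solve_prevalence_cohort(rs, 0.0, 0.0, 0.2, 50.0)
        assert np.allclose(traj.p_values, 0.2, atol=1e-12)

    def test_range_preservation_under_extreme_rates(self):
        rs = constant_rates(i=5.0, r=4.0, mA=0.5, mB=3.0)
        traj = solve_prevalence_cohort(rs, 0.0, 0.0, 0.0, 60.0, step=0.25)
        assert np.all((traj.p_values >= 0) & (traj.p_values <= 1))

    def test_rk4_step_convergence_order(self):
        """Halving the step shrinks the closed-form error by about 2^4."""
        rs = constant_rates(i=0.3, mA=0.02, mB=0.02)
        exact = 1 - np.exp(-0.3 * 10)
        errs = []
        for step in (0.8, 0.4, 0.2):
            traj = solve_prevalence_cohort(rs, 0.0, 0.0, 0.0, 10.0, step=step)
            errs.append(abs(traj.final_p() - exact))
        ratios = [errs[k] / errs[k + 1] for k in range(2)]
        assert all(r > 8 for r in ratios)  # nominal order 4 -> ratio ~16

    def test_invalid_start_rejected(self):
        with pytest.raises(DomainError):
            solve_prevalence_cohort(constant_rates(), 0.0, 0.0, 1.5, 10.0)

    def test_characteristic_clipped_at_domain_edge(self):
        rs = RateSet(
            i=RateSurface.constant(0.1, t_bounds=(0.0, 30.0), a_bounds=(0.0, 50.0)),
            r=RateSurface.constant(0.0, t_bounds=(0.0, 30.0), a_bounds=(0.0, 50.0)),
            m_A=RateSurface.constant(0.0, t_bounds=(0.0, 30.0), a_bounds=(0.0, 50.0)),
            m_B=RateSurface.constant(0.0, t_bounds=(0.0, 30.0), a_bounds=(0.0, 50.0)),
        )
        traj = solve_prevalence_cohort(rs, t0=10.0, a0=0.0, p0=0.0, a_end=40.0)
        assert traj.truncated
        assert traj.ages[-1] == pytest.approx(20.0, abs=1e-6)


class TestSurfaceSolver:
    def test_zero_rates_zero_boundary(self):
        surf = solve_prevalence_surface(constant_rates(), np.arange(50, 55.0), np.arange(0, 10.0))
        assert np.allclose(surf.p, 0.0)

    def test_time_constant_rates_give_time_constant_surface(self):
        rs = constant_rates(i=0.05, r=0.02, mA=0.01, mB=0.03)
        surf = solve_prevalence_surface(rs, np.arange(100, 105.0), np.arange(0, 40, 5.0))
        assert np.allclose(surf.p, surf.p[0][None, :], atol=1e-9)

    def test_matches_cohort_solver_at_shared_nodes(self, smooth_rates):
        surf = solve_prevalence_surface(smooth_rates, np.array([80.0]), np.array([25.0]), step=0.05)
        traj = solve_prevalence_cohort(smooth_rates, t0=55.0, a0=0.0, p0=0.0, a_end=25.0, step=0.05)
        assert surf.p[0, 0] == pytest.approx(traj.final_p(), abs=1e-9)


class TestSCSystem:
    def test_no_incidence_means_no_cases(self):
        rs = constant_rates(i=0.0, r=0.1, mA=0.02, mB=0.05)
        S, C = solve_SC_system(rs, np.arange(60, 63.0), np.arange(0, 30, 10.0), lambda t: 500.0)
        assert np.allclose(C, 0.0)
        assert np.all(S > 0)

    def test_two_state_markov_closed_form(self):
        # equal mortalities cancel in the prevalence: p(a) = i/(i+r) (1 - e^{-(i+r)a})
        i, r = 0.02, 0.08
        rs = constant_rates(i=i, r=r, mA=0.01, mB=0.01)
        S, C = solve_SC_system(rs, np.array([60.0]), np.array([30.0]), lambda t: 1000.0, step=0.05)
        p = C / (S + C)
        expected = i / (i + r) * (1 - np.exp(-(i + r) * 30))
        assert p[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_consistency_with_prevalence_surface(self, smooth_rates):
        t_grid = np.array([70.0, 75.0])
        a_grid = np.array([10.0, 20.0, 30.0])
        S, C = solve_SC_system(smooth_rates, t_grid, a_grid, lambda t: 1234.0, step=0.02)
        surf = solve_prevalence_surface(smooth_rates, t_grid, a_grid, step=0.02)
        assert np.nanmax(np.abs(C / (S + C) - surf.p)) < 1e-6

    def test_prevalence_scale_free_in_newborns(self, smooth_rates):
        t_grid = np.array([70.0])
        a_grid = np.array([20.0])
        p_vals = []
        for n0 in (10.0, 1e6):
            S, C = solve_SC_system(smooth_rates, t_grid, a_grid, lambda t: n0, step=0.05)
            p_vals.append((C / (S + C))[0, 0])
        assert p_vals[0] == pytest.approx(p_vals[1], abs=1e-12)

    def test_negative_newborns_rejected(self):
        with pytest.raises(ValueError):
            solve_SC_system(constant_rates(), np.array([60.0]), np.array([10.0]), lambda t: -5.0)


class TestKeidingIntegral:
    def test_zero_incidence_gives_zero_prevalence(self):
        z = RateSurface.constant(0.0)
        m = RateSurface.constant(0.05)
        assert keiding_prevalence(z, m, m, t=50.0, a=30.0) == 0.0

    def test_constant_rates_closed_form(self):
        i = RateSurface.constant(0.1)
        m = RateSurface.constant(0.02)
        p = keiding_prevalence(i, m, m, t=50.0, a=10.0)
        assert p == pytest.approx(1 - np.exp(-1), abs=1e-9)

    def test_agrees_with_pde_solver_under_differential_mortality(self, smooth_rates):
        p_int = keiding_prevalence(smooth_rates.i, smooth_rates.m_A, smooth_rates.m_B, t=80.0, a=30.0)
        traj = solve_prevalence_cohort(smooth_rates, t0=50.0, a0=0.0, p0=0.0, a_end=30.0, step=0.02)
        assert abs(p_int - traj.final_p()) < 1e-5

    def test_negative_age_rejected(self):
        z = RateSurface.constant(0.1)
        with pytest.raises(DomainError):
            keiding_prevalence(z, z, z, t=50.0, a=-1.0)


class TestInversions:
    def test_incidence_inversion_worked_example(self):
        assert invert_incidence(0.0364, 0.2, 0.01, 0.01, 0.02) == pytest.approx(0.05, abs=1e-12)

    def test_remission_inversion_worked_example(self):
        assert invert_remission(0.0364, 0.2, 0.05, 0.01, 0.02) == pytest.approx(0.01, abs=1e-12)

    def test_incidence_at_zero_prevalence_is_the_derivative(self):
        assert invert_incidence(0.033, 0.0, 0.0, 0.4, 0.9) == pytest.approx(0.033, abs=1e-15)

    def test_remission_zero_when_derivative_saturates(self):
        # dp = (1-p) i with mA = mB leaves no room for remission
        p, i = 0.37, 0.08
        assert invert_remission((1 - p) * i, p, i, 0.02, 0.02) == pytest.approx(0.0, abs=1e-12)

    @given(p=probs, i=hazards, r=hazards, mA=hazards, mB=hazards)
    @settings(derandomize=True, max_examples=200)
    def test_round_trips_are_algebraic_identities(self, p, i, r, mA, mB):
        dp = pde_rhs(p, i, r, mA, mB)
        assert invert_incidence(dp, p, r, mA, mB) == pytest.approx(i, abs=1e-12)
        assert invert_remission(dp, p, i, mA, mB) == pytest.approx(r, abs=1e-12)

    def test_singular_cells_are_reported_not_infinite(self):
        with pytest.raises(SingularInversionError):
            invert_incidence(0.01, 1.0 - 1e-12, 0.0, 0.0, 0.0)
        with pytest.raises(SingularInversionError):
            invert_remission(0.01, 1e-12, 0.1, 0.0, 0.0)


class TestRateSurfaceDomain:
    def test_out_of_domain_evaluation_is_an_error(self):
        s = RateSurface.constant(0.1, t_bounds=(0.0, 10.0), a_bounds=(0.0, 5.0))
        with pytest.raises(DomainError):
            s(11.0, 1.0)
        with pytest.raises(DomainError):
            s(5.0, 6.0)

    def test_negative_rate_functions_rejected_on_evaluation(self):
        s = RateSurface(lambda t, a: -1.0 + 0 * np.asarray(t, float))
        with pytest.raises(ValueError):
            s(1.0, 1.0)

    def test_mortality_parameterization_exclusivity(self):
        c = RateSurface.constant(0.1)
        with pytest.raises(ValueError):
            RateSet(i=c, r=c, m_A=c, m_B=c, m=c, R=c)
        with pytest.raises(ValueError):
            RateSet(i=c, r=c)
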