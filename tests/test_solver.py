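import numpy as np
import pytest

import undiag as u
from undiag.boundaries import BoundaryCurve, CountsInitialData, InitialData
from undiag.model import LexisPoint, PrevalenceState
from undiag.solver import (_arc_samples, characteristic_foot, prevalence_foot,
                           solve_along_characteristic)


class TestCharacteristicFoot:
    half = InitialData(u.HALF_PLANE, BoundaryCurve.constant((0.05, 0.1)))
    quad = InitialData(u.FIRST_QUADRANT, BoundaryCurve.constant((0.0, 0.0)),
                       age_axis=BoundaryCurve.constant((0.05, 0.1)), t_min=1999.0)

    def test_half_plane_traces_to_birth(self):
        start, value, arc = prevalence_foot(LexisPoint(2010.0, 60.0), self.half)
        assert (start.t, start.a) == (1950.0, 0.0)
        assert arc == 60.0
        assert (value.p1, value.p2) == (0.05, 0.1)

    def test_quadrant_cohort_born_before_window_enters_left_edge(self):
        start, value, arc = prevalence_foot(LexisPoint(2005.0, 60.0), self.quad)
        assert (start.t, start.a) == (1999.0, 54.0)
        assert arc == 6.0
        assert (value.p1, value.p2) == (0.05, 0.1)

    def test_quadrant_young_cohort_enters_abscissa(self):
        start, value, arc = prevalence_foot(LexisPoint(2005.0, 3.0), self.quad)
        assert (start.t, start.a) == (2002.0, 0.0)
        assert arc == 3.0
        assert (value.p1, value.p2) == (0.0, 0.0)

    def test_point_left_of_window_rejected(self):
        with pytest.raises(u.DomainError, match="t_min"):
            characteristic_foot(LexisPoint(1998.0, 10.0), self.quad)


class TestArcSampling:
    def test_partial_final_step_lands_exactly_on_arc(self):
        s = _arc_samples(1.03, 0.25)
        assert s[0] == 0.0 and s[-1] == 1.03
        assert np.all(np.diff(s) > 0)
        assert np.max(np.diff(s)) <= 0.25 + 1e-12

    def test_whole_multiple_has_uniform_steps(self):
        s = _arc_samples(1.0, 0.25)
        assert np.allclose(np.diff(s), 0.25)
        assert s[-1] == 1.0

    def test_zero_arc(self):
        assert list(_arc_samples(0.0, 0.1)) == [0.0]


class TestCharacteristicIntegration:
    def test_zero_rates_freeze_the_state(self):
        rs = u.RateSet(lambda0=u.ConstantRate(0.0), lambda1=u.ConstantRate(0.0),
                       mode=u.GENERAL_MU, mu=u.ConstantRate(0.0), r1=1.0, r2=1.0)
        sol = solve_along_characteristic(LexisPoint(2000.0, 5.0),
                                         PrevalenceState(0.2, 0.3), rs, 20.0, 0.5)
        assert np.all(sol.states == [0.2, 0.3])

    def test_matches_matrix_exponential_for_constant_rates(self, const_general_rates):
        sol = solve_along_characteristic(LexisPoint(2000.0, 0.0),
                                         PrevalenceState(0.0, 0.0),
                                         const_general_rates, 50.0, 0.1)
        ref = u.constant_rate_closed_form(0.08, 0.3, 0.01, 0.011, 0.012, (0.0, 0.0), 50.0)
        assert np.max(np.abs(sol.final - ref)) < 1e-6

    def test_rate_domain_violation_reports_point(self):
        mu = u.GriddedRate([1999.0, 2005.0], [0.0, 40.0],
                           np.full((2, 2), 0.01), name="mu")
        rs = u.RateSet(lambda0=u.ConstantRate(0.1), lambda1=u.ConstantRate(0.0),
                       mode=u.GENERAL_MU, mu=mu, r1=1.0, r2=1.0)
        with pytest.raises(u.RateDomainError, match="mu"):
            solve_along_characteristic(LexisPoint(1999.0, 0.0),
                                       PrevalenceState(0.0, 0.0), rs, 50.0, 0.5)


class TestSolveSurface:
    grid = u.LexisGrid.from_range(2000.0, 2006.0, 2.0, 0.0, 30.0, 5.0)

    def test_no_incidence_keeps_surface_empty(self, zero_boundary_half_plane):
        rs = u.RateSet(lambda0=u.ConstantRate(0.0), lambda1=u.ConstantRate(0.3),
                       mode=u.GENERAL_MU, mu=u.ConstantRate(0.01), r1=1.0, r2=1.2)
        surf = u.solve_surface(rs, zero_boundary_half_plane, self.grid)
        assert np.all(surf.p1 == 0.0) and np.all(surf.p2 == 0.0)

    def test_constant_rates_give_time_invariant_surface(self, const_general_rates,
                                                        zero_boundary_half_plane):
        surf = u.solve_surface(const_general_rates, zero_boundary_half_plane, self.grid)
        for i in range(1, self.grid.t_levels.size):
            assert np.array_equal(surf.p1[i], surf.p1[0])
            assert np.array_equal(surf.p2[i], surf.p2[0])

    def test_deterministic_bit_identical(self, const_general_rates,
                                         zero_boundary_half_plane):
        a = u.solve_surface(const_general_rates, zero_boundary_half_plane, self.grid)
        b = u.solve_surface(const_general_rates, zero_boundary_half_plane, self.grid)
        assert np.array_equal(a.p1, b.p1) and np.array_equal(a.p2, b.p2)

    def test_every_node_equals_its_own_characteristic_solve(self, const_state_rates,
                                                            zero_boundary_half_plane):
        # non-aligned step exercises the per-node fallback path
        for step in (0.25, 0.3):
            surf = u.solve_surface(const_state_rates, zero_boundary_half_plane,
                                   self.grid, step=step)
            for i, t in enumerate(self.grid.t_levels):
                for j, a in enumerate(self.grid.a_levels):
                    start, p0, arc = prevalence_foot(LexisPoint(t, a),
                                                     zero_boundary_half_plane)
                    if arc == 0:
                        continue
                    ref = solve_along_characteristic(start, p0, const_state_rates,
                                                     arc, step).final
                    assert surf.p1[i, j] == ref[0] and surf.p2[i, j] == ref[1]

    def test_inconsistent_general_mu_triggers_simplex_diagnostic(self,
                                                                 zero_boundary_half_plane):
        # huge "overall" mortality with low state mortalities inflates p
        rs = u.RateSet(lambda0=u.ConstantRate(0.5), lambda1=u.ConstantRate(0.5),
                       mode=u.GENERAL_MU, mu=u.ConstantRate(0.5),
                       mu1=u.ConstantRate(0.0), mu2=u.ConstantRate(0.0))
        with pytest.raises(u.SimplexError, match="simplex"):
            u.solve_surface(rs, zero_boundary_half_plane, self.grid)
        with pytest.warns(RuntimeWarning, match="simplex"):
            u.solve_surface(rs, zero_boundary_half_plane, self.grid, simplex="warn")


class TestSolveCounts:
    grid = u.LexisGrid.from_range(2000.0, 2004.0, 2.0, 0.0, 20.0, 5.0)

    def test_closed_population_is_conserved_without_mortality(self,
                                                              unit_counts_half_plane):
        rs = u.RateSet(lambda0=u.ConstantRate(0.0), lambda1=u.ConstantRate(0.0),
                       mode=u.STATE_SPECIFIC, mu0=u.ConstantRate(0.0),
                       mu1=u.ConstantRate(0.0), mu2=u.ConstantRate(0.0))
        cs = u.solve_counts(rs, unit_counts_half_plane, self.grid)
        assert np.allclose(cs.total, 1.0, atol=1e-14)
        assert np.all(cs.N1 == 0.0) and np.all(cs.N2 == 0.0)

    def test_cumulative_incidence_closed_form(self, unit_counts_half_plane):
        """Without mortality or detection, N1/N = 1 - exp(-lambda0 * a)."""
        lam0 = 0.1
        rs = u.RateSet(lambda0=u.ConstantRate(lam0), lambda1=u.ConstantRate(0.0),
                       mode=u.STATE_SPECIFIC, mu0=u.ConstantRate(0.0),
                       mu1=u.ConstantRate(0.0), mu2=u.ConstantRate(0.0))
        cs = u.solve_counts(rs, unit_counts_half_plane, self.grid, step=0.1)
        for j, a in enumerate(self.grid.a_levels):
            expected = 1.0 - np.exp(-lam0 * a)
            assert cs.N1[0, j] / cs.total[0, j] == pytest.approx(expected, abs=1e-8)

    def test_total_nonincreasing_along_life_lines(self, const_state_rates,
                                                  unit_counts_half_plane):
        cs = u.solve_counts(const_state_rates, unit_counts_half_plane, self.grid)
        # constant rates: N(t, a) depends on a only; totals fall with age
        totals = cs.total[0]
        assert np.all(np.diff(totals) < 0)
        assert np.all(cs.N0 >= 0) and np.all(cs.N1 >= 0) and np.all(cs.N2 >= 0)


class TestCompatibility:
    def test_half_plane_has_no_corner(self):
        init = InitialData(u.HALF_PLANE, BoundaryCurve.constant((0.0, 0.0)))
        with pytest.raises(ValueError, match="first quadrant"):
            u.check_compatibility(init)

    def test_matching_data_pass(self):
        init = InitialData(
            u.FIRST_QUADRANT, BoundaryCurve.constant((0.0, 0.0)),
            age_axis=BoundaryCurve(fn=lambda a: np.stack(
                [0.3 * (1 - np.exp(-0.05 * np.asarray(a)))**2,
                 np.zeros_like(np.asarray(a, dtype=float))], axis=-1)),
            t_min=1999.0)
        report = u.check_compatibility(init, tol_value=1e-12, tol_slope=1e-4)
        assert report.passed
        assert report.value_gap == 0.0

    def test_value_gap_reported_and_solve_rejected(self, const_state_rates):
        init = InitialData(u.FIRST_QUADRANT, BoundaryCurve.constant((0.0, 0.0)),
                           age_axis=BoundaryCurve.constant((0.05, 0.0)),
                           t_min=1999.0)
        report = u.check_compatibility(init)
        assert report.value_gap == pytest.approx(0.05)
        assert not report.passed
        grid = u.LexisGrid.from_range(1999.0, 2005.0, 1.0, 0.0, 20.0, 5.0)
        with pytest.raises(u.CompatibilityError, match="0.05|5.000e-02"):
            u.solve_surface(const_state_rates, init, grid)


class TestConvergenceOrder:
    def closed_form_setup(self):
        rs = u.RateSet(lambda0=u.ConstantRate(0.1), lambda1=u.ConstantRate(0.0),
                       mode=u.GENERAL_MU, mu=u.ConstantRate(0.01), r1=1.0, r2=1.0)
        ref = np.array([1.0 - np.exp(-1.0), 0.0])
        return rs, ref

    def test_euler_control_is_first_order(self):
        rs, ref = self.closed_form_setup()
        est = u.convergence_order(rs, LexisPoint(2000.0, 0.0), PrevalenceState(0.0, 0.0),
                                  10.0, [0.4, 0.2, 0.1], reference=ref, method="euler")
        assert 0.8 <= est.order <= 1.2

    def test_zero_rates_have_undefined_order(self):
        rs = u.RateSet(lambda0=u.ConstantRate(0.0), lambda1=u.ConstantRate(0.0),
                       mode=u.GENERAL_MU, mu=u.ConstantRate(0.0), r1=1.0, r2=1.0)
        est = u.convergence_order(rs, LexisPoint(2000.0, 0.0), PrevalenceState(0.1, 0.1),
                                  10.0, [0.4, 0.2, 0.1],
                                  reference=np.array([0.1, 0.1]))
        assert not est.defined
        assert np.all(est.errors < 1e-13)
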