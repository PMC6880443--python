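import numpy as np
import pandas as pd
import pytest

import undiag as u
from undiag.boundaries import BoundaryCurve, InitialData
from undiag.model import PrevalenceState
from undiag.surfaces import LexisGrid, PrevalenceSurface
from undiag.synthetic import SurveySample


class TestDecomposeAwareness:
    def test_basic_split(self):
        p = u.decompose_awareness(0.5, 0.7)
        assert (p.p1, p.p2) == pytest.approx((0.15, 0.35))

    @pytest.mark.parametrize("total,aware,expected", [
        (0.3, 1.0, (0.0, 0.3)),   # full awareness: everything diagnosed
        (0.3, 0.0, (0.3, 0.0)),   # no awareness: everything undiagnosed
        (0.0, 0.6, (0.0, 0.0)),   # no disease at all
    ])
    def test_edge_cases(self, total, aware, expected):
        p = u.decompose_awareness(total, aware)
        assert (p.p1, p.p2) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            u.decompose_awareness(1.2, 0.5)
        with pytest.raises(ValueError):
            u.decompose_awareness(0.5, -0.1)

    def test_array_input_preserves_total(self):
        rng = np.random.default_rng(2)
        total = rng.uniform(0, 1, 20)
        aware = rng.uniform(0, 1, 20)
        p1, p2 = u.decompose_awareness(total, aware)
        assert np.allclose(p1 + p2, total)
        assert np.all(p1 >= 0) and np.all(p2 >= 0)


class TestHypertensionScenario:
    def test_mortality_ratios_match_the_assumed_values(self, hyp_scenario):
        assert hyp_scenario.rates.r1 == 1.1
        assert hyp_scenario.rates.r2 == 1.2

    def test_corner_compatibility_is_exact(self, hyp_scenario):
        report = u.check_compatibility(hyp_scenario.initial,
                                       tol_value=1e-10, tol_slope=1e-10)
        assert report.passed
        assert report.value_gap == 0.0
        assert report.slope_gap == 0.0

    def test_total_prevalence_monotone_in_age_over_adulthood(self, hyp_surface):
        grid = hyp_surface.grid
        adult = (grid.a_levels >= 18) & (grid.a_levels <= 70)
        total = hyp_surface.total[:, adult]
        assert np.all(np.diff(total, axis=1) > 0)

    def test_qualitative_pattern_matches_the_application(self, hyp_surface):
        """Undiagnosed prevalence near 14% and total near 49% at age 60 early
        in the window; diagnosed share rises while undiagnosed falls."""
        g = hyp_surface.grid
        i0 = int(np.flatnonzero(g.t_levels == 2000.0)[0])
        i1 = int(np.flatnonzero(g.t_levels == 2010.0)[0])
        j60 = int(np.flatnonzero(g.a_levels == 60.0)[0])
        assert hyp_surface.p1[i0, j60] == pytest.approx(0.14, abs=0.03)
        assert hyp_surface.total[i0, j60] == pytest.approx(0.49, abs=0.05)
        assert hyp_surface.p1[i1, j60] < hyp_surface.p1[i0, j60]
        assert hyp_surface.p2[i1, j60] > hyp_surface.p2[i0, j60]

    def test_config_round_trip_reproduces_identical_inputs(self, hyp_scenario):
        clone = u.Scenario.from_config(hyp_scenario.to_config())
        assert np.array_equal(clone.initial.age_axis.values,
                              hyp_scenario.initial.age_axis.values)
        assert clone.rates.to_dict() == hyp_scenario.rates.to_dict()
        assert np.array_equal(clone.grid.t_levels, hyp_scenario.grid.t_levels)


def zero_rate_scenario():
    rs = u.RateSet(lambda0=u.ConstantRate(0.0), lambda1=u.ConstantRate(0.0),
                   mode=u.STATE_SPECIFIC, mu0=u.ConstantRate(0.0),
                   mu1=u.ConstantRate(0.0), mu2=u.ConstantRate(0.0))
    grid = LexisGrid.from_range(1990.0, 2000.0, 5.0, 0.0, 10.0, 5.0)
    init = InitialData(u.HALF_PLANE, BoundaryCurve.constant((0.0, 0.0)))
    return u.Scenario(rates=rs, initial=init, grid=grid, seed=0, description="zero")


class TestMicrosimulate:
    def test_zero_rates_keep_everyone_healthy(self):
        sc = zero_rate_scenario()
        res = u.microsimulate(sc, [1990.0, 1995.0], 500, 0.5, seed=4)
        cov = res.counts.covered
        assert np.any(cov)
        prev = res.prevalence()
        assert np.all(prev.p1[cov] == 0.0) and np.all(prev.p2[cov] == 0.0)
        assert np.all(res.counts.N0[cov] == 500)

    def test_cumulative_incidence_matches_binomial_closed_form(self):
        """Pure incidence at rate 0.1: p1 at age 10 is 1 - e^-1, within a
        3-standard-error Monte-Carlo band."""
        lam0, n = 0.1, 100_000
        rs = u.RateSet(lambda0=u.ConstantRate(lam0), lambda1=u.ConstantRate(0.0),
                       mode=u.STATE_SPECIFIC, mu0=u.ConstantRate(0.0),
                       mu1=u.ConstantRate(0.0), mu2=u.ConstantRate(0.0))
        grid = LexisGrid.from_range(1990.0, 2000.0, 10.0, 0.0, 10.0, 10.0)
        init = InitialData(u.HALF_PLANE, BoundaryCurve.constant((0.0, 0.0)))
        sc = u.Scenario(rs, init, grid, seed=0, description="pure-incidence")
        res = u.microsimulate(sc, [1990.0], n, 0.05, seed=5)
        p = 1.0 - np.exp(-1.0)
        j10 = 1
        p_hat = res.prevalence().p1[1, j10]
        assert abs(p_hat - p) <= 3.0 * np.sqrt(p * (1 - p) / n)

    def test_reproducible_from_seed(self):
        sc = zero_rate_scenario()
        sc = u.Scenario(u.RateSet(lambda0=u.ConstantRate(0.2),
                                  lambda1=u.ConstantRate(0.3),
                                  mode=u.STATE_SPECIFIC, mu0=u.ConstantRate(0.01),
                                  mu1=u.ConstantRate(0.011), mu2=u.ConstantRate(0.012)),
                        sc.initial, sc.grid, seed=0, description="x")
        a = u.microsimulate(sc, [1990.0, 1995.0], 2000, 0.1, seed=9)
        b = u.microsimulate(sc, [1990.0, 1995.0], 2000, 0.1, seed=9)
        c = u.microsimulate(sc, [1990.0, 1995.0], 2000, 0.1, seed=10)
        for name in ("N0", "N1", "N2"):
            assert np.array_equal(getattr(a.counts, name), getattr(b.counts, name),
                                  equal_nan=True)
        assert not a.sample.cells.equals(c.sample.cells)

    def test_survey_sample_invariants_hold(self):
        sc = zero_rate_scenario()
        res = u.microsimulate(sc, [1990.0], 100, 0.5, seed=1)
        df = res.sample.cells
        assert np.all(df["k_aware"] <= df["k_total"])
        assert np.all(df["k_total"] <= df["n"])

    def test_warns_when_dt_too_coarse(self):
        rs = u.RateSet(lambda0=u.ConstantRate(1.0), lambda1=u.ConstantRate(0.0),
                       mode=u.STATE_SPECIFIC, mu0=u.ConstantRate(0.0),
                       mu1=u.ConstantRate(0.0), mu2=u.ConstantRate(0.0))
        sc = zero_rate_scenario()
        sc = u.Scenario(rs, sc.initial, sc.grid, seed=0, description="coarse")
        with pytest.warns(RuntimeWarning, match="dt"):
            u.microsimulate(sc, [1990.0], 10, 0.5, seed=1)


class TestAddSurveyNoise:
    def make_surface(self, p1, p2):
        grid = LexisGrid.from_range(2000.0, 2001.0, 1.0, 0.0, 10.0, 5.0)
        return PrevalenceSurface(grid, np.full(grid.shape, p1), np.full(grid.shape, p2))

    def test_zero_prevalence_cells_stay_empty(self):
        sample = u.add_survey_noise(self.make_surface(0.0, 0.0), 1000,
                                    [(0.0, 10.0)], seed=3)
        assert np.all(sample.cells["k_total"] == 0)
        assert np.all(sample.cells["k_aware"] == 0)

    def test_binomial_concentration_at_large_n(self):
        n = 1_000_000
        sample = u.add_survey_noise(self.make_surface(0.1, 0.3), n,
                                    [(0.0, 10.0)], seed=3)
        k = sample.cells["k_total"].iloc[0]
        assert abs(k / n - 0.4) <= 3.0 * np.sqrt(0.4 * 0.6 / n)

    def test_round_trip_through_awareness_decomposition(self):
        n = 200_000
        sample = u.add_survey_noise(self.make_surface(0.1, 0.3), n,
                                    [(0.0, 10.0)], seed=8)
        est = sample.estimates().iloc[0]
        se = 3.0 * np.sqrt(0.4 * 0.6 / n)
        assert est["p_hat1"] == pytest.approx(0.1, abs=3 * se)
        assert est["p_hat2"] == pytest.approx(0.3, abs=3 * se)

    def test_deterministic_under_seed(self):
        s1 = u.add_survey_noise(self.make_surface(0.2, 0.2), 5000, [(0.0, 5.0)], seed=6)
        s2 = u.add_survey_noise(self.make_surface(0.2, 0.2), 5000, [(0.0, 5.0)], seed=6)
        assert s1.cells.equals(s2.cells)


def test_survey_sample_rejects_inconsistent_counts():
    df = pd.DataFrame([(2000.0, 0.0, 5.0, 100, 40, 50)],
                      columns=list(SurveySample.COLUMNS))
    with pytest.raises(ValueError, match="k_aware"):
        SurveySample(df)
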