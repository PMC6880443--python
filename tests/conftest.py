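import numpy as np
import pytest

import undiag as u
from undiag.boundaries import BoundaryCurve, CountsInitialData, InitialData


@pytest.fixture
def const_general_rates():
    """Constant rates in general-mu mode (affine-linear system)."""
    return u.RateSet(
        lambda0=u.ConstantRate(0.08),
        lambda1=u.ConstantRate(0.3),
        mode=u.GENERAL_MU,
        mu=u.ConstantRate(0.01),
        mu1=u.ConstantRate(0.011),
        mu2=u.ConstantRate(0.012),
    )


@pytest.fixture
def const_state_rates():
    """Constant rates in state-specific mode."""
    return u.RateSet(
        lambda0=u.ConstantRate(0.08),
        lambda1=u.ConstantRate(0.3),
        mode=u.STATE_SPECIFIC,
        mu0=u.ConstantRate(0.01),
        mu1=u.ConstantRate(0.011),
        mu2=u.ConstantRate(0.012),
    )


@pytest.fixture
def zero_boundary_half_plane():
    return InitialData(u.HALF_PLANE, BoundaryCurve.constant((0.0, 0.0)))


@pytest.fixture
def unit_counts_half_plane():
    return CountsInitialData(u.HALF_PLANE, BoundaryCurve.constant((1.0, 0.0, 0.0)))


def make_random_smooth_rates(rng: np.random.Generator) -> u.RateSet:
    """A randomized smooth state-specific scenario: separable rates with
    logistic age profiles, Gompertz mortality, gentle time trends."""
    def trend(lo, hi):
        return u.PiecewiseLinearFactor((1900.0, 2020.0), (1.0, rng.uniform(lo, hi)))

    return u.RateSet(
        lambda0=u.SeparableRate(
            trend(0.7, 1.3),
            u.LogisticFactor(rng.uniform(0.02, 0.08), rng.uniform(35, 55),
                             rng.uniform(8, 15), floor_at_zero=True),
        ),
        lambda1=u.SeparableRate(
            trend(0.8, 1.5),
            u.LogisticFactor(rng.uniform(0.05, 0.3), rng.uniform(25, 45),
                             rng.uniform(8, 15), floor_at_zero=True),
        ),
        mode=u.STATE_SPECIFIC,
        mu0=u.SeparableRate(
            trend(0.85, 1.0),
            u.GompertzFactor(rng.uniform(2e-5, 1e-4), rng.uniform(0.07, 0.11)),
        ),
        r1=float(rng.uniform(1.0, 1.3)),
        r2=float(rng.uniform(1.0, 1.5)),
    )


@pytest.fixture(scope="session")
def hyp_scenario():
    return u.make_hypertension_like_scenario(seed=1)


@pytest.fixture(scope="session")
def hyp_surface(hyp_scenario):
    return hyp_scenario.solve()
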