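"""Core state types and the right-hand sides of the illness-death PDE system.

The four-state model tracks a birth cohort through the states

    0: healthy  --lambda0-->  1: undiagnosed disease  --lambda1-->  2: diagnosed

with state-specific mortalities ``mu0``, ``mu1``, ``mu2``.  Writing
``N_j(t, a)`` for the number of persons in state ``j`` aged ``a`` at calendar
time ``t`` (no migration), the counts satisfy a linear transport system whose
directional derivative ``(d/dt + d/da)`` acts along Lexis life lines.  The
age-specific prevalences ``p_j = N_j / N`` of the two disease states satisfy

    (d/dt + d/da) p1 = -(lambda0 + lambda1 + mu1 - mu) p1 - lambda0 p2 + lambda0
    (d/dt + d/da) p2 = lambda1 p1 - (mu2 - mu) p2

where ``mu = mu0 p0 + mu1 p1 + mu2 p2`` is the overall mortality.  When ``mu``
is supplied from data (general-mu mode) the system is affine-linear in
``(p1, p2)``; when it is closed via the mixture identity (state-specific mode)
it is quadratic, but only through the local state, so no global iteration is
ever needed.

Note on the constant term: the ``+lambda0`` in the first equation is the
correct sign — with ``p = (0, 0)`` the right-hand side must reduce to
``(lambda0, 0)`` so that positive incidence raises the undiagnosed prevalence
from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rates import GENERAL_MU, STATE_SPECIFIC, RateSet


class ModeError(ValueError):
    """An operation was called in the wrong mortality mode."""


@dataclass(frozen=True)
class LexisPoint:
    """A point ``(t, a)`` of the Lexis plane; ``t0 = t - a`` indexes the cohort."""

    t: float
    a: float

    def __post_init__(self):
        if self.a < 0:
            raise ValueError(f"age must be >= 0, got {self.a}")

    @property
    def cohort(self) -> float:
        return self.t - self.a


@dataclass(frozen=True)
class PrevalenceState:
    """Prevalence vector ``(p1, p2)``; ``p0 = 1 - p1 - p2`` is implied."""

    p1: float
    p2: float

    def validate(self, tol: float = 0.0) -> "PrevalenceState":
        if self.p1 < -tol or self.p2 < -tol or self.p1 + self.p2 > 1.0 + tol:
            raise ValueError(
                f"prevalence state ({self.p1}, {self.p2}) outside the simplex"
            )
        return self

    @property
    def p0(self) -> float:
        return 1.0 - self.p1 - self.p2

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2], dtype=float)


def overall_mortality(rates: RateSet, point: LexisPoint, p: PrevalenceState) -> float:
    """Prevalence-weighted overall mortality ``mu0 p0 + mu1 p1 + mu2 p2``.

    Only meaningful in state-specific mode; in general-mu mode the overall
    mortality is an input, not a derived quantity, and calling this is a
    usage error.
    """
    if rates.mode != STATE_SPECIFIC:
        raise ModeError(
            "overall_mortality requires state-specific rates; in general-mu "
            "mode mu is an input"
        )
    p.validate(tol=1e-12)
    t, a = point.t, point.a
    return float(
        rates.mu0(t, a) * p.p0
        + rates.mu1_at(t, a) * p.p1
        + rates.mu2_at(t, a) * p.p2
    )


def _mu_value(t: float, a: float, p1, p2, rates: RateSet):
    """Overall mortality at ``(t, a)`` for either mode (vectorized in p)."""
    if rates.mode == GENERAL_MU:
        return rates.mu(t, a)
    mu0 = rates.mu0(t, a)
    return (
        mu0 * (1.0 - p1 - p2)
        + rates.mu1_at(t, a) * p1
        + rates.mu2_at(t, a) * p2
    )


def _b_values(t, a, p1, p2, rates: RateSet):
    """Vectorized right-hand side of the prevalence system.

    Accepts scalars or broadcastable arrays for all of ``t, a, p1, p2`` and
    returns ``(b1, b2)`` with the broadcast shape.
    """
    lam0 = rates.lambda0(t, a)
    lam1 = rates.lambda1(t, a)
    mu1 = rates.mu1_at(t, a)
    mu2 = rates.mu2_at(t, a)
    mu = _mu_value(t, a, p1, p2, rates)
    b1 = -(lam0 + lam1 + mu1 - mu) * p1 - lam0 * p2 + lam0
    b2 = lam1 * p1 - (mu2 - mu) * p2
    return b1, b2


def rhs_b(point: LexisPoint, p: PrevalenceState, rates: RateSet) -> np.ndarray:
    """Right-hand side ``b = (b1, b2)`` of the prevalence transport system.

    In general-mu mode ``mu`` is read from the supplied surface; in
    state-specific mode it is closed locally via the mixture identity.
    """
    b1, b2 = _b_values(point.t, point.a, p.p1, p.p2, rates)
    return np.array([float(b1), float(b2)])


def counts_rhs(point: LexisPoint, N, rates: RateSet) -> np.ndarray:
    """Right-hand side of the counts system along a life line.

    ``dN0 = -(mu0 + lambda0) N0``;
    ``dN1 = -(mu1 + lambda1) N1 + lambda0 N0``;
    ``dN2 = -mu2 N2 + lambda1 N1``.
    The components sum to ``-(mu0 N0 + mu1 N1 + mu2 N2)``: with no migration,
    only deaths change the cohort total.
    """
    if rates.mode != STATE_SPECIFIC:
        raise ModeError("counts_rhs requires state-specific rates (mu0 is needed)")
    N = np.asarray(N, dtype=float)
    if N.shape != (3,):
        raise ValueError(f"N must be a 3-vector, got shape {N.shape}")
    if np.any(N < 0):
        raise ValueError(f"counts must be >= 0, got {N}")
    t, a = point.t, point.a
    lam0 = float(rates.lambda0(t, a))
    lam1 = float(rates.lambda1(t, a))
    mu0 = float(rates.mu0(t, a))
    mu1 = float(rates.mu1_at(t, a))
    mu2 = float(rates.mu2_at(t, a))
    return np.array([
        -(mu0 + lam0) * N[0],
        -(mu1 + lam1) * N[1] + lam0 * N[0],
        -mu2 * N[2] + lam1 * N[1],
    ])
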