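"""Method-of-characteristics solver for the prevalence and counts systems.

The transport operator ``(d/dt + d/da)`` is a total derivative along the
slope-1 life lines of the Lexis diagram, so the PDE systems reduce to ODE
initial-value problems along each line: starting from the boundary point
where a life line enters the solution domain, the prevalence vector evolves
as ``dp/ds = b(t0 + s, a0 + s, p)``.  Each grid node is solved independently
by classical fourth-order Runge–Kutta from the foot of its characteristic;
the final partial step is shortened to land exactly on the node, and no
interpolation of the solution itself is ever performed.

For smooth (continuously differentiable) rates the global error is
``O(step^4)``; piecewise-bilinear gridded rates are accepted, with the caveat
that the formal order degrades at grid creases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .boundaries import (FIRST_QUADRANT, HALF_PLANE, BoundaryCurve,
                         CountsInitialData, InitialData)
from .model import LexisPoint, PrevalenceState, _b_values
from .rates import STATE_SPECIFIC, RateSet
from .surfaces import CountsSurface, LexisGrid, PrevalenceSurface

logger = logging.getLogger(__name__)

DEFAULT_STEP_CAP = 0.25  # years; default RK4 step is min(dt, da, this)
SIMPLEX_EPS = 1e-8


class DomainError(ValueError):
    """A point lies outside the solution domain of the chosen geometry."""


class CompatibilityError(ValueError):
    """First-quadrant corner data fail the compatibility conditions."""


class SimplexError(RuntimeError):
    """A solved node left the prevalence simplex beyond tolerance."""


# ---------------------------------------------------------------------------
# life-line geometry
# ---------------------------------------------------------------------------

def characteristic_foot(point: LexisPoint, initial: InitialData | CountsInitialData):
    """Trace a Lexis point back along its life line to the domain boundary.

    Returns ``(start, boundary_value, arc)``: the entry point of the life
    line, the boundary datum there, and the arc length (in years) from entry
    to ``point``.  On the half-plane every life line enters through the
    age-0 axis at ``(t - a, 0)``; on the first quadrant, cohorts born before
    ``t_min`` enter through the left edge ``(t_min, a - (t - t_min))``.
    """
    t, a = point.t, point.a
    if initial.geometry == HALF_PLANE:
        start = LexisPoint(t - a, 0.0)
        value = initial.abscissa(start.t)
        return start, value, a
    if t < initial.t_min - 1e-12:
        raise DomainError(
            f"point (t={t}, a={a}) lies left of the first-quadrant edge "
            f"t_min={initial.t_min}"
        )
    if t - a >= initial.t_min - 1e-12:
        start = LexisPoint(t - a, 0.0)
        return start, initial.abscissa(start.t), a
    arc = t - initial.t_min
    start = LexisPoint(initial.t_min, a - arc)
    return start, initial.age_axis(start.a), arc


def prevalence_foot(point: LexisPoint, initial: InitialData):
    """Like :func:`characteristic_foot` but wraps the value as a state."""
    start, value, arc = characteristic_foot(point, initial)
    return start, PrevalenceState(float(value[0]), float(value[1])), arc


# ---------------------------------------------------------------------------
# ODE integration along one life line
# ---------------------------------------------------------------------------

@dataclass
class CharacteristicSolution:
    """Trajectory along one life line: states sampled at arc lengths ``s``."""

    start: LexisPoint
    s: np.ndarray           # arc lengths, s[0] = 0, s[-1] = arc
    states: np.ndarray      # shape (len(s), k)

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def _arc_samples(arc: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if arc < 0:
        raise ValueError(f"arc must be >= 0, got {arc}")
    if arc == 0:
        return np.array([0.0])
    n_full = int(np.floor(arc / step + 1e-9))
    s = step * np.arange(n_full + 1)
    if arc - s[-1] > 1e-9 * max(step, 1.0):
        s = np.append(s, arc)
    else:
        s[-1] = arc  # land exactly on the target
    return s


def _integrate(f, y0: np.ndarray, arc: float, step: float,
               method: str = "rk4") -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step explicit integration of ``dy/ds = f(s, y)`` on ``[0, arc]``."""
    s = _arc_samples(arc, step)
    out = np.empty((s.size, y0.size))
    out[0] = y0
    y = np.array(y0, dtype=float)
    for k in range(1, s.size):
        h = s[k] - s[k - 1]
        s0 = s[k - 1]
        if method == "rk4":
            k1 = f(s0, y)
            k2 = f(s0 + 0.5 * h, y + 0.5 * h * k1)
            k3 = f(s0 + 0.5 * h, y + 0.5 * h * k2)
            k4 = f(s0 + h, y + h * k3)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        elif method == "euler":
            y = y + h * f(s0, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        out[k] = y
    return s, out


def solve_along_characteristic(start: LexisPoint, p_start: PrevalenceState,
                               rates: RateSet, arc: float, step: float,
                               method: str = "rk4") -> CharacteristicSolution:
    """Integrate the prevalence system along one life line.

    The life line runs from ``(start.t, start.a)`` to
    ``(start.t + arc, start.a + arc)``; the trajectory is sampled at every
    internal step and at ``s = arc`` exactly.
    """
    t0, a0 = start.t, start.a

    def f(s, y):
        b1, b2 = _b_values(t0 + s, a0 + s, y[0], y[1], rates)
        return np.array([float(b1), float(b2)])

    s, states = _integrate(f, p_start.as_array(), arc, step, method)
    return CharacteristicSolution(start, s, states)


def solve_counts_along_characteristic(start: LexisPoint, N_start, rates: RateSet,
                                      arc: float, step: float,
                                      method: str = "rk4") -> CharacteristicSolution:
    """Integrate the counts system along one life line (state-specific mode)."""
    if rates.mode != STATE_SPECIFIC:
        raise ValueError("counts integration requires state-specific rates")
    N_start = np.asarray(N_start, dtype=float)
    if np.any(N_start < 0):
        raise ValueError("boundary counts must be >= 0")
    t0, a0 = start.t, start.a

    def f(s, y):
        t, a = t0 + s, a0 + s
        lam0 = float(rates.lambda0(t, a))
        lam1 = float(rates.lambda1(t, a))
        mu0 = float(rates.mu0(t, a))
        mu1 = float(rates.mu1_at(t, a))
        mu2 = float(rates.mu2_at(t, a))
        return np.array([
            -(mu0 + lam0) * y[0],
            -(mu1 + lam1) * y[1] + lam0 * y[0],
            -mu2 * y[2] + lam1 * y[1],
        ])

    s, states = _integrate(f, N_start, arc, step, method)
    return CharacteristicSolution(start, s, states)


# ---------------------------------------------------------------------------
# compatibility at the first-quadrant corner
# ---------------------------------------------------------------------------

@dataclass
class CompatibilityReport:
    """Corner gaps between the two boundary data curves of the quadrant."""

    value_gap: float
    slope_gap: float | None
    tol_value: float
    tol_slope: float
    corner: tuple

    @property
    def value_ok(self) -> bool:
        return self.value_gap <= self.tol_value

    @property
    def slope_ok(self) -> bool:
        return self.slope_gap is None or self.slope_gap <= self.tol_slope

    @property
    def passed(self) -> bool:
        return self.value_ok and self.slope_ok

    def __str__(self):
        slope = "n/a" if self.slope_gap is None else f"{self.slope_gap:.3e}"
        return (
            f"compatibility at corner {self.corner}: value gap "
            f"{self.value_gap:.3e} (tol {self.tol_value:.1e}), slope gap "
            f"{slope} (tol {self.tol_slope:.1e}) -> "
            f"{'pass' if self.passed else 'FAIL'}"
        )


def _one_sided_slope(curve: BoundaryCurve, x0: float, analytic, h: float):
    if analytic is not None:
        return np.asarray(analytic, dtype=float)
    if curve.x is not None:
        # gridded data: difference quotient over the first table interval
        return (curve.values[1] - curve.values[0]) / (curve.x[1] - curve.x[0])
    return (np.asarray(curve(x0 + h)) - np.asarray(curve(x0))) / h


def check_compatibility(initial: InitialData, tol_value: float = 1e-8,
                        tol_slope: float = 1e-6, fd_h: float = 1e-5) -> CompatibilityReport:
    """Check the corner conditions of the first-quadrant geometry.

    A continuously differentiable solution requires the age-0 data and the
    left-edge age profile to agree at the corner ``(t_min, 0)`` in value and
    in first (one-sided) derivative.  Analytic corner slopes attached to the
    :class:`~undiag.boundaries.InitialData` are used when present; otherwise
    slopes are estimated by one-sided finite differences (the first table
    interval for gridded data, step ``fd_h`` for callables).
    """
    if initial.geometry != FIRST_QUADRANT:
        raise ValueError("compatibility conditions only exist for the first quadrant")
    corner = (initial.t_min, 0.0)
    v_abs = np.asarray(initial.abscissa(initial.t_min), dtype=float)
    v_age = np.asarray(initial.age_axis(0.0), dtype=float)
    value_gap = float(np.max(np.abs(v_abs - v_age)))
    s_abs = _one_sided_slope(initial.abscissa, initial.t_min,
                             initial.abscissa_corner_slope, fd_h)
    s_age = _one_sided_slope(initial.age_axis, 0.0,
                             initial.age_axis_corner_slope, fd_h)
    slope_gap = float(np.max(np.abs(s_abs - s_age)))
    return CompatibilityReport(value_gap, slope_gap, tol_value, tol_slope, corner)


# ---------------------------------------------------------------------------
# surface solvers
# ---------------------------------------------------------------------------

def default_step(grid: LexisGrid) -> float:
    return min(grid.dt, grid.da, DEFAULT_STEP_CAP)


def _check_grid_in_domain(grid: LexisGrid, initial) -> None:
    if initial.geometry == FIRST_QUADRANT and grid.t_levels[0] < initial.t_min - 1e-12:
        raise DomainError(
            f"grid starts at t={grid.t_levels[0]} but the first-quadrant "
            f"domain begins at t_min={initial.t_min}"
        )


def _handle_simplex(surface: PrevalenceSurface, policy: str, eps: float) -> None:
    viol, node = surface.simplex_violation()
    if viol <= eps:
        return
    msg = (
        f"solved prevalence leaves the simplex by {viol:.3e} at node "
        f"(t={node[0]}, a={node[1]}) (tolerance {eps:.1e}); with general-mu "
        "rates this indicates mu inconsistent with mu1/mu2"
    )
    if policy == "raise":
        raise SimplexError(msg)
    if policy == "warn":
        warnings.warn(msg, RuntimeWarning, stacklevel=3)
    elif policy != "ignore":
        raise ValueError(f"unknown simplex policy {policy!r}")


def _solve_by_life_line(grid: LexisGrid, initial, out: np.ndarray,
                        integrate, step: float) -> None:
    """Fill ``out[i, j]`` with the characteristic solution at every node.

    Nodes sharing a life line are integrated sequentially along it whenever
    their arcs are whole multiples of ``step`` — the step sequence is then
    identical to integrating each node independently from its foot — and
    node by node otherwise.
    """
    groups: dict = {}
    for i, t in enumerate(grid.t_levels):
        for j, a in enumerate(grid.a_levels):
            start, value, arc = characteristic_foot(LexisPoint(float(t), float(a)),
                                                    initial)
            value = np.asarray(value, dtype=float)
            if arc == 0:
                out[i, j] = value
                continue
            key = (round(start.t, 9), round(start.a, 9))
            groups.setdefault(key, (start, value, []))[2].append((float(arc), i, j))
    for start, value, nodes in groups.values():
        nodes.sort()
        aligned = all(
            abs(arc / step - round(arc / step)) < 1e-9 for arc, _, _ in nodes
        )
        if aligned:
            y = value
            s_prev = 0.0
            for arc, i, j in nodes:
                gap = arc - s_prev
                if gap > 1e-12:
                    here = LexisPoint(start.t + s_prev, start.a + s_prev)
                    y = np.asarray(integrate(here, y, gap), dtype=float)
                    s_prev = arc
                out[i, j] = y
        else:
            for arc, i, j in nodes:
                out[i, j] = integrate(start, value, arc)


def solve_surface(rates: RateSet, initial: InitialData, grid: LexisGrid,
                  step: float | None = None, method: str = "rk4",
                  compat: str = "raise", compat_tol_value: float = 1e-6,
                  compat_tol_slope: float = 1e-3,
                  simplex: str = "raise", simplex_eps: float = SIMPLEX_EPS
                  ) -> PrevalenceSurface:
    """Solve the prevalence system on a Lexis grid.

    Every node value is the RK4 characteristic solution integrated from the
    node's boundary foot; the result is deterministic given its inputs.  For
    the first-quadrant geometry the corner compatibility conditions are
    checked before any integration (``compat``: ``"raise"``, ``"warn"`` or
    ``"skip"``), and solved states are verified to stay within the prevalence
    simplex up to ``simplex_eps`` (``simplex``: ``"raise"``, ``"warn"`` or
    ``"ignore"``).
    """
    if step is None:
        step = default_step(grid)
    _check_grid_in_domain(grid, initial)
    if initial.geometry == FIRST_QUADRANT and compat != "skip":
        report = check_compatibility(initial, compat_tol_value, compat_tol_slope)
        if not report.passed:
            if compat == "raise":
                raise CompatibilityError(str(report))
            warnings.warn(str(report), RuntimeWarning, stacklevel=2)
    values = np.empty(grid.shape + (2,))

    def integrate(start, y0, arc):
        return solve_along_characteristic(
            start, PrevalenceState(float(y0[0]), float(y0[1])),
            rates, arc, step, method).final

    _solve_by_life_line(grid, initial, values, integrate, step)
    surface = PrevalenceSurface(grid, values[:, :, 0], values[:, :, 1])
    _handle_simplex(surface, simplex, simplex_eps)
    return surface


def solve_counts(rates: RateSet, initial_counts: CountsInitialData,
                 grid: LexisGrid, step: float | None = None,
                 method: str = "rk4") -> CountsSurface:
    """Solve the counts system on a Lexis grid (state-specific mode).

    Along each life line the cohort total ``N0 + N1 + N2`` can only decrease
    (deaths are the only exits under the no-migration assumption).
    """
    if step is None:
        step = default_step(grid)
    _check_grid_in_domain(grid, initial_counts)
    N = np.empty(grid.shape + (3,))

    def integrate(start, y0, arc):
        return solve_counts_along_characteristic(start, y0, rates, arc,
                                                 step, method).final

    _solve_by_life_line(grid, initial_counts, N, integrate, step)
    return CountsSurface(grid, N[:, :, 0], N[:, :, 1], N[:, :, 2])


# ---------------------------------------------------------------------------
# empirical order of accuracy
# ---------------------------------------------------------------------------

@dataclass
class OrderEstimate:
    """Empirical convergence order from a step-halving experiment."""

    order: float
    steps: np.ndarray
    errors: np.ndarray

    @property
    def defined(self) -> bool:
        return np.isfinite(self.order)


def convergence_order(rates: RateSet, start: LexisPoint, p_start: PrevalenceState,
                      arc: float, steps, reference=None,
                      method: str = "rk4") -> OrderEstimate:
    """Estimate the integrator's order on one characteristic.

    Runs the integrator at each step size, measures the max-abs error of the
    final state against ``reference`` (a known closed-form state, or computed
    at ``min(steps)/16`` when omitted), and fits the log–log slope of error
    versus step.  When all errors vanish (e.g. zero rates) the order is
    undefined and reported as NaN.
    """
    steps = np.asarray(sorted(steps, reverse=True), dtype=float)
    if steps.size < 3:
        raise ValueError("need at least three step sizes")
    if reference is None:
        reference = solve_along_characteristic(
            start, p_start, rates, arc, float(steps.min()) / 16.0, method="rk4"
        ).final
    reference = np.asarray(reference, dtype=float)
    errors = np.array([
        np.max(np.abs(
            solve_along_characteristic(start, p_start, rates, arc,
                                       float(h), method).final - reference
        ))
        for h in steps
    ])
    if np.max(errors) < 1e-13:
        logger.info("convergence_order: errors all ~0; order undefined")
        return OrderEstimate(float("nan"), steps, errors)
    slope = np.polyfit(np.log(steps), np.log(np.maximum(errors, 1e-300)), 1)[0]
    return OrderEstimate(float(slope), steps, errors)
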