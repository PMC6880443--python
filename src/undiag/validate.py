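"""Independent reference solutions used to validate the characteristics solver.

Two cross-checks with entirely different numerics live here:

* :func:`constant_rate_closed_form` — for constant rates the prevalence ODE
  along a life line is affine-linear with constant coefficients; its exact
  solution is obtained from a single matrix exponential of the augmented
  system, with no time stepping at all.
* :func:`upwind_solve` — a first-order explicit upwind finite-difference
  discretization of the prevalence transport system on the Lexis plane,
  marching forward in calendar time with a backward difference in age.  It
  never looks at characteristics; as its mesh is refined it must converge
  (first order) to the method-of-characteristics solution.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .boundaries import FIRST_QUADRANT, InitialData
from .model import _b_values
from .rates import GENERAL_MU, RateSet
from .surfaces import LexisGrid, PrevalenceSurface


def constant_rate_closed_form(lam0: float, lam1: float, mu: float, mu1: float,
                              mu2: float, p_start, s) -> np.ndarray:
    """Exact prevalence after arc ``s`` for constant rates (general-mu form).

    The system ``dp/ds = A p + c`` with

        A = [[-(lam0 + lam1 + mu1 - mu), -lam0], [lam1, -(mu2 - mu)]],
        c = (lam0, 0)

    is solved exactly via the matrix exponential of the augmented matrix
    ``[[A, c], [0, 0]]`` acting on ``(p1, p2, 1)``; this avoids any special
    casing when ``A`` is singular.
    """
    A = np.array([
        [-(lam0 + lam1 + mu1 - mu), -lam0],
        [lam1, -(mu2 - mu)],
    ])
    c = np.array([lam0, 0.0])
    M = np.zeros((3, 3))
    M[:2, :2] = A
    M[:2, 2] = c
    y0 = np.array([p_start[0], p_start[1], 1.0])
    return (expm(M * float(s)) @ y0)[:2]


def upwind_solve(rates: RateSet, initial: InitialData, grid: LexisGrid,
                 h_a: float, cfl: float = 0.5) -> PrevalenceSurface:
    """First-order upwind finite-difference solve, sampled on ``grid``.

    Marches ``p`` forward in calendar time with time step ``cfl * h_a`` on an
    age mesh of spacing ``h_a`` covering ``[0, a_max]``; the age-0 row is
    imposed from the abscissa boundary and the ``t = t_min`` column from the
    age-axis profile.  ``grid`` nodes must fall on the fine mesh (its age
    levels multiples of ``h_a``, its time levels reachable in whole time
    steps), so the comparison against the characteristics solution needs no
    interpolation.

    Requires the first-quadrant geometry and general-mu rates (the scheme is
    vectorized over the age axis through the affine right-hand side; the
    state-specific closure would work identically but is not needed by the
    validation suite).
    """
    if initial.geometry != FIRST_QUADRANT:
        raise ValueError("upwind_solve requires first-quadrant initial data")
    if rates.mode != GENERAL_MU:
        raise ValueError("upwind_solve is implemented for general-mu rates")
    if not (0 < cfl <= 1):
        raise ValueError("need 0 < cfl <= 1 for stability")
    t_min = float(initial.t_min)
    if abs(grid.t_levels[0] - t_min) > 1e-12:
        raise ValueError("grid must start at t_min")
    a_max = float(grid.a_levels[-1])
    n_a = int(round(a_max / h_a))
    if abs(n_a * h_a - a_max) > 1e-9:
        raise ValueError("a_max must be a multiple of h_a")
    a_fine = h_a * np.arange(n_a + 1)
    for a in grid.a_levels:
        if abs(round(a / h_a) * h_a - a) > 1e-9:
            raise ValueError(f"grid age {a} does not fall on the fine mesh")
    dt = cfl * h_a
    nu = dt / h_a

    # fine state: shape (n_a + 1, 2), initialized from the left-edge profile
    p = np.asarray(initial.age_axis(a_fine), dtype=float).copy()
    p[0] = np.asarray(initial.abscissa(t_min), dtype=float)

    a_idx = np.array([int(round(a / h_a)) for a in grid.a_levels])
    out = np.empty((grid.t_levels.size, grid.a_levels.size, 2))
    next_out = 0
    if abs(grid.t_levels[0] - t_min) <= 1e-9:
        out[0] = p[a_idx]
        next_out = 1

    t = t_min
    t_end = float(grid.t_levels[-1])
    n_steps = int(round((t_end - t_min) / dt))
    if abs(t_min + n_steps * dt - t_end) > 1e-9:
        raise ValueError("grid time span must be a whole number of time steps")
    for k in range(1, n_steps + 1):
        b1, b2 = _b_values(t, a_fine[1:], p[1:, 0], p[1:, 1], rates)
        p_new = np.empty_like(p)
        p_new[1:, 0] = p[1:, 0] - nu * (p[1:, 0] - p[:-1, 0]) + dt * b1
        p_new[1:, 1] = p[1:, 1] - nu * (p[1:, 1] - p[:-1, 1]) + dt * b2
        t = t_min + k * dt
        p_new[0] = np.asarray(initial.abscissa(t), dtype=float)
        p = p_new
        while next_out < grid.t_levels.size and abs(t - grid.t_levels[next_out]) <= 1e-9:
            out[next_out] = p[a_idx]
            next_out += 1
    if next_out != grid.t_levels.size:
        raise RuntimeError("internal error: not all grid time levels were hit")
    return PrevalenceSurface(grid, out[:, :, 0], out[:, :, 1])
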