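"""Boundary data for the two initial-condition geometries.

The prevalence system is solved either on the upper half-plane (boundary data
``p(t, 0)`` on the age-0 axis for all calendar times) or on a shifted first
quadrant ``[t_min, inf) x [0, inf)`` (boundary data on the age-0 axis for
``t >= t_min`` plus an age profile ``p(t_min, a)`` on the left edge).  For a
continuously differentiable solution on the quadrant the two data curves must
agree at the corner ``(t_min, 0)`` in value and first derivative — the
compatibility conditions checked by :func:`undiag.solver.check_compatibility`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

HALF_PLANE = "half-plane"
FIRST_QUADRANT = "first-quadrant"


class BoundaryDomainError(ValueError):
    """Boundary data evaluated outside its tabulated range."""


class BoundaryCurve:
    """A vector-valued curve ``x -> R^k`` given as a callable or a table.

    Tabulated curves are interpolated linearly between nodes; evaluation
    beyond the table is an error (no extrapolation of boundary data).
    """

    def __init__(self, fn: Callable | None = None,
                 x: Sequence[float] | None = None,
                 values: np.ndarray | None = None,
                 ncomp: int = 2, name: str = "boundary"):
        self.ncomp = ncomp
        self.name = name
        if fn is not None:
            if x is not None or values is not None:
                raise ValueError("give either a callable or a table, not both")
            self._fn = fn
            self.x = None
            self.values = None
        else:
            x = np.asarray(x, dtype=float)
            values = np.asarray(values, dtype=float)
            if x.ndim != 1 or values.shape != (x.size, ncomp):
                raise ValueError(
                    f"table must have shape (n,) and (n, {ncomp}); got "
                    f"{x.shape} and {values.shape}"
                )
            if np.any(np.diff(x) <= 0):
                raise ValueError("table abscissae must be strictly increasing")
            self._fn = None
            self.x = x
            self.values = values

    @classmethod
    def constant(cls, value: Sequence[float], name: str = "boundary") -> "BoundaryCurve":
        value = np.asarray(value, dtype=float)
        return cls(fn=lambda x, v=value: np.broadcast_to(
            v, np.shape(np.asarray(x)) + v.shape).copy(),
            ncomp=value.size, name=name)

    def __call__(self, x):
        scalar = np.isscalar(x) or np.ndim(x) == 0
        xs = np.atleast_1d(np.asarray(x, dtype=float))
        if self._fn is not None:
            out = np.asarray(self._fn(xs), dtype=float)
            out = out.reshape(xs.shape + (self.ncomp,))
        else:
            lo, hi = self.x[0], self.x[-1]
            if np.any(xs < lo - 1e-9) or np.any(xs > hi + 1e-9):
                raise BoundaryDomainError(
                    f"boundary {self.name!r} evaluated outside its table "
                    f"range [{lo}, {hi}]"
                )
            xs_c = np.clip(xs, lo, hi)
            out = np.stack(
                [np.interp(xs_c, self.x, self.values[:, j]) for j in range(self.ncomp)],
                axis=-1,
            )
        return out[0] if scalar else out


@dataclass
class InitialData:
    """Boundary prevalence for one of the two solution geometries.

    Parameters
    ----------
    geometry
        ``"half-plane"`` or ``"first-quadrant"``.
    abscissa
        ``t -> (p1, p2)`` on the age-0 axis.
    age_axis, t_min
        First-quadrant only: ``a -> (p1, p2)`` on the left edge ``t = t_min``.
    abscissa_corner_slope, age_axis_corner_slope
        Optional analytic one-sided derivatives of the two data curves at the
        corner, used by the compatibility check when available (generators
        that construct compatible data can supply them exactly).
    """

    geometry: str
    abscissa: BoundaryCurve
    age_axis: BoundaryCurve | None = None
    t_min: float | None = None
    abscissa_corner_slope: tuple | None = None
    age_axis_corner_slope: tuple | None = None

    def __post_init__(self):
        if self.geometry not in (HALF_PLANE, FIRST_QUADRANT):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == FIRST_QUADRANT:
            if self.age_axis is None or self.t_min is None:
                raise ValueError(
                    "first-quadrant geometry needs age_axis data and t_min"
                )
        else:
            if self.age_axis is not None or self.t_min is not None:
                raise ValueError(
                    "half-plane geometry takes no age_axis data or t_min"
                )


@dataclass
class CountsInitialData:
    """Boundary counts ``(N0, N1, N2)``; same geometries as :class:`InitialData`."""

    geometry: str
    abscissa: BoundaryCurve
    age_axis: BoundaryCurve | None = None
    t_min: float | None = None

    def __post_init__(self):
        if self.geometry not in (HALF_PLANE, FIRST_QUADRANT):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == FIRST_QUADRANT and (self.age_axis is None or self.t_min is None):
            raise ValueError("first-quadrant geometry needs age_axis data and t_min")
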