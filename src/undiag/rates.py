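"""Hazard-rate surfaces over the Lexis plane.

Every transition intensity of the four-state illness-death model (incidence
``lambda0``, detection ``lambda1``, state-specific mortalities ``mu0``,
``mu1``, ``mu2``, and the overall mortality ``mu``) is a nonnegative function
of calendar time ``t`` and age ``a``, both measured in years; rates are per
person-year.  This module provides the small parametric family used for
serializable scenario configurations, bilinear interpolation of gridded rate
tables, and the :class:`RateSet` bundle that fixes which mortality inputs are
available.

Two mortality modes exist:

``general-mu``
    The overall population mortality ``mu(t, a)`` is supplied (e.g. from a
    life table) and the hypertension-state mortalities are resolved either as
    explicit surfaces or through proportional ratios ``mu_j = R_j * mu``.
    The prevalence system is then affine-linear in the prevalence vector.

``state-specific``
    The mortalities ``mu0``, ``mu1``, ``mu2`` of the healthy, undiagnosed and
    diagnosed states are supplied directly; the overall mortality is the
    prevalence-weighted mixture ``mu = mu0*p0 + mu1*p1 + mu2*p2`` and the
    prevalence system acquires a mild (local) nonlinearity.  When ratio
    shortcuts ``R_j`` are used in this mode they are applied to ``mu0``, the
    only prevalence-independent baseline available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import math

import numpy as np
from scipy.interpolate import RegularGridInterpolator


class RateDomainError(ValueError):
    """A rate surface was evaluated outside its declared domain."""


class RateSetError(ValueError):
    """The combination of supplied mortality inputs is inconsistent."""


def _as_float_array(x):
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# one-dimensional factors (the serializable parametric family)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantFactor:
    """Constant factor ``f(x) = value``."""

    value: float

    def __post_init__(self):
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"constant factor must be finite and >= 0, got {self.value}")

    def __call__(self, x):
        if np.ndim(x) == 0:
            return self.value
        x = _as_float_array(x)
        return np.full_like(x, self.value)

    def to_dict(self):
        return {"kind": "constant", "value": self.value}


@dataclass(frozen=True)
class GompertzFactor:
    """Exponential-in-age factor ``f(a) = coef * exp(slope * a)``.

    The canonical adult-mortality shape; ``coef`` is the rate at age 0 and
    ``slope`` the log-linear increase per year of age.
    """

    coef: float
    slope: float

    def __post_init__(self):
        if self.coef < 0:
            raise ValueError("Gompertz coef must be >= 0")

    def __call__(self, x):
        if np.ndim(x) == 0:
            return self.coef * math.exp(self.slope * float(x))
        return self.coef * np.exp(self.slope * _as_float_array(x))

    def to_dict(self):
        return {"kind": "gompertz", "coef": self.coef, "slope": self.slope}


@dataclass(frozen=True)
class LogisticFactor:
    """Logistic-in-age factor rising to ``plateau`` around ``midpoint``.

    ``f(a) = plateau * sigma((a - midpoint)/width)``, optionally shifted so
    that ``f(0) = 0`` exactly (``floor_at_zero``), which keeps the factor
    smooth and nonnegative while making rates vanish at birth — convenient for
    boundary compatibility at the Lexis-domain corner.
    """

    plateau: float
    midpoint: float
    width: float
    floor_at_zero: bool = False

    def __post_init__(self):
        if self.plateau < 0 or self.width <= 0:
            raise ValueError("logistic factor needs plateau >= 0 and width > 0")

    def _sigma(self, x):
        return 1.0 / (1.0 + np.exp(-x))

    def __call__(self, x):
        if np.ndim(x) == 0:
            out = self.plateau / (1.0 + math.exp(-(float(x) - self.midpoint) / self.width))
            if self.floor_at_zero:
                out -= self.plateau / (1.0 + math.exp(self.midpoint / self.width))
                out = max(out, 0.0)
            return out
        x = _as_float_array(x)
        out = self.plateau * self._sigma((x - self.midpoint) / self.width)
        if self.floor_at_zero:
            out = out - self.plateau * self._sigma(-self.midpoint / self.width)
            out = np.maximum(out, 0.0)  # guards rounding for x slightly < 0
        return out

    def to_dict(self):
        return {
            "kind": "logistic",
            "plateau": self.plateau,
            "midpoint": self.midpoint,
            "width": self.width,
            "floor_at_zero": self.floor_at_zero,
        }


@dataclass(frozen=True)
class PiecewiseLinearFactor:
    """Piecewise-linear-in-time factor through the given knots.

    Evaluation outside ``[knots_x[0], knots_x[-1]]`` is an error: silent
    extrapolation of secular trends hides data problems.
    """

    knots_x: tuple
    knots_y: tuple

    def __post_init__(self):
        xs = np.asarray(self.knots_x, dtype=float)
        ys = np.asarray(self.knots_y, dtype=float)
        if xs.ndim != 1 or xs.size < 2 or xs.size != ys.size:
            raise ValueError("need >= 2 knots with matching x and y lengths")
        if np.any(np.diff(xs) <= 0):
            raise ValueError("knot x-values must be strictly increasing")
        if np.any(ys < 0):
            raise ValueError("knot values must be >= 0")
        object.__setattr__(self, "knots_x", tuple(float(v) for v in xs))
        object.__setattr__(self, "knots_y", tuple(float(v) for v in ys))

    def __call__(self, x):
        lo, hi = self.knots_x[0], self.knots_x[-1]
        if np.ndim(x) == 0:
            xf = float(x)
            if xf < lo - 1e-12 or xf > hi + 1e-12:
                raise RateDomainError(
                    f"piecewise-linear factor evaluated outside [{lo}, {hi}]"
                )
            return float(np.interp(xf, self.knots_x, self.knots_y))
        x = _as_float_array(x)
        if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
            raise RateDomainError(
                f"piecewise-linear factor evaluated outside [{lo}, {hi}]"
            )
        return np.interp(x, self.knots_x, self.knots_y)

    def to_dict(self):
        return {
            "kind": "piecewise-linear",
            "knots_x": list(self.knots_x),
            "knots_y": list(self.knots_y),
        }


_FACTOR_KINDS = {
    "constant": ConstantFactor,
    "gompertz": GompertzFactor,
    "logistic": LogisticFactor,
    "piecewise-linear": PiecewiseLinearFactor,
}


def factor_from_dict(spec: dict):
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind not in _FACTOR_KINDS:
        raise ValueError(f"unknown factor kind {kind!r}; choose from {sorted(_FACTOR_KINDS)}")
    return _FACTOR_KINDS[kind](**spec)


# ---------------------------------------------------------------------------
# rate surfaces
# ---------------------------------------------------------------------------

class RateSurface:
    """A nonnegative hazard evaluated at Lexis coordinates ``(t, a)``.

    Subclasses implement ``__call__(t, a)`` (vectorized, returning an array
    broadcast over the inputs) and ``to_dict``.
    """

    kind: str = "abstract"

    def __call__(self, t, a):  # pragma: no cover - interface
        raise NotImplementedError

    def to_dict(self) -> dict:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class ConstantRate(RateSurface):
    value: float
    kind = "constant"

    def __post_init__(self):
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"rate must be finite and >= 0, got {self.value}")

    def __call__(self, t, a):
        if np.ndim(t) == 0 and np.ndim(a) == 0:
            return self.value
        t, a = np.broadcast_arrays(_as_float_array(t), _as_float_array(a))
        return np.full_like(t, self.value)

    def to_dict(self):
        return {"kind": "constant", "value": self.value}


@dataclass(frozen=True)
class SeparableRate(RateSurface):
    """Rate of the form ``lambda(t, a) = time_factor(t) * age_factor(a)``."""

    time_factor: object
    age_factor: object
    kind = "separable"

    def __call__(self, t, a):
        if np.ndim(t) == 0 and np.ndim(a) == 0:
            return self.time_factor(t) * self.age_factor(a)
        t, a = np.broadcast_arrays(_as_float_array(t), _as_float_array(a))
        return self.time_factor(t) * self.age_factor(a)

    def to_dict(self):
        return {
            "kind": "separable",
            "time": self.time_factor.to_dict(),
            "age": self.age_factor.to_dict(),
        }


class GriddedRate(RateSurface):
    """Bilinear interpolation of a rate table on a regular ``(t, a)`` grid.

    Node values are reproduced exactly; evaluation outside the rectangle
    ``[t[0], t[-1]] x [a[0], a[-1]]`` raises :class:`RateDomainError` naming
    the surface and the offending point (constant extrapolation is forbidden).
    """

    kind = "gridded"

    def __init__(self, t_levels: Sequence[float], a_levels: Sequence[float],
                 values: np.ndarray, name: str = "rate"):
        t_levels = _as_float_array(t_levels)
        a_levels = _as_float_array(a_levels)
        values = _as_float_array(values)
        if np.any(np.diff(t_levels) <= 0) or np.any(np.diff(a_levels) <= 0):
            raise ValueError("grid levels must be strictly increasing")
        if values.shape != (t_levels.size, a_levels.size):
            raise ValueError(
                f"values shape {values.shape} does not match grid "
                f"({t_levels.size}, {a_levels.size})"
            )
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValueError("rate table values must be finite and >= 0")
        self.t_levels = t_levels
        self.a_levels = a_levels
        self.values = values
        self.name = name
        self._interp = RegularGridInterpolator(
            (t_levels, a_levels), values, method="linear", bounds_error=True
        )

    @property
    def domain(self):
        return (
            (self.t_levels[0], self.t_levels[-1]),
            (self.a_levels[0], self.a_levels[-1]),
        )

    def __call__(self, t, a):
        t, a = np.broadcast_arrays(_as_float_array(t), _as_float_array(a))
        pts = np.stack([t.ravel(), a.ravel()], axis=-1)
        try:
            out = self._interp(pts)
        except ValueError as exc:
            (tlo, thi), (alo, ahi) = self.domain
            bad_t = (pts[:, 0] < tlo) | (pts[:, 0] > thi)
            bad_a = (pts[:, 1] < alo) | (pts[:, 1] > ahi)
            bad = np.flatnonzero(bad_t | bad_a)
            where = tuple(pts[bad[0]]) if bad.size else "unknown"
            raise RateDomainError(
                f"rate surface {self.name!r} evaluated at {where}, outside its "
                f"domain [{tlo}, {thi}] x [{alo}, {ahi}]"
            ) from exc
        return out.reshape(t.shape)

    def to_dict(self):
        return {
            "kind": "gridded",
            "name": self.name,
            "t_levels": [float(v) for v in self.t_levels],
            "a_levels": [float(v) for v in self.a_levels],
            "values": [[float(v) for v in row] for row in self.values],
        }


def rate_from_dict(spec: dict) -> RateSurface:
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind == "constant":
        return ConstantRate(**spec)
    if kind == "separable":
        return SeparableRate(
            time_factor=factor_from_dict(spec["time"]),
            age_factor=factor_from_dict(spec["age"]),
        )
    if kind == "gridded":
        return GriddedRate(
            t_levels=spec["t_levels"], a_levels=spec["a_levels"],
            values=np.asarray(spec["values"], dtype=float),
            name=spec.get("name", "rate"),
        )
    raise ValueError(f"unknown rate kind {kind!r}")


# ---------------------------------------------------------------------------
# the rate bundle
# ---------------------------------------------------------------------------

GENERAL_MU = "general-mu"
STATE_SPECIFIC = "state-specific"


@dataclass(frozen=True)
class RateSet:
    """The full set of transition intensities of the four-state model.

    Parameters
    ----------
    lambda0, lambda1
        Incidence of (undiagnosed) disease and detection rate.
    mode
        ``"general-mu"`` or ``"state-specific"`` (see module docstring).
    mu
        Overall mortality; required in general-mu mode, forbidden otherwise.
    mu0, mu1, mu2
        State-specific mortalities.  ``mu0`` is required in state-specific
        mode and forbidden in general-mu mode (there it is eliminated by the
        overall-mortality identity).  ``mu1``/``mu2`` may instead be given
        through the proportional ratios ``r1``/``r2``.
    r1, r2
        Mortality ratios; ``mu_j = r_j * mu`` (general-mu) or
        ``mu_j = r_j * mu0`` (state-specific).
    """

    lambda0: RateSurface
    lambda1: RateSurface
    mode: str
    mu: RateSurface | None = None
    mu0: RateSurface | None = None
    mu1: RateSurface | None = None
    mu2: RateSurface | None = None
    r1: float | None = None
    r2: float | None = None

    def __post_init__(self):
        if self.mode not in (GENERAL_MU, STATE_SPECIFIC):
            raise RateSetError(
                f"mode must be {GENERAL_MU!r} or {STATE_SPECIFIC!r}, got {self.mode!r}"
            )
        for name in ("r1", "r2"):
            r = getattr(self, name)
            if r is not None and r < 0:
                raise RateSetError(f"{name} must be >= 0, got {r}")
        for j, surf, ratio in (("mu1", self.mu1, self.r1), ("mu2", self.mu2, self.r2)):
            if (surf is None) == (ratio is None):
                raise RateSetError(
                    f"exactly one of {j} (surface) or its ratio must be supplied"
                )
        if self.mode == GENERAL_MU:
            if self.mu is None:
                raise RateSetError("general-mu mode requires the overall mortality mu")
            if self.mu0 is not None:
                raise RateSetError(
                    "general-mu mode must not supply mu0 (it is eliminated by "
                    "the overall-mortality identity)"
                )
        else:
            if self.mu0 is None:
                raise RateSetError("state-specific mode requires mu0")
            if self.mu is not None:
                raise RateSetError(
                    "state-specific mode must not supply mu (it is derived "
                    "from the prevalence via overall_mortality)"
                )

    # -- resolution helpers ------------------------------------------------
    def _ratio_base(self, t, a):
        return self.mu(t, a) if self.mode == GENERAL_MU else self.mu0(t, a)

    def mu1_at(self, t, a):
        if self.mu1 is not None:
            return self.mu1(t, a)
        return self.r1 * self._ratio_base(t, a)

    def mu2_at(self, t, a):
        if self.mu2 is not None:
            return self.mu2(t, a)
        return self.r2 * self._ratio_base(t, a)

    def to_dict(self):
        out = {
            "mode": self.mode,
            "lambda0": self.lambda0.to_dict(),
            "lambda1": self.lambda1.to_dict(),
        }
        for name in ("mu", "mu0", "mu1", "mu2"):
            surf = getattr(self, name)
            if surf is not None:
                out[name] = surf.to_dict()
        for name in ("r1", "r2"):
            r = getattr(self, name)
            if r is not None:
                out[name] = r
        return out

    @staticmethod
    def from_dict(spec: dict) -> "RateSet":
        kw = {"mode": spec["mode"]}
        for name in ("lambda0", "lambda1", "mu", "mu0", "mu1", "mu2"):
            if name in spec:
                kw[name] = rate_from_dict(spec[name])
        for name in ("r1", "r2"):
            if name in spec:
                kw[name] = float(spec[name])
        return RateSet(**kw)
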