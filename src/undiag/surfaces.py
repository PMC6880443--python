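"""Gridded solution surfaces on the Lexis plane and their CSV round trip.

Surfaces are stored row-major by calendar time ``t`` then age ``a`` and
serialized as long-format CSV (``t,a,p1,p2`` or ``t,a,N0,N1,N2``) with
full-precision decimal floats, so that a write/read round trip is bit-exact
and two runs with identical inputs produce byte-identical files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _fmt(x: float) -> str:
    """Shortest decimal that round-trips the float exactly."""
    return repr(float(x))


@dataclass(frozen=True)
class LexisGrid:
    """Regular rectangular grid ``t_levels x a_levels`` on the Lexis plane."""

    t_levels: np.ndarray
    a_levels: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t_levels, dtype=float)
        a = np.asarray(self.a_levels, dtype=float)
        for name, levels in (("t", t), ("a", a)):
            if levels.ndim != 1 or levels.size < 2:
                raise ValueError(f"{name}_levels needs at least two values")
            d = np.diff(levels)
            if np.any(d <= 0):
                raise ValueError(f"{name}_levels must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
                raise ValueError(f"{name}_levels must be regularly spaced")
        if a[0] < 0:
            raise ValueError("ages must be >= 0")
        object.__setattr__(self, "t_levels", t)
        object.__setattr__(self, "a_levels", a)

    @classmethod
    def from_range(cls, t_lo, t_hi, dt, a_lo, a_hi, da) -> "LexisGrid":
        nt = int(round((t_hi - t_lo) / dt))
        na = int(round((a_hi - a_lo) / da))
        return cls(t_lo + dt * np.arange(nt + 1), a_lo + da * np.arange(na + 1))

    @property
    def dt(self) -> float:
        return float(self.t_levels[1] - self.t_levels[0])

    @property
    def da(self) -> float:
        return float(self.a_levels[1] - self.a_levels[0])

    @property
    def shape(self):
        return (self.t_levels.size, self.a_levels.size)


def _long_csv(grid: LexisGrid, columns: dict) -> str:
    names = list(columns)
    lines = ["t,a," + ",".join(names)]
    for i, t in enumerate(grid.t_levels):
        for j, a in enumerate(grid.a_levels):
            vals = ",".join(_fmt(columns[n][i, j]) for n in names)
            lines.append(f"{_fmt(t)},{_fmt(a)},{vals}")
    return "\n".join(lines) + "\n"


def _grid_from_frame(df: pd.DataFrame) -> LexisGrid:
    return LexisGrid(np.unique(df["t"].to_numpy()), np.unique(df["a"].to_numpy()))


@dataclass
class PrevalenceSurface:
    """Solved prevalences ``p1(t, a)``, ``p2(t, a)`` on a Lexis grid."""

    grid: LexisGrid
    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self):
        for name in ("p1", "p2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            setattr(self, name, arr)

    def simplex_violation(self) -> tuple[float, tuple]:
        """Worst distance outside the prevalence simplex and where it occurs."""
        viol = np.maximum.reduce([
            -self.p1, -self.p2, self.p1 + self.p2 - 1.0,
            np.zeros_like(self.p1),
        ])
        idx = np.unravel_index(int(np.argmax(viol)), viol.shape)
        node = (float(self.grid.t_levels[idx[0]]), float(self.grid.a_levels[idx[1]]))
        return float(viol[idx]), node

    @property
    def total(self) -> np.ndarray:
        return self.p1 + self.p2

    def to_frame(self) -> pd.DataFrame:
        tt, aa = np.meshgrid(self.grid.t_levels, self.grid.a_levels, indexing="ij")
        return pd.DataFrame({
            "t": tt.ravel(), "a": aa.ravel(),
            "p1": self.p1.ravel(), "p2": self.p2.ravel(),
        })

    def write_csv(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write(_long_csv(self.grid, {"p1": self.p1, "p2": self.p2}))

    @classmethod
    def read_csv(cls, path) -> "PrevalenceSurface":
        df = pd.read_csv(path, float_precision="round_trip")
        grid = _grid_from_frame(df)
        shape = grid.shape
        return cls(grid,
                   df["p1"].to_numpy().reshape(shape),
                   df["p2"].to_numpy().reshape(shape))


@dataclass
class CountsSurface:
    """State occupancy counts ``(N0, N1, N2)`` on a Lexis grid.

    Empirical (microsimulation) surfaces may contain NaN at nodes not covered
    by any simulated cohort.
    """

    grid: LexisGrid
    N0: np.ndarray
    N1: np.ndarray
    N2: np.ndarray

    def __post_init__(self):
        for name in ("N0", "N1", "N2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            setattr(self, name, arr)

    @property
    def total(self) -> np.ndarray:
        return self.N0 + self.N1 + self.N2

    @property
    def covered(self) -> np.ndarray:
        """Nodes where counts are defined and at least one person is alive."""
        tot = self.total
        return np.isfinite(tot) & (tot > 0)

    def prevalence(self) -> PrevalenceSurface:
        """Convert counts to prevalences ``p_j = N_j / N`` (NaN where N = 0)."""
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = np.where(tot > 0, self.N1 / tot, np.nan)
            p2 = np.where(tot > 0, self.N2 / tot, np.nan)
        return PrevalenceSurface(self.grid, p1, p2)

    def to_frame(self) -> pd.DataFrame:
        tt, aa = np.meshgrid(self.grid.t_levels, self.grid.a_levels, indexing="ij")
        return pd.DataFrame({
            "t": tt.ravel(), "a": aa.ravel(),
            "N0": self.N0.ravel(), "N1": self.N1.ravel(), "N2": self.N2.ravel(),
        })

    def write_csv(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write(_long_csv(self.grid, {"N0": self.N0, "N1": self.N1, "N2": self.N2}))

    @classmethod
    def read_csv(cls, path) -> "CountsSurface":
        df = pd.read_csv(path, float_precision="round_trip")
        grid = _grid_from_frame(df)
        shape = grid.shape
        return cls(grid,
                   df["N0"].to_numpy().reshape(shape),
                   df["N1"].to_numpy().reshape(shape),
                   df["N2"].to_numpy().reshape(shape))
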