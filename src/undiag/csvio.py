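"""CSV readers and writers for rate tables and boundary profiles.

All files are UTF-8, comma-separated, with a mandatory header row.  Floats
are written as shortest round-tripping decimals so a write/read cycle is
bit-exact.  Formats:

* rate table: ``t,a,value`` — one row per node of a regular Lexis grid,
  row-major by ``t`` then ``a``;
* boundary profile: ``t,p1,p2`` (age-0 axis data) or ``a,p1,p2`` (left-edge
  age profile).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .boundaries import BoundaryCurve
from .rates import GriddedRate


def _fmt(x: float) -> str:
    return repr(float(x))


def read_rate_table(path, name: str = "rate") -> GriddedRate:
    """Load a long-format ``t,a,value`` table as a bilinear rate surface."""
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["t", "a", "value"]
    if list(df.columns) != expected:
        raise ValueError(
            f"rate table {path} must have columns {expected}, got {list(df.columns)}"
        )
    t_levels = np.unique(df["t"].to_numpy())
    a_levels = np.unique(df["a"].to_numpy())
    if t_levels.size * a_levels.size != len(df):
        raise ValueError(f"rate table {path} is not a complete regular grid")
    pivot = df.pivot(index="t", columns="a", values="value")
    values = pivot.loc[t_levels, a_levels].to_numpy()
    if np.any(~np.isfinite(values)):
        raise ValueError(f"rate table {path} has missing or non-finite nodes")
    return GriddedRate(t_levels, a_levels, values, name=name)


def write_rate_table(surface: GriddedRate, path) -> None:
    lines = ["t,a,value"]
    for i, t in enumerate(surface.t_levels):
        for j, a in enumerate(surface.a_levels):
            lines.append(f"{_fmt(t)},{_fmt(a)},{_fmt(surface.values[i, j])}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_boundary(path, axis: str) -> BoundaryCurve:
    """Load a boundary profile; ``axis`` is ``"t"`` or ``"a"``."""
    df = pd.read_csv(path, float_precision="round_trip")
    expected = [axis, "p1", "p2"]
    if list(df.columns) != expected:
        raise ValueError(
            f"boundary file {path} must have columns {expected}, got {list(df.columns)}"
        )
    return BoundaryCurve(x=df[axis].to_numpy(),
                         values=df[["p1", "p2"]].to_numpy(),
                         name=str(path))


def write_boundary(curve: BoundaryCurve, path, axis: str) -> None:
    if curve.x is None:
        raise ValueError("only tabulated boundary curves can be written")
    lines = [f"{axis},p1,p2"]
    for x, (p1, p2) in zip(curve.x, curve.values):
        lines.append(f"{_fmt(x)},{_fmt(p1)},{_fmt(p2)}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
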