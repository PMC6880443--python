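"""Validated run configurations — the reproducibility shell.

One YAML format is shared by all subcommands.  A configuration either names a
builtin scenario::

    seed: 1
    scenario:
      builtin: hypertension-like
    solver:
      step: 0.25

or spells out rates, boundary data and grid explicitly::

    scenario:
      rates:
        mode: general-mu
        lambda0: {kind: separable, time: {...}, age: {...}}
        mu: {kind: gridded, path: mu.csv}
        r1: 1.1
        r2: 1.2
      initial:
        geometry: first-quadrant
        t_min: 1999
        abscissa: {kind: constant, p1: 0.0, p2: 0.0}
        age_axis: {kind: table, path: boundary_1999.csv}
      grid: {t_lo: 1999, t_hi: 2010, dt: 1.0, a_lo: 0, a_hi: 70, da: 1.0}

Unknown keys are rejected, cross-field invariants (exactly one mortality
mode, geometry vs boundary data) are checked before any computation, and all
referenced files are verified to exist — missing ones are listed
exhaustively in a single error.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import csvio
from .boundaries import FIRST_QUADRANT, HALF_PLANE, BoundaryCurve, InitialData
from .rates import RateSet, rate_from_dict
from .surfaces import LexisGrid
from .synthetic import HYPERTENSION_SCENARIO, Scenario, make_hypertension_like_scenario


class ConfigError(ValueError):
    """A configuration file failed validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSpec(_Strict):
    t_lo: float
    t_hi: float
    dt: float = Field(gt=0)
    a_lo: float = Field(ge=0)
    a_hi: float
    da: float = Field(gt=0)

    def build(self) -> LexisGrid:
        return LexisGrid.from_range(self.t_lo, self.t_hi, self.dt,
                                    self.a_lo, self.a_hi, self.da)


class BoundarySpec(_Strict):
    kind: Literal["constant", "table"]
    p1: Optional[float] = None
    p2: Optional[float] = None
    path: Optional[str] = None

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "constant":
            if self.p1 is None or self.p2 is None or self.path is not None:
                raise ValueError("constant boundary needs p1 and p2, no path")
        else:
            if self.path is None or self.p1 is not None or self.p2 is not None:
                raise ValueError("table boundary needs a path, no p1/p2")
        return self

    def paths(self):
        return [self.path] if self.path else []

    def build(self, axis: str, base: Path) -> BoundaryCurve:
        if self.kind == "constant":
            return BoundaryCurve.constant((self.p1, self.p2))
        return csvio.read_boundary(base / self.path, axis)


_RATE_KEYS = ("lambda0", "lambda1", "mu", "mu0", "mu1", "mu2")


class RatesSpec(_Strict):
    mode: Literal["general-mu", "state-specific"]
    lambda0: dict
    lambda1: dict
    mu: Optional[dict] = None
    mu0: Optional[dict] = None
    mu1: Optional[dict] = None
    mu2: Optional[dict] = None
    r1: Optional[float] = None
    r2: Optional[float] = None

    @model_validator(mode="after")
    def _check(self):
        if self.mu is not None and self.mu0 is not None:
            raise ValueError(
                "keys 'mu' and 'mu0' are mutually exclusive: supply the "
                "overall mortality 'mu' (general-mu mode) or the healthy-state "
                "mortality 'mu0' (state-specific mode), not both"
            )
        return self

    def paths(self):
        out = []
        for key in _RATE_KEYS:
            spec = getattr(self, key)
            if spec and spec.get("kind") == "gridded" and "path" in spec:
                out.append(spec["path"])
        return out

    def build(self, base: Path) -> RateSet:
        kw = {"mode": self.mode, "r1": self.r1, "r2": self.r2}
        for key in _RATE_KEYS:
            spec = getattr(self, key)
            if spec is None:
                continue
            if spec.get("kind") == "gridded" and "path" in spec:
                kw[key] = csvio.read_rate_table(base / spec["path"], name=key)
            else:
                kw[key] = rate_from_dict(spec)
        return RateSet(**kw)


class InitialSpec(_Strict):
    geometry: Literal["half-plane", "first-quadrant"]
    abscissa: BoundarySpec
    age_axis: Optional[BoundarySpec] = None
    t_min: Optional[float] = None

    @model_validator(mode="after")
    def _check(self):
        if self.geometry == FIRST_QUADRANT:
            if self.age_axis is None or self.t_min is None:
                raise ValueError(
                    "first-quadrant geometry requires 'age_axis' data and 't_min'"
                )
        elif self.age_axis is not None or self.t_min is not None:
            raise ValueError("half-plane geometry takes no 'age_axis' or 't_min'")
        return self

    def paths(self):
        out = list(self.abscissa.paths())
        if self.age_axis:
            out += self.age_axis.paths()
        return out

    def build(self, base: Path) -> InitialData:
        return InitialData(
            geometry=self.geometry,
            abscissa=self.abscissa.build("t", base),
            age_axis=self.age_axis.build("a", base) if self.age_axis else None,
            t_min=self.t_min,
        )


class ScenarioSpec(_Strict):
    builtin: Optional[str] = None
    seed: Optional[int] = None
    rates: Optional[RatesSpec] = None
    initial: Optional[InitialSpec] = None
    grid: Optional[GridSpec] = None

    @model_validator(mode="after")
    def _check(self):
        explicit = [self.rates, self.initial, self.grid]
        if self.builtin is not None:
            if any(x is not None for x in explicit):
                raise ValueError("a builtin scenario takes no explicit rates/initial/grid")
            if self.builtin != HYPERTENSION_SCENARIO:
                raise ValueError(
                    f"unknown builtin scenario {self.builtin!r}; "
                    f"available: {HYPERTENSION_SCENARIO!r}"
                )
        elif any(x is None for x in explicit):
            raise ValueError(
                "an explicit scenario needs all of 'rates', 'initial' and 'grid'"
            )
        return self

    def paths(self):
        out = []
        if self.rates:
            out += self.rates.paths()
        if self.initial:
            out += self.initial.paths()
        return out


class SolverSpec(_Strict):
    step: Optional[float] = Field(default=None, gt=0)
    simplex: Literal["raise", "warn", "ignore"] = "raise"
    compat: Literal["raise", "warn", "skip"] = "raise"


class RunConfig(_Strict):
    seed: int = 0
    scenario: ScenarioSpec
    solver: SolverSpec = SolverSpec()
    output: Optional[str] = None
    verbosity: Literal["debug", "info", "warning", "error"] = "info"

    def build_scenario(self, base: Path) -> Scenario:
        s = self.scenario
        if s.builtin == HYPERTENSION_SCENARIO:
            return make_hypertension_like_scenario(
                s.seed if s.seed is not None else self.seed)
        return Scenario(
            rates=s.rates.build(base),
            initial=s.initial.build(base),
            grid=s.grid.build(),
            seed=s.seed if s.seed is not None else self.seed,
            description="explicit",
        )


def load_config(path) -> RunConfig:
    """Parse and fully validate a YAML run configuration.

    Schema violations are reported with their field paths; every referenced
    file that does not exist (relative to the config file) is listed.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config {path} is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping at top level")
    try:
        cfg = RunConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"config {path} failed validation:\n{exc}") from exc
    missing = [p for p in cfg.scenario.paths() if not (path.parent / p).exists()]
    if missing:
        raise ConfigError(
            f"config {path} references missing files: " + ", ".join(sorted(missing))
        )
    return cfg
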