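"""Self-contained synthetic inputs: a hypertension-like scenario, survey
noise, and an individual-level microsimulation oracle.

The scenario generator emulates a national-survey setting: a first-quadrant
Lexis window (calendar years 1999–2010, ages 0–70), zero prevalence at birth,
a Gompertz overall-mortality schedule with a mild secular decline, separable
incidence and detection rates (logistic in age, gently trending in time), and
proportional mortality ratios R1 = 1.1 (undiagnosed) and R2 = 1.2 (diagnosed).
Magnitudes are illustrative, chosen so the solved surface shows roughly 14%
undiagnosed and a total near 49% around age 60 early in the window, with the
diagnosed share rising over time; no real survey's rates are claimed.

The microsimulation is the package's independent stochastic oracle: it never
touches the PDE machinery, simulating each person's path through the
four-state model with per-step competing-risk exponential probabilities, and
tallying state occupancy on the grid.  Its empirical prevalences converge to
the characteristics solution as the cohort size grows and the step shrinks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boundaries import FIRST_QUADRANT, BoundaryCurve, InitialData
from .model import LexisPoint, PrevalenceState
from .rates import (STATE_SPECIFIC, GompertzFactor, LogisticFactor,
                    PiecewiseLinearFactor, RateSet, SeparableRate)
from .solver import solve_along_characteristic, solve_surface
from .surfaces import CountsSurface, LexisGrid, PrevalenceSurface

HYPERTENSION_SCENARIO = "hypertension-like"

#: Illustrative parameter constants of the hypertension-like scenario, all in
#: one place.  Time trends are flat before the survey window opens in 1999 so
#: that the pre-window system is autonomous and the left-edge age profile can
#: be pre-solved exactly; the gentle post-1999 trends (falling incidence,
#: rising detection, falling mortality) reproduce the qualitative pattern of
#: shrinking undiagnosed and growing diagnosed prevalence.
HYPERTENSION_PARAMS = {
    "t_start": 1900.0,          # earliest calendar time any cohort is simulated
    "t_min": 1999.0,
    "t_max": 2010.0,
    "a_max": 70.0,
    "incidence_plateau": 0.042,     # 1/year, lambda0 age factor ceiling
    "incidence_midpoint": 45.0,     # years of age
    "incidence_width": 10.0,
    "incidence_trend_2010": 0.85,   # lambda0 time factor at 2010 (1.0 at 1999)
    "detection_plateau": 0.15,      # 1/year, lambda1 age factor ceiling
    "detection_midpoint": 35.0,
    "detection_width": 12.0,
    "detection_trend_2010": 1.5,    # lambda1 time factor at 2010
    "gompertz_coef": 5.0e-5,        # mu0 at age 0, 1/year
    "gompertz_slope": 0.095,        # 1/year of age
    "mortality_trend_2010": 0.92,   # mu0 time factor at 2010
    "r1": 1.1,                      # mortality ratio, undiagnosed
    "r2": 1.2,                      # mortality ratio, diagnosed
    "grid_dt": 1.0,
    "grid_da": 1.0,
    "presolve_step": 0.02,          # RK4 step for the left-edge age profile
}


@dataclass
class Scenario:
    """A fully specified solvable problem: rates, boundary data and grid."""

    rates: RateSet
    initial: InitialData
    grid: LexisGrid
    seed: int
    description: str = ""

    def solve(self, step: float | None = None, **kwargs) -> PrevalenceSurface:
        return solve_surface(self.rates, self.initial, self.grid, step=step, **kwargs)

    def to_config(self) -> dict:
        if self.description == HYPERTENSION_SCENARIO:
            return {"builtin": HYPERTENSION_SCENARIO, "seed": int(self.seed)}
        raise NotImplementedError(
            "only builtin scenarios serialize through Scenario.to_config; "
            "compose explicit configs via undiag.config"
        )

    @staticmethod
    def from_config(spec: dict) -> "Scenario":
        if spec.get("builtin") == HYPERTENSION_SCENARIO:
            return make_hypertension_like_scenario(int(spec.get("seed", 0)))
        raise ValueError(f"unknown scenario config {spec!r}")


def _trend(t_knee: float, t_end: float, end_value: float,
           t_start: float) -> PiecewiseLinearFactor:
    """Flat at 1 until ``t_knee``, then linear to ``end_value`` at ``t_end``."""
    return PiecewiseLinearFactor(
        (t_start, t_knee, t_end, t_end + 10.0),
        (1.0, 1.0, end_value, end_value),
    )


def make_hypertension_like_scenario(seed: int = 0) -> Scenario:
    """Build the hypertension-like first-quadrant scenario.

    Zero prevalence at birth on the whole age-0 axis; the 1999 age profile is
    obtained by pre-solving the (pre-1999 autonomous) system along a life
    line, which makes the corner compatibility conditions hold exactly —
    both data curves have value (0, 0) and one-sided slope (0, 0) at the
    corner, because the incidence and detection age factors vanish at age 0.
    """
    P = HYPERTENSION_PARAMS
    t0, t1, t2 = P["t_start"], P["t_min"], P["t_max"]
    rates = RateSet(
        lambda0=SeparableRate(
            _trend(t1, t2, P["incidence_trend_2010"], t0),
            LogisticFactor(P["incidence_plateau"], P["incidence_midpoint"],
                           P["incidence_width"], floor_at_zero=True),
        ),
        lambda1=SeparableRate(
            _trend(t1, t2, P["detection_trend_2010"], t0),
            LogisticFactor(P["detection_plateau"], P["detection_midpoint"],
                           P["detection_width"], floor_at_zero=True),
        ),
        mode=STATE_SPECIFIC,
        mu0=SeparableRate(
            _trend(t1, t2, P["mortality_trend_2010"], t0),
            GompertzFactor(P["gompertz_coef"], P["gompertz_slope"]),
        ),
        r1=P["r1"], r2=P["r2"],
    )
    a_max = P["a_max"]
    # pre-1999 the time factors are constant, so the solution along the life
    # line born at t_min - a_max is exactly the age profile p(t_min, a)
    presolve = solve_along_characteristic(
        LexisPoint(t1 - a_max, 0.0), PrevalenceState(0.0, 0.0),
        rates, arc=a_max, step=P["presolve_step"],
    )
    age_axis = BoundaryCurve(x=presolve.s, values=presolve.states,
                             name="p(1999, a) (pre-solved)")
    initial = InitialData(
        geometry=FIRST_QUADRANT,
        abscissa=BoundaryCurve.constant((0.0, 0.0), name="p(t, 0)"),
        age_axis=age_axis,
        t_min=t1,
        abscissa_corner_slope=(0.0, 0.0),
        age_axis_corner_slope=(0.0, 0.0),
    )
    grid = LexisGrid.from_range(t1, t2, P["grid_dt"], 0.0, a_max, P["grid_da"])
    return Scenario(rates=rates, initial=initial, grid=grid, seed=int(seed),
                    description=HYPERTENSION_SCENARIO)


# ---------------------------------------------------------------------------
# awareness decomposition
# ---------------------------------------------------------------------------

def decompose_awareness(total_prev, awareness):
    """Split total prevalence into (undiagnosed, diagnosed) via awareness.

    Awareness is the fraction of the diseased who know their diagnosis,
    ``p2 / (p1 + p2)``; hence ``p2 = awareness * total`` and
    ``p1 = (1 - awareness) * total``.  Scalars return a
    :class:`~undiag.model.PrevalenceState`; arrays return ``(p1, p2)``.
    """
    tp = np.asarray(total_prev, dtype=float)
    aw = np.asarray(awareness, dtype=float)
    if np.any(tp < 0) or np.any(tp > 1) or np.any(aw < 0) or np.any(aw > 1):
        raise ValueError("total prevalence and awareness must lie in [0, 1]")
    p2 = aw * tp
    p1 = (1.0 - aw) * tp
    if tp.ndim == 0 and aw.ndim == 0:
        return PrevalenceState(float(p1), float(p2))
    return p1, p2


# ---------------------------------------------------------------------------
# survey samples
# ---------------------------------------------------------------------------

@dataclass
class SurveySample:
    """Binomial survey tallies per (time, age-band) cell.

    Columns: ``t, age_lo, age_hi, n, k_total, k_aware`` with the invariant
    chain ``0 <= k_aware <= k_total <= n`` in every cell.
    """

    cells: pd.DataFrame

    COLUMNS = ("t", "age_lo", "age_hi", "n", "k_total", "k_aware")

    def __post_init__(self):
        df = self.cells
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"survey sample missing columns {missing}")
        bad = (
            (df["k_aware"] < 0) | (df["k_aware"] > df["k_total"])
            | (df["k_total"] > df["n"]) | (df["n"] < 0)
        )
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} cells violate 0 <= k_aware <= k_total <= n"
            )

    def estimates(self) -> pd.DataFrame:
        """Per-cell prevalence estimates ``p_hat1``, ``p_hat2``."""
        df = self.cells.copy()
        n = df["n"].to_numpy(dtype=float)
        kt = df["k_total"].to_numpy(dtype=float)
        ka = df["k_aware"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            total = np.where(n > 0, kt / n, np.nan)
            aware = np.where(kt > 0, ka / kt, 0.0)
        df["p_hat1"] = (1.0 - aware) * total
        df["p_hat2"] = aware * total
        return df

    def write_csv(self, path) -> None:
        df = self.cells[list(self.COLUMNS)]
        lines = [",".join(self.COLUMNS)]
        for row in df.itertuples(index=False):
            lines.append(",".join(
                repr(float(v)) if c in ("t", "age_lo", "age_hi") else str(int(v))
                for c, v in zip(self.COLUMNS, row)
            ))
        with open(path, "w", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def read_csv(cls, path) -> "SurveySample":
        return cls(pd.read_csv(path, float_precision="round_trip"))


def add_survey_noise(surface: PrevalenceSurface, n_per_cell: int,
                     age_bands, seed: int) -> SurveySample:
    """Overlay binomial survey noise on a solved prevalence surface.

    For each time level and age band the band-mean prevalence is surveyed:
    ``k_total ~ Binomial(n, p1 + p2)`` cases, of which
    ``k_aware ~ Binomial(k_total, p2 / (p1 + p2))`` report a diagnosis (the
    aware fraction is taken as 0 where the band prevalence vanishes).
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5e]))
    rows = []
    a = surface.grid.a_levels
    for i, t in enumerate(surface.grid.t_levels):
        for lo, hi in age_bands:
            in_band = (a >= lo) & (a <= hi)
            if not np.any(in_band):
                raise ValueError(f"age band ({lo}, {hi}) contains no grid ages")
            p1 = float(np.mean(surface.p1[i, in_band]))
            p2 = float(np.mean(surface.p2[i, in_band]))
            total = p1 + p2
            k_total = int(rng.binomial(n_per_cell, total))
            aware = p2 / total if total > 0 else 0.0
            k_aware = int(rng.binomial(k_total, aware)) if k_total > 0 else 0
            rows.append((float(t), float(lo), float(hi), n_per_cell, k_total, k_aware))
    return SurveySample(pd.DataFrame(rows, columns=list(SurveySample.COLUMNS)))


# ---------------------------------------------------------------------------
# microsimulation oracle
# ---------------------------------------------------------------------------

@dataclass
class MicrosimResult:
    """Empirical state-occupancy counts tallied on the scenario grid.

    ``counts`` holds NaN at grid nodes not crossed by any simulated cohort;
    nodes where everyone has died are covered but yield undefined (NaN)
    prevalence, flagged through :meth:`undiag.surfaces.CountsSurface.covered`.
    """

    counts: CountsSurface
    sample: SurveySample
    persons_per_cohort: int
    dt: float

    def prevalence(self) -> PrevalenceSurface:
        return self.counts.prevalence()


def default_cohorts(grid: LexisGrid, spacing: int = 1) -> np.ndarray:
    """Birth times whose life lines pass through grid nodes.

    With integer-spaced grids these are ``t - a`` over all nodes; ``spacing``
    thins them (every k-th birth year) to trade coverage for runtime.
    """
    births = np.unique(np.round(
        np.subtract.outer(grid.t_levels, grid.a_levels).ravel(), 9))
    return births[::spacing]


def microsimulate(scenario: Scenario, cohort_birth_times, persons_per_cohort: int,
                  dt: float, seed: int) -> MicrosimResult:
    """Simulate individual persons through the four-state model.

    Every person starts in the healthy state at birth.  In each step of
    length ``dt`` the competing transitions out of the current state fire
    with exponential probabilities: from healthy, disease onset at
    ``lambda0`` or death at ``mu0``; from undiagnosed, detection at
    ``lambda1`` or death at ``mu1``; from diagnosed, death at ``mu2``.
    Rates are evaluated at the midpoint of each step along the person's life
    line, leaving an ``O(dt)`` (small-constant) discretization bias.  State
    occupancy is tallied whenever a life line crosses a node of the scenario
    grid.  Fully reproducible from ``seed``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rates = scenario.rates
    if rates.mode != STATE_SPECIFIC:
        raise ValueError(
            "microsimulation needs state-specific mortalities (mu0/mu1/mu2)"
        )
    grid = scenario.grid
    t_levels, a_levels = grid.t_levels, grid.a_levels
    t_index = {round(float(t), 9): i for i, t in enumerate(t_levels)}
    shape = grid.shape
    N = np.full(shape + (3,), np.nan)

    births = np.asarray(cohort_birth_times, dtype=float)
    children = np.random.SeedSequence([int(seed), 0x51]).spawn(births.size)
    max_rate_dt = 0.0
    rows = []
    for c, t0 in enumerate(births):
        # grid nodes on this life line: ages a with (t0 + a) a grid time level
        rec = {}
        for j, a in enumerate(a_levels):
            i = t_index.get(round(float(t0 + a), 9))
            if i is not None:
                rec[int(round(a / dt))] = (i, j)
        if not rec:
            continue
        n_steps = max(rec)
        if n_steps == 0:
            rng = np.random.default_rng(children[c])
            states = np.zeros(int(persons_per_cohort), dtype=np.int8)
            i, j = rec[0]
            N[i, j, :] = (float(states.size), 0.0, 0.0)
            rows.append((float(t0), 0.0, 0.0, int(states.size), 0, 0))
            continue
        s_mid = dt * (np.arange(n_steps) + 0.5)
        t_mid = t0 + s_mid
        lam0 = np.asarray(rates.lambda0(t_mid, s_mid), dtype=float)
        lam1 = np.asarray(rates.lambda1(t_mid, s_mid), dtype=float)
        mu0 = np.asarray(rates.mu0(t_mid, s_mid), dtype=float)
        mu1 = np.asarray(rates.mu1_at(t_mid, s_mid), dtype=float)
        mu2 = np.asarray(rates.mu2_at(t_mid, s_mid), dtype=float)
        max_rate_dt = max(max_rate_dt, float(np.max([lam0 + mu0, lam1 + mu1, mu2])) * dt)
        rho0 = lam0 + mu0
        rho1 = lam1 + mu1
        with np.errstate(invalid="ignore", divide="ignore"):
            pe0 = -np.expm1(-rho0 * dt)
            p01 = np.where(rho0 > 0, pe0 * lam0 / np.where(rho0 > 0, rho0, 1.0), 0.0)
            pe1 = -np.expm1(-rho1 * dt)
            p12 = np.where(rho1 > 0, pe1 * lam1 / np.where(rho1 > 0, rho1, 1.0), 0.0)
            pe2 = -np.expm1(-mu2 * dt)

        rng = np.random.default_rng(children[c])
        states = np.zeros(int(persons_per_cohort), dtype=np.int8)

        def tally(k):
            ij = rec.get(k)
            if ij is None:
                return
            counts = np.bincount(states, minlength=4)[:3].astype(float)
            N[ij[0], ij[1], :] = counts
            alive = int(counts.sum())
            rows.append((float(t0 + k * dt), float(k * dt), float(k * dt),
                         alive, int(counts[1] + counts[2]), int(counts[2])))

        tally(0)
        for k in range(n_steps):
            u = rng.random(states.size)
            is0 = states == 0
            is1 = states == 1
            is2 = states == 2
            to1 = is0 & (u < p01[k])
            dead = (is0 & ~to1 & (u < pe0[k]))
            to2 = is1 & (u < p12[k])
            dead |= (is1 & ~to2 & (u < pe1[k]))
            dead |= (is2 & (u < pe2[k]))
            states[to1] = 1
            states[to2] = 2
            states[dead] = 3
            tally(k + 1)

    if max_rate_dt > 0.1:
        warnings.warn(
            f"max transition rate times dt is {max_rate_dt:.3f} > 0.1; the "
            "discrete-step bias may be appreciable",
            RuntimeWarning, stacklevel=2,
        )
    counts = CountsSurface(grid, N[:, :, 0], N[:, :, 1], N[:, :, 2])
    sample = SurveySample(pd.DataFrame(rows, columns=list(SurveySample.COLUMNS)))
    return MicrosimResult(counts, sample, int(persons_per_cohort), float(dt))
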