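"""Overlay binomial survey noise and recover prevalence via awareness.

Surveys the solved surface in 5-year age bands (n = 5000 per cell, the order
of a national examination survey's cell sizes), then splits each cell's total
prevalence into undiagnosed and diagnosed parts using the surveyed awareness
fraction p2/(p1+p2).  The recovered estimates scatter around the true surface
within binomial sampling error.
"""

import numpy as np

import undiag as u

scenario = u.make_hypertension_like_scenario(seed=1)
surface = scenario.solve()

bands = [(lo, lo + 4.0) for lo in np.arange(18.0, 70.0, 5.0)]
sample = u.add_survey_noise(surface, n_per_cell=5000, age_bands=bands, seed=7)
est = sample.estimates()

year = est[np.isclose(est["t"], 2005.0)]
print("year 2005, per age band: surveyed estimates vs a worst-case 3 SE band")
n = 5000
band3se = 3 * np.sqrt(0.25 / n)
bad = 0
for row in year.itertuples(index=False):
    in_band = (surface.grid.a_levels >= row.age_lo) & (surface.grid.a_levels <= row.age_hi)
    i = int(np.flatnonzero(surface.grid.t_levels == 2005.0)[0])
    true1 = float(np.mean(surface.p1[i, in_band]))
    true2 = float(np.mean(surface.p2[i, in_band]))
    d1, d2 = abs(row.p_hat1 - true1), abs(row.p_hat2 - true2)
    bad += (d1 > band3se) + (d2 > band3se)
    print(f"  ages {row.age_lo:.0f}-{row.age_hi:.0f}: "
          f"p1_hat {row.p_hat1:.3f} (true {true1:.3f}), "
          f"p2_hat {row.p_hat2:.3f} (true {true2:.3f})")
print(f"estimates outside the worst-case 3 SE band: {bad} of {2 * len(year)}")
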