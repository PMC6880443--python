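"""Optional plots, always derived from the CSV artifacts.

Heatmap-with-contours renderings of a prevalence surface over the Lexis
window and age-specific year-slice line plots; both read the long-format
CSVs written by the solver and CLI, never in-memory-only state, so every
figure can be regenerated from files alone.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .surfaces import PrevalenceSurface


def plot_surface_heatmap(surface_csv, out_path, state: str = "p1",
                         percent: bool = True) -> None:
    """Render one prevalence component as colour plus contour lines."""
    surface = PrevalenceSurface.read_csv(surface_csv)
    values = getattr(surface, state).T * (100.0 if percent else 1.0)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    extent = [surface.grid.t_levels[0], surface.grid.t_levels[-1],
              surface.grid.a_levels[0], surface.grid.a_levels[-1]]
    im = ax.imshow(values, origin="lower", aspect="auto", extent=extent,
                   cmap="viridis")
    cs = ax.contour(surface.grid.t_levels, surface.grid.a_levels, values,
                    colors="white", linewidths=0.7)
    ax.clabel(cs, fmt="%.0f" if percent else "%.2f", fontsize=7)
    ax.set_xlabel("calendar time t (years)")
    ax.set_ylabel("age a (years)")
    label = {"p1": "undiagnosed", "p2": "diagnosed"}.get(state, state)
    fig.colorbar(im, ax=ax, label=f"{label} prevalence" + (" (%)" if percent else ""))
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_year_slice(modelled_csv, year: float, out_path,
                    surveyed_csv=None) -> None:
    """Age-specific prevalence at one year; optionally overlay a second surface."""
    modelled = PrevalenceSurface.read_csv(modelled_csv)
    i = int(np.flatnonzero(np.isclose(modelled.grid.t_levels, year))[0])
    a = modelled.grid.a_levels
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    for ax, comp, title in zip(axes, ("p1", "p2"), ("undiagnosed", "diagnosed")):
        ax.plot(a, getattr(modelled, comp)[i], "k--", label="modelled")
        if surveyed_csv is not None:
            other = PrevalenceSurface.read_csv(surveyed_csv)
            k = int(np.flatnonzero(np.isclose(other.grid.t_levels, year))[0])
            ax.plot(other.grid.a_levels, getattr(other, comp)[k], "b-",
                    label="surveyed")
        ax.set_title(f"{title}, t = {year:g}")
        ax.set_xlabel("age a (years)")
        ax.set_ylabel("prevalence")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
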