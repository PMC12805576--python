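"""Matplotlib helpers for validation figures.

All functions take an optional ``ax`` and return it, so figures compose.
"""

from __future__ import annotations

import numpy as np

from .analysis import FloryFit, RdfProfile
from .inversion import BondedDistribution

__all__ = ["plot_distribution_comparison", "plot_flory_fit", "plot_rdf"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_distribution_comparison(
    ref: BondedDistribution,
    test: BondedDistribution,
    labels=("reference", "CG"),
    ax=None,
):
    """Overlay two normalized bonded distributions (the parity check view)."""
    ax = _get_ax(ax)
    for dist, label, color in zip((ref, test), labels, ("C0", "C3")):
        edges, counts = dist.histogram()
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = counts / counts.sum() / dist.bin_width
        ax.plot(centers, dens, label=label, color=color)
    unit = "nm" if ref.kind == "bond" else "deg"
    ax.set_xlabel(f"{ref.kind} ({unit})")
    ax.set_ylabel("probability density")
    ax.legend(frameon=False)
    return ax


def plot_flory_fit(fit: FloryFit, rg, mw, ax=None):
    """Rg vs Mw on log-log axes with the fitted power law."""
    ax = _get_ax(ax)
    rg, mw = np.asarray(rg), np.asarray(mw)
    ax.loglog(mw, rg, "o", label="data")
    grid = np.logspace(np.log10(mw.min()), np.log10(mw.max()), 50)
    ax.loglog(grid, fit.predict(grid), "--",
              label=f"$R_g = R_0 M_w^{{{fit.v:.3f}}}$")
    ax.set_xlabel("$M_w$ (Da)")
    ax.set_ylabel("$R_g$ (nm)")
    ax.legend(frameon=False)
    return ax


def plot_rdf(profile: RdfProfile, label=None, ax=None):
    ax = _get_ax(ax)
    ax.plot(profile.bin_centers, profile.g, label=label)
    ax.axhline(1.0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("r (nm)")
    ax.set_ylabel("g(r)")
    if label:
        ax.legend(frameon=False)
    return ax
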