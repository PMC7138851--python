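"""Diagnostic plots for the fitting results (matplotlib)."""

from __future__ import annotations

import numpy as np

from .dalziel import DalzielResults
from .pka import ResidualActivityProfile, Hill4Fit, hill4

__all__ = ["plot_dalziel_primary", "plot_protection_profile"]


def plot_dalziel_primary(results: DalzielResults, ax=None):
    """Primary reciprocal plot: e0/v against 1/[GSH], one line per fixed
    [GSSR] level.  Parallel lines are the ping-pong signature."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = results.model.df
    p = results.params
    for gssr, sub in df.groupby("gssr_M"):
        x = 1.0 / sub["gsh_M"].to_numpy()
        y = (sub["enzyme_M"] / sub["rate_M_per_s"]).to_numpy()
        order = np.argsort(x)
        ax.plot(x[order], y[order], "o", label=f"[GSSR] = {gssr * 1e6:.0f} uM")
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, p.phi0 + p.phi1 / gssr + p.phi2 * xs, "-", color="gray",
                lw=0.8)
    ax.set_xlabel("1 / [GSH] (M$^{-1}$)")
    ax.set_ylabel("$e_0 / v$ (s)")
    ax.legend(fontsize=8)
    return ax


def plot_protection_profile(profile: ResidualActivityProfile,
                            fit: Hill4Fit | None = None, ax=None):
    """Residual activity vs pH with the fitted Hill curve overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.ph, profile.residual_pct, "o",
            label=profile.variant_label)
    if fit is not None:
        ph = np.linspace(profile.ph.min(), profile.ph.max(), 200)
        ax.plot(ph, hill4(ph, fit.top, fit.bottom, fit.midpoint, fit.hill),
                "-", label=f"pKa = {fit.midpoint:.2f}")
    ax.axhline(100.0, color="gray", lw=0.5, ls=":")
    ax.set_xlabel("pH")
    ax.set_ylabel("residual activity (%)")
    ax.legend(fontsize=8)
    return ax
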