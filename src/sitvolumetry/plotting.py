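"""Scatter/concordance and Bland-Altman plots for agreement results."""

from __future__ import annotations

import numpy as np


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(5, 5))
    return ax


def plot_concordance(results, ax=None):
    """X-Y scatter with the line of equality (dashed) and the reduced major
    axis regression line (solid)."""
    ax = _get_ax(ax)
    x, y = results.model.x, results.model.y
    ax.scatter(x, y, s=25, color="tab:blue", zorder=3)
    lim = [0.0, 1.05 * max(x.max(), y.max())]
    ax.plot(lim, lim, "k--", lw=1, label="equality")
    xs = np.linspace(lim[0], lim[1], 2)
    ax.plot(xs, results.rma.predict(xs), "k-", lw=1.5, label="RMA fit")
    cc = results.concordance
    ax.set_xlabel(f"{results.model.xname} volume (mm$^3$)")
    ax.set_ylabel(f"{results.model.yname} volume (mm$^3$)")
    ax.set_title(
        f"rho = {cc.rho:.3f}, C_b = {cc.c_b:.3f}, rho_c = {cc.rho_c:.3f}",
        fontsize=10,
    )
    ax.legend(frameon=False, fontsize=8)
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    return ax


def plot_bland_altman(results, ax=None):
    """Percent differences vs reference volume with bias and LoA lines."""
    ax = _get_ax(ax)
    x, y = results.model.x, results.model.y
    d = 100.0 * (y - x) / x
    ba = results.bland_altman
    ax.scatter(x, d, s=25, color="tab:blue", zorder=3)
    ax.axhline(ba.bias, color="k", lw=1.5)
    for loa in (ba.loa_low, ba.loa_high):
        ax.axhline(loa, color="k", lw=1, ls="--")
    ax.set_xlabel(f"{results.model.xname} volume (mm$^3$)")
    ax.set_ylabel("difference (%)")
    ax.set_title(
        f"bias = {ba.bias:.1f}%, LoA = [{ba.loa_low:.1f}%, {ba.loa_high:.1f}%]",
        fontsize=10,
    )
    return ax
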