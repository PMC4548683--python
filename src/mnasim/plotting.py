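"""Optional quick-look plots for breakthrough curves and plume maps."""

from __future__ import annotations

import numpy as np


def plot_btc(curves, labels=None, ax=None, pore_volumes: bool = True):
    """Overlay breakthrough curves; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels = labels or [c.column_id or c.analyte for c in curves]
    for curve, label in zip(curves, labels):
        x = curve.pore_volumes if pore_volumes else curve.times
        ax.plot(x, curve.concentrations, marker="o", ms=3, lw=1, label=label)
    ax.set_xlabel("pore volumes" if pore_volumes else "time (d)")
    ax.set_ylabel("effluent concentration")
    ax.legend(frameon=False)
    return ax


def plot_plume(state, site, layer: int = 1, ax=None, log: bool = True):
    """Plan-view map of one layer of a plume state; returns the Axes."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    c = state.concentration[layer]
    norm = LogNorm(vmin=max(c[c > 0].min(), 1e-4), vmax=c.max()) if log and c.max() > 0 else None
    im = ax.imshow(
        c, origin="lower", norm=norm,
        extent=(0, site.nx * site.dx, 0, site.ny * site.dy),
    )
    ax.figure.colorbar(im, ax=ax, label="mg/L")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_title(f"layer {layer}, t = {state.time:g} d")
    return ax
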