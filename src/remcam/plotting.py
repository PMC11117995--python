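"""Diagnostic plots for fitted activity and encounter-rate summaries."""
from __future__ import annotations

import numpy as np


def plot_activity(activity, ax=None, path=None):
    """Diel activity density with its bootstrap band.

    Mirrors the standard circular-activity figure: fitted density over
    time of day, dotted confidence band when the fit carried a bootstrap.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    hours = activity.grid * 24 / (2 * np.pi)
    ax.plot(hours, activity.f_hat, color="k", lw=1.5,
            label=f"p = {activity.p:.2f}")
    if activity.f_lo is not None:
        ax.plot(hours, activity.f_lo, "k:", lw=0.8)
        ax.plot(hours, activity.f_hi, "k:", lw=0.8)
    ax.set_xlabel("time of day (h)")
    ax.set_ylabel("density (rad$^{-1}$)")
    ax.set_xlim(0, 24)
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_rate_by_altitude(table, ax=None, path=None):
    """Bar plot of mean station encounter rate per altitude band."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels = [f"{int(lo)}-{int(hi)}" for lo, hi in
              zip(table["alt_lo"], table["alt_hi"])]
    ax.bar(labels, table["rate"], yerr=table["se"], color="0.6",
           edgecolor="k", capsize=3)
    ax.set_xlabel("altitude band (m)")
    ax.set_ylabel("encounter rate (/camera-day)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
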