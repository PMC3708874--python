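"""Diagnostic figures: time courses, health histograms, scan curves.

These are visual checks on simulation output, not part of the quantitative
contract; every underlying number comes from `metrics`.
"""

from __future__ import annotations

import numpy as np

from .engine import Trajectory, trajectory_table
from .metrics import health_histogram


def plot_time_courses(trajs, ax=None):
    """Ensemble mean health (with 25th-75th percentile band) and population."""
    import matplotlib.pyplot as plt

    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    df = trajectory_table(trajs)
    g = df.groupby("time_min")
    t = np.array(sorted(g.groups))
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(t, g.mean_health.mean(), color="crimson", label="mean health")
    ax.fill_between(t, g.p25_health.mean(), g.p75_health.mean(),
                    color="crimson", alpha=0.2, lw=0)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("health", color="crimson")
    ax.set_ylim(0, 1)
    ax2 = ax.twinx()
    ax2.plot(t, g.n_mito.mean(), color="steelblue", label="population")
    ax2.set_ylabel("mitochondria per cell", color="steelblue")
    return ax


def plot_health_histogram(healths, n_HU, ax=None, **bar_kw):
    """Distribution of per-mitochondrion healths on the discrete lattice."""
    import matplotlib.pyplot as plt

    centers, masses = health_histogram(healths, n_HU)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(centers, masses, width=0.8 / n_HU, **bar_kw)
    ax.set_xlabel("health")
    ax.set_ylabel("fraction of mitochondria")
    return ax


def plot_scan(agg, x, y="mean_health", hue=None, ax=None, logx=False):
    """Aggregated scan table as one curve (or one per ``hue`` value)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    if hue is None:
        ax.plot(agg[x], agg[y], "o-")
    else:
        for val, sub in agg.groupby(hue):
            ax.plot(sub[x], sub[y], "o-", label=f"{hue}={val}")
        ax.legend(fontsize=8)
    if logx:
        ax.set_xscale("log")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    return ax
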