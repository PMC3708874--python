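"""Derived quantities: steady-state summaries, fusion accounting, network
component histograms, and health distributions."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CellState, EventRecord
from .engine import Trajectory

__all__ = [
    "SteadyStateSummary",
    "steady_state_summary",
    "fusion_frequency",
    "components",
    "health_histogram",
]


@dataclass
class SteadyStateSummary:
    window: tuple[float, float]        # min
    mean_health: float
    p25_health: float
    p75_health: float
    mean_population: float
    fusion_per_hour: float             # events/hr averaged per cell
    motility_fractions: dict | None    # both / one / neither, None if no fusion
    n_empty_samples: int               # samples with zero mitochondria (health 0)


def _as_list(trajs) -> list[Trajectory]:
    return [trajs] if isinstance(trajs, Trajectory) else list(trajs)


def steady_state_summary(trajs, window: tuple[float, float]) -> SteadyStateSummary:
    """Time-and-ensemble averages over the samples inside ``window``.

    Health statistics are taken over the pooled per-mitochondrion healths of
    all cells and samples in the window; a sample with an empty cell
    contributes a single health of 0 and is counted in ``n_empty_samples``.
    """
    trajs = _as_list(trajs)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("steady-state window is empty")
    span = trajs[0].times
    if t0 < span[0] or t1 > span[-1]:
        raise ValueError(
            f"window {window} outside the simulated span ({span[0]}, {span[-1]})"
        )
    pooled, pops = [], []
    n_empty = 0
    for tr in trajs:
        sel = (tr.times >= t0) & (tr.times <= t1)
        for idx in np.flatnonzero(sel):
            h = tr.healths[idx]
            if h.size == 0:
                n_empty += 1
                pooled.append(np.zeros(1))
            else:
                pooled.append(h)
            pops.append(tr.n_mito[idx])
    pooled = np.concatenate(pooled)
    rates, counts = [], {"both": 0, "one": 0, "neither": 0}
    for tr in trajs:
        rate, fracs, n_events = _fusion_stats(tr.log, window)
        rates.append(rate)
        for k, v in n_events.items():
            counts[k] += v
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()} if total else None
    return SteadyStateSummary(
        window=(t0, t1),
        mean_health=float(pooled.mean()),
        p25_health=float(np.percentile(pooled, 25)),
        p75_health=float(np.percentile(pooled, 75)),
        mean_population=float(np.mean(pops)),
        fusion_per_hour=float(np.mean(rates)),
        motility_fractions=fractions,
        n_empty_samples=n_empty,
    )


def _fusion_stats(log, window):
    t0, t1 = window
    hours = (t1 - t0) / 60.0
    counts = {"both": 0, "one": 0, "neither": 0}
    n = 0
    for e in log:
        if e.kind == "fusion" and t0 < e.time <= t1:
            n += 1
            counts[e.detail] += 1
    fracs = {k: v / n for k, v in counts.items()} if n else None
    return n / hours, fracs, counts


def fusion_frequency(log: list[EventRecord], window: tuple[float, float]):
    """Fusion events per hour in ``window`` plus motility-class fractions.

    Events are counted on (t0, t1].  Returns ``(rate_per_hr, fractions)``;
    ``fractions`` is None (flagged undefined) when no fusion occurred.
    Additive over disjoint windows by construction.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("zero-length window")
    rate, fracs, _ = _fusion_stats(log, window)
    return rate, fracs


def components(state: CellState, mode: str = "fused", p=None,
               r: float | None = None, tol: float | None = None) -> dict[int, int]:
    """Histogram {component size: count} of fused or contact networks.

    ``fused`` uses the fusion-bond graph; ``contact`` uses the geometric
    contact graph regardless of fusion state (requires the geometry, either
    via ``p`` or explicit ``r``/``tol``).  Fused components always refine
    contact components, because bonded pairs remain in contact.
    """
    if mode == "fused":
        pairs = state.bond_indices()
    elif mode == "contact":
        from .spatial import contacts as _contacts

        pairs = _contacts(state, tol=tol, r=r, p=p).pairs
    else:
        raise ValueError("mode must be 'fused' or 'contact'")
    return components_from_pairs(state.n, pairs)


def components_from_pairs(n: int, pairs: np.ndarray) -> dict[int, int]:
    """Component-size histogram of an undirected graph on n nodes."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    if n == 0:
        return {}
    if len(pairs) == 0:
        return {1: n}
    m = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(m, directed=False)
    sizes = np.bincount(labels)
    hist: dict[int, int] = {}
    for s in sizes:
        hist[int(s)] = hist.get(int(s), 0) + 1
    return hist


def health_histogram(healths, n_HU: int, bin_width: float | None = None):
    """Normalised histogram of pooled healths on the discrete lattice.

    Health takes values on {0, 1/n_HU, ..., 1}; bins are centred on lattice
    points.  ``bin_width`` must be a positive integer multiple of 1/n_HU
    (default one lattice spacing).  Returns ``(bin_centers, masses)`` with
    masses summing to 1.
    """
    if isinstance(healths, CellState):
        healths = healths.healths()
    healths = np.concatenate([np.atleast_1d(np.asarray(h, dtype=float)) for h in
                              (healths if isinstance(healths, (list, tuple)) else [healths])])
    lattice = 1.0 / n_HU
    bin_width = lattice if bin_width is None else bin_width
    mult = bin_width / lattice
    if not math.isclose(mult, round(mult)) or round(mult) < 1:
        raise ValueError("bin width must be a positive multiple of 1/n_HU")
    edges = np.arange(-bin_width / 2, 1.0 + bin_width, bin_width)
    masses, edges = np.histogram(healths, bins=edges)
    if healths.size == 0:
        raise ValueError("no healths to histogram")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, masses / healths.size
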