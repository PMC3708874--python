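"""The stochastic quality-control processes.

Damage flips individual health units; fusion joins touching healthy
mitochondria; fission breaks bonds and exchanges a fixed number of randomly
chosen health units between the two fissioning partners (the source of
health asymmetry); autophagy removes unfused mitochondria below the health
threshold; biogenesis copies an existing mitochondrion at a rate that
saturates with population size.  All processes are Bernoulli-discretised at
the engine time step: an event of rate k fires in a step with probability
1 - exp(-k dt).
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    MOTILITY_CLASS_NAMES,
    CellState,
    EventRecord,
    Params,
)
from .spatial import ContactGraph, sample_free_position

__all__ = [
    "damage_step",
    "fusion_step",
    "fission_step",
    "exchange_units",
    "autophagy_step",
    "replication_rate",
    "replicate_step",
    "window_allows",
]


def damage_step(state: CellState, p: Params, rng: np.random.Generator) -> CellState:
    """ROS-like damage: each healthy HU flips with prob 1 - exp(-k_damage dt).

    Damaged units never recover.  In ``per_mito`` mode the same rate instead
    drives one Poisson process per mitochondrion, each event damaging one
    randomly chosen healthy unit.
    """
    if state.n == 0 or p.k_damage == 0.0:
        return state
    if p.damage_mode == "per_hu":
        p_flip = -math.expm1(-p.k_damage * p.dt)
        flips = (rng.random(state.hu.shape) < p_flip) & (state.hu == 1)
        n_flips = int(flips.sum())
        if n_flips:
            state.hu[flips] = 0
            hit = np.flatnonzero(flips.any(axis=1))
            state.log.append(EventRecord(
                state.time, "damage", tuple(int(state.ids[i]) for i in hit), n_flips
            ))
    else:  # per_mito
        p_evt = -math.expm1(-p.k_damage * p.dt)
        hit = np.flatnonzero((rng.random(state.n) < p_evt) & (state.hu.sum(axis=1) > 0))
        for i in hit:
            healthy = np.flatnonzero(state.hu[i])
            state.hu[i, rng.choice(healthy)] = 0
        if hit.size:
            state.log.append(EventRecord(
                state.time, "damage", tuple(int(state.ids[i]) for i in hit), int(hit.size)
            ))
    return state


def fusion_step(state: CellState, graph: ContactGraph, p: Params,
                rng: np.random.Generator) -> CellState:
    """Selective fusion of touching pairs.

    A touching pair fuses with probability s * (1 - exp(-k_fus dt)) when both
    members' health is at or above the fusion threshold; s scales with the
    motility class of the contact (both moving -> 1, one -> alpha, neither ->
    beta).  Fusing adds a bond (networks of more than two are allowed) and
    immobilises both members.
    """
    if len(graph) == 0 or p.k_fus == 0.0:
        return state
    pairs, motility = graph.pairs, graph.motility
    h = state.healths()
    eligible = (h[pairs[:, 0]] >= p.h_fus) & (h[pairs[:, 1]] >= p.h_fus)
    base = -math.expm1(-p.k_fus * p.dt)
    scale = np.choose(motility, [p.beta, p.alpha, 1.0])
    draws = rng.random(len(pairs))
    fuse = eligible & (draws < scale * base)
    for k in np.flatnonzero(fuse):
        i, j = int(pairs[k, 0]), int(pairs[k, 1])
        id_i, id_j = int(state.ids[i]), int(state.ids[j])
        if state.has_bond(id_i, id_j):
            continue
        state.add_bond(id_i, id_j)
        state.n_fusion += 1
        state.log.append(EventRecord(
            state.time, "fusion", (id_i, id_j),
            MOTILITY_CLASS_NAMES[int(motility[k])],
        ))
    return state


def exchange_units(a: np.ndarray, b: np.ndarray, n: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Swap n randomly chosen health units between two unit vectors.

    Positions are drawn uniformly without replacement, independently in each
    vector, and the selected unit states are swapped pairwise; the total
    healthy-unit count is conserved.  Exchanging n units is statistically
    equivalent to exchanging len - n units up to relabelling of the two
    mitochondria.
    """
    a = np.asarray(a).copy()
    b = np.asarray(b).copy()
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("unit vectors must be 1-D and of equal length")
    if not 0 <= n <= a.size:
        raise ValueError(f"cannot exchange {n} of {a.size} units")
    if n:
        pa = rng.choice(a.size, size=n, replace=False)
        pb = rng.choice(b.size, size=n, replace=False)
        a[pa], b[pb] = b[pb], a[pa].copy()
    return a, b


def fission_step(state: CellState, p: Params, rng: np.random.Generator) -> CellState:
    """Break each fusion bond with prob 1 - exp(-k_fis dt), exchanging HUs.

    The exchange applies only to the two endpoint mitochondria of the
    breaking bond.  Mitochondria left without bonds revert to independent,
    stationary, filament-unbound entities (they are already unbound).
    """
    if not state.bonds or p.k_fis == 0.0:
        return state
    p_break = -math.expm1(-p.k_fis * p.dt)
    bonds = sorted(state.bonds)
    breaks = rng.random(len(bonds)) < p_break
    nhu = state.hu.shape[1]
    hu = state.hu
    for bond, brk in zip(bonds, breaks):
        if not brk:
            continue
        id_a, id_b = bond
        ia, ib = state.index_of(id_a), state.index_of(id_b)
        pre = (int(hu[ia].sum()) / nhu, int(hu[ib].sum()) / nhu)
        if p.n_exchange:
            pa = rng.permutation(nhu)[: p.n_exchange]
            pb = rng.permutation(nhu)[: p.n_exchange]
            hu[ia, pa], hu[ib, pb] = hu[ib, pb], hu[ia, pa].copy()
        post = (int(hu[ia].sum()) / nhu, int(hu[ib].sum()) / nhu)
        state.remove_bond(id_a, id_b)
        # the daughters restart as independent entities unbound from the
        # cytoskeleton, and their encounter is scored afresh on re-contact
        state.bound[ia] = state.bound[ib] = False
        state.contact_class.pop(bond, None)
        state.n_fission += 1
        state.log.append(EventRecord(
            state.time, "fission", (id_a, id_b), {"pre": pre, "post": post}
        ))
    return state


def window_allows(timestamps, cap, now: float, window: float = 180.0) -> bool:
    """True iff fewer than ``cap`` events fall in the trailing window (now-180, now].

    ``timestamps`` is a sorted deque of past event times and is pruned in
    place; an unlimited cap (None) always allows.
    """
    while timestamps and timestamps[0] <= now - window:
        timestamps.popleft()
    return cap is None or len(timestamps) < cap


def autophagy_step(state: CellState, p: Params, rng: np.random.Generator) -> CellState:
    """Selective mitophagy of unfused mitochondria with health < h_aut.

    Each eligible mitochondrion is removed with prob 1 - exp(-k_aut dt),
    subject to the 180-min windowed cap; fused mitochondria are protected
    (the autophagosome size limit is one unfused mitochondrion).
    """
    if state.n == 0 or p.k_aut == 0.0:
        return state
    h = state.healths()
    eligible = (state.degree() == 0) & (h < p.h_aut)
    if not eligible.any():
        return state
    p_rem = -math.expm1(-p.k_aut * p.dt)
    selected = np.flatnonzero(eligible & (rng.random(state.n) < p_rem))
    removals = []
    for i in selected:
        if not window_allows(state.aut_times, p.cap_autophagy, state.time, p.CAP_WINDOW):
            break
        state.aut_times.append(state.time)
        removals.append(int(i))
        state.n_autophagy += 1
        state.log.append(EventRecord(
            state.time, "autophagy", (int(state.ids[i]),), float(h[i])
        ))
    state.remove_mitos(removals)
    return state


def replication_rate(N: float, p: Params) -> float:
    """Per-mitochondrion biogenesis rate with population-size saturation.

    k_rep * g(N), where g is monotone non-increasing with g -> 0 as the
    population grows, so the population self-limits near the typical size
    N0.  Two drop-in forms are provided:

    * ``linear`` (default): g(N) = max(0, 1 - N / N0).  The equilibrium
      population sits at N0 regardless of the feedback width, matching the
      premise of a roughly constant mitochondrial population.
    * ``logistic``: g(N) = 1 / (1 + exp((N - N0) / sigma_N)).  Smooth
      saturation; the equilibrium overshoots N0 by a few sigma_N.
    """
    if N < 0:
        raise ValueError("population size must be non-negative")
    if p.replication_form == "linear":
        return p.k_rep * max(0.0, 1.0 - N / p.N0)
    x = (N - p.N0) / p.sigma_N
    if x > 700:
        return 0.0
    return p.k_rep / (1.0 + math.exp(x))


def replicate_step(state: CellState, p: Params, rng: np.random.Generator) -> CellState:
    """Biogenesis: copy one random mitochondrion to a random free location.

    At most one replication per cell per step, with probability
    1 - exp(-N * replication_rate(N) * dt); the daughter inherits the
    progenitor's exact unit vector, starts stationary and unfused, and is
    subject to the windowed replication cap.  If no free location is found
    within the placement budget the event is skipped and logged.
    """
    N = state.n
    if N == 0 or p.k_rep == 0.0:
        return state
    p_rep = -math.expm1(-N * replication_rate(N, p) * p.dt)
    if rng.random() >= p_rep:
        return state
    if not window_allows(state.rep_times, p.cap_replication, state.time, p.CAP_WINDOW):
        return state
    progenitor = int(rng.integers(N))
    position = sample_free_position(state, p, rng)
    if position is None:
        state.log.append(EventRecord(
            state.time, "replication", (int(state.ids[progenitor]),),
            "skipped: no free placement",
        ))
        return state
    new_id = state.add_mito(position, state.hu[progenitor])
    state.rep_times.append(state.time)
    state.n_replication += 1
    state.log.append(EventRecord(
        state.time, "replication", (int(state.ids[progenitor]), new_id),
        float(state.hu[progenitor].sum() / state.hu.shape[1]),
    ))
    return state
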