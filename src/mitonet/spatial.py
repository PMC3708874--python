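"""Geometry and transport: placement, persistent random walks, contacts.

Mitochondria are hard disks of radius ``r`` whose centers live in the square
``[r, L-r]^2``.  Unfused mitochondria alternate between a stationary state
and ballistic runs along implicit cytoskeletal filaments: they bind a
filament pointing in a uniformly random direction at rate ``k_on``, move at
constant speed ``v`` and unbind at rate ``k_off``, or stop early when they
hit another mitochondrion or the cell wall.  Fused mitochondria never move.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .core import (
    BOTH_MOVING,
    NEITHER_MOVING,
    ONE_MOVING,
    CellState,
    Params,
)

__all__ = [
    "PackingError",
    "ContactGraph",
    "filling_fraction",
    "side_for_filling",
    "place_non_overlapping",
    "initial_positions",
    "sample_free_position",
    "transport_step",
    "contacts",
]


class PackingError(RuntimeError):
    """Raised when non-overlapping placement cannot be achieved."""


def filling_fraction(n: int, r: float, L: float) -> float:
    """Fraction of the cell area occupied by n disks of radius r."""
    if L <= 0:
        raise ValueError("cell side must be positive")
    return n * math.pi * r * r / (L * L)


def side_for_filling(n: int, r: float, phi: float) -> float:
    """Cell side realising filling fraction ``phi`` for n disks of radius r."""
    if not 0 < phi <= 0.9:
        raise ValueError("target filling fraction must lie in (0, 0.9]")
    return math.sqrt(n * math.pi * r * r / phi)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def place_non_overlapping(
    n: int, L: float, r: float, rng: np.random.Generator, budget: int = 100_000
) -> np.ndarray:
    """Place n disk centers uniformly in [r, L-r]^2 with pairwise distance >= 2r.

    Sequential rejection sampling; each center gets at most ``budget``
    attempts before an infeasible-packing error (which names the filling
    fraction) is raised.
    """
    if L <= 2 * r:
        raise PackingError("cell side must exceed the mitochondrial diameter")
    lo, hi = r, L - r
    pos = np.empty((n, 2))
    d2 = (2 * r) ** 2
    batch = 256
    for i in range(n):
        placed = False
        attempts = 0
        while attempts < budget:
            cand = rng.uniform(lo, hi, size=(batch, 2))
            attempts += batch
            if i == 0:
                pos[0] = cand[0]
                placed = True
                break
            dists = ((cand[:, None, :] - pos[None, :i, :]) ** 2).sum(-1)
            ok = (dists >= d2).all(axis=1)
            hit = np.flatnonzero(ok)
            if hit.size:
                pos[i] = cand[hit[0]]
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place disk {i + 1}/{n} within {budget} attempts "
                f"(filling fraction {filling_fraction(n, r, L):.3f})"
            )
    return pos


def _lattice_positions(n: int, L: float, r: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered triangular-lattice placement for dense packings.

    Used above the random-sequential-addition regime (disks jam near 55%
    coverage under pure rejection sampling).  Sites of a triangular lattice
    with the largest spacing ``a`` that still fits n sites in [r, L-r]^2 are
    jittered independently by less than (a - 2r)/2, which preserves the
    hard-disk constraint exactly.
    """
    lo, hi = r, L - r
    span = hi - lo

    def capacity(a: float) -> int:
        cols = int(span / a) + 1
        rows = int(span / (a * math.sqrt(3) / 2)) + 1
        # odd rows are offset by a/2; the last column may not fit
        full = (rows + 1) // 2 * cols
        off_cols = cols if span - (cols - 1) * a >= a / 2 else cols - 1
        return full + rows // 2 * max(off_cols, 0)

    a_lo, a_hi = 2 * r, max(span, 2 * r + 1e-9)
    if capacity(a_lo) < n:
        raise PackingError(
            f"{n} disks of radius {r} cannot fit in a {L}x{L} cell "
            f"(filling fraction {filling_fraction(n, r, L):.3f})"
        )
    for _ in range(60):
        mid = 0.5 * (a_lo + a_hi)
        if capacity(mid) >= n:
            a_lo = mid
        else:
            a_hi = mid
    a = a_lo
    sites = []
    rows = int(span / (a * math.sqrt(3) / 2)) + 1
    for j in range(rows):
        y = lo + j * a * math.sqrt(3) / 2
        x0 = lo + (a / 2 if j % 2 else 0.0)
        k = 0
        while x0 + k * a <= hi + 1e-12:
            sites.append((x0 + k * a, y))
            k += 1
    sites = np.asarray(sites)
    pick = rng.choice(len(sites), size=n, replace=False)
    pos = sites[pick]
    jit_r = max((a - 2 * r) / 2 * 0.999, 0.0)
    ang = rng.uniform(0, 2 * math.pi, n)
    rad = jit_r * np.sqrt(rng.uniform(0, 1, n))
    pos = pos + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    return np.clip(pos, lo, hi)


def initial_positions(n: int, L: float, r: float, rng: np.random.Generator,
                      budget: int = 100_000) -> np.ndarray:
    """Non-overlapping initial placement at any feasible density.

    Uses uniform rejection sampling; above ~40% coverage (where sequential
    addition jams) it falls back to a jittered triangular lattice.
    """
    if filling_fraction(n, r, L) <= 0.40:
        return place_non_overlapping(n, L, r, rng, budget)
    return _lattice_positions(n, L, r, rng)


def sample_free_position(
    state: CellState, p: Params, rng: np.random.Generator, budget: int | None = None
) -> np.ndarray | None:
    """Uniform random position not overlapping any existing mitochondrion.

    Returns None when the attempt budget is exhausted (cell too crowded).
    """
    budget = p.placement_budget if budget is None else budget
    lo, hi = p.r, p.L - p.r
    d2 = (2 * p.r) ** 2
    batch = 8  # most draws succeed quickly at typical densities
    attempts = 0
    while attempts < budget:
        cand = rng.uniform(lo, hi, size=(batch, 2))
        attempts += batch
        if state.n == 0:
            return cand[0]
        dists = ((cand[:, None, :] - state.pos[None, :, :]) ** 2).sum(-1)
        ok = (dists >= d2).all(axis=1)
        hit = np.flatnonzero(ok)
        if hit.size:
            return cand[hit[0]]
        batch = min(batch * 4, 512)
    return None


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

@njit(cache=True)
def _advance_movers(pos, order, theta, step_len, r, L, stopped):  # pragma: no cover
    """Advance movers sequentially along their filament directions.

    Each mover travels up to ``step_len`` along its direction, stopping at
    the first contact with any other disk (center distance 2r) or at the
    wall (center clamped to [r, L-r]).  ``stopped[i]`` records the cause:
    0 = free run, 1 = wall, 2 = blocked by another mitochondrion.  Earlier
    movers in ``order`` act as obstacles for later ones.
    """
    n = pos.shape[0]
    d2 = 4.0 * r * r
    for k in range(order.shape[0]):
        i = order[k]
        ux = math.cos(theta[i])
        uy = math.sin(theta[i])
        smax = step_len
        cause = 0
        # wall truncation
        if ux > 0.0:
            s = (L - r - pos[i, 0]) / ux
            if s < smax:
                smax = s
                cause = 1
        elif ux < 0.0:
            s = (r - pos[i, 0]) / ux
            if s < smax:
                smax = s
                cause = 1
        if uy > 0.0:
            s = (L - r - pos[i, 1]) / uy
            if s < smax:
                smax = s
                cause = 1
        elif uy < 0.0:
            s = (r - pos[i, 1]) / uy
            if s < smax:
                smax = s
                cause = 1
        # contact truncation: smallest positive root of |c + s u - q| = 2r
        for j in range(n):
            if j == i:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            b = dx * ux + dy * uy
            if b <= 0.0:
                continue  # moving away
            c0 = dx * dx + dy * dy - d2
            disc = b * b - c0
            if disc <= 0.0:
                continue  # ray misses the disk
            s = b - math.sqrt(disc)
            if c0 < 0.0:
                s = 0.0  # already touching/overlapping and closing: stay put
            if s < smax:
                smax = s
                cause = 2
        if smax < 0.0:
            smax = 0.0
        pos[i, 0] += smax * ux
        pos[i, 1] += smax * uy
        stopped[i] = cause


def transport_step(state: CellState, p: Params, rng: np.random.Generator) -> CellState:
    """One persistent-random-walk sub-step (in place).

    (a) every motor-free mitochondrion engages a filament with probability
    1 - exp(-k_on dt), direction uniform on [0, 2pi); (b) every engaged
    mitochondrion releases with probability 1 - exp(-k_off dt); (c) engaged
    *unfused* mitochondria advance v dt along their direction, truncated at
    the first contact or wall.  Fused mitochondria keep cycling their motor
    engagement but are anchored by the network and never translocate.
    A wall stop always releases the motor; a contact stop releases it only
    under ``on_block='detach'`` -- under the default ``'stall'`` the motor
    stays engaged (pushing against the obstacle) until k_off releases it or
    the obstacle clears.  ``state.was_moving`` records motor engagement
    during this sub-step (used for the motility classes of contacts).
    """
    n = state.n
    if n == 0:
        state.was_moving = np.zeros(0, dtype=bool)
        return state
    unfused = state.degree() == 0
    old_bound = state.bound
    p_on = -math.expm1(-p.k_on * p.dt)
    p_off = -math.expm1(-p.k_off * p.dt)

    binders = ~old_bound & (rng.random(n) < p_on)
    state.theta = np.where(binders, rng.uniform(0.0, 2 * math.pi, n), state.theta)
    stays = old_bound & ~(rng.random(n) < p_off)
    bound = stays | binders
    state.was_moving = bound.copy()

    movers = np.flatnonzero(bound & unfused)
    if movers.size:
        order = rng.permutation(movers)
        stopped = np.zeros(n, dtype=np.int8)
        _advance_movers(
            state.pos, order, state.theta, p.v * p.dt, p.r, p.L, stopped
        )
        bound &= stopped != 1  # a wall stop always detaches
        if p.on_block == "detach":
            bound &= stopped != 2
    state.bound = bound
    return state


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

@njit(cache=True)
def _contact_pairs(pos, cutoff):  # pragma: no cover
    """All index pairs (i < j) with center distance <= cutoff."""
    n = pos.shape[0]
    c2 = cutoff * cutoff
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            if dx * dx + dy * dy <= c2:
                count += 1
    out = np.empty((count, 2), dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            if dx * dx + dy * dy <= c2:
                out[k, 0] = i
                out[k, 1] = j
                k += 1
    return out


class ContactGraph:
    """Touching pairs with the motility class of each pair.

    ``pairs`` is an (m, 2) array of compact state indices (i < j);
    ``motility`` the per-pair class (0 neither, 1 one, 2 both moving), taken
    from the transport sub-step just completed.
    """

    __slots__ = ("pairs", "motility")

    def __init__(self, pairs: np.ndarray, motility: np.ndarray):
        self.pairs = pairs
        self.motility = motility

    def __len__(self) -> int:
        return len(self.pairs)


def contacts(state: CellState, tol: float | None = None, r: float | None = None,
             p: Params | None = None) -> ContactGraph:
    """All unordered pairs with center distance <= 2r + tol."""
    if p is not None:
        tol = p.contact_tol if tol is None else tol
        r = p.r if r is None else r
    if tol is None or r is None:
        raise ValueError("contacts() needs tol and r (or a Params)")
    if state.n < 2:
        return ContactGraph(np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.int8))
    cutoff = 2 * r + tol
    if state.n <= 1024:
        # compiled pair scan beats tree construction at these sizes
        pairs = _contact_pairs(state.pos, cutoff)
    else:
        tree = cKDTree(state.pos)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        pairs = np.sort(pairs.astype(np.int64), axis=1)
    if pairs.size == 0:
        return ContactGraph(pairs.reshape(0, 2), np.empty(0, dtype=np.int8))
    mv = state.was_moving
    motility = (mv[pairs[:, 0]].astype(np.int8) + mv[pairs[:, 1]].astype(np.int8))
    return ContactGraph(pairs, motility)


def formation_classes(state: CellState, graph: ContactGraph) -> ContactGraph:
    """Re-annotate a contact graph with formation-time motility classes.

    The class of a contact is fixed when the pair comes into contact (by
    whether both, one, or neither partner was in motion during that step)
    and retained while the contact persists; ``state.contact_class`` is
    rebuilt so that broken contacts forget their class.
    """
    old = state.contact_class
    new: dict[tuple[int, int], int] = {}
    motility = graph.motility.copy()
    id_a = state.ids[graph.pairs[:, 0]].tolist()
    id_b = state.ids[graph.pairs[:, 1]].tolist()
    fresh = motility.tolist()
    get = old.get
    for k, (a, b, m) in enumerate(zip(id_a, id_b, fresh)):
        key = (a, b) if a < b else (b, a)
        cls = get(key)
        if cls is None:
            cls = m
        else:
            motility[k] = cls
        new[key] = cls
    state.contact_class = new
    return ContactGraph(graph.pairs, motility)
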