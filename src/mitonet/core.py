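"""Domain types and health accounting for the mitochondrial quality-control model.

A cell is a 2D square of side ``L`` containing hard-disk mitochondria of
radius ``r``.  Each mitochondrion carries ``n_HU`` binary health units (HUs);
its *health* is the fraction of undamaged units and serves as a proxy for the
inner-membrane potential.  All stochastic processes (damage, fusion, fission,
selective autophagy, population-limited biogenesis, filament transport) act
on this state at a fixed time step ``dt``.
"""

from __future__ import annotations

import dataclasses
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "Params",
    "ParamError",
    "Mitochondrion",
    "CellState",
    "EventRecord",
    "mito_health",
    "validate_params",
    "read_config",
    "write_config",
]


class ParamError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class Params:
    """Full parameter set of the simulator.

    Defaults are the typical values used for the baseline quality-control
    simulations (25 cells, 150 mitochondria in a 25x25 um cell, 10 HUs of
    which 2 are exchanged at fission).  Rates are first-order rates per
    minute; per-step Bernoulli probabilities are ``1 - exp(-rate * dt)``.
    """

    # time discretisation
    dt: float = 1.0               # min
    t_sim: float = 10000.0        # min
    n_cells: int = 25             # ensemble size
    # geometry / population
    n_init: int = 150             # initial mitochondria per cell
    L: float = 25.0               # cell side, um
    r: float = 0.5                # mitochondrial radius, um
    # kinetic rates (min^-1)
    k_damage: float = 5e-4        # per healthy HU
    k_fus: float = 0.1            # per touching eligible pair
    k_fis: float = 0.1            # per fusion bond
    k_aut: float = 3.33e-3        # per eligible (unfused, unhealthy) mitochondrion
    k_rep: float = 0.02           # replication rate scale, per mitochondrion
    # biogenesis saturation (population-size feedback)
    N0: float = 150.0             # typical population size
    sigma_N: float = 15.0         # width of the logistic feedback form
    replication_form: str = "linear"  # "linear" or "logistic" shutoff g(N)
    # selectivity thresholds (health fractions)
    h_aut: float = 0.3
    h_fus: float = 0.3
    # discrete health representation
    n_HU: int = 10
    n_exchange: int = 2           # HUs exchanged at each fission
    # transport (persistent random walk on implicit filaments)
    v: float = 0.5                # um / min
    # motor engagement rates, calibrated against the steady-state fusion
    # frequency (~168 events/hr) and 70/25/5% motility-class split
    k_on: float = 1.2             # filament binding rate, min^-1
    k_off: float = 0.03           # filament unbinding rate, min^-1
    # motility scaling of fusion: both moving -> 1, one -> alpha, neither -> beta
    alpha: float = 1.0
    beta: float = 1.0
    # what a mover does when blocked by another mitochondrion: "stall" keeps
    # it engaged on its filament (motor pushing against the obstacle) until
    # k_off releases it; "detach" drops it to the stationary pool at once
    on_block: str = "stall"
    # windowed caps on event rates (max events per trailing 180 min); None = unlimited
    cap_autophagy: Optional[int] = None
    cap_replication: Optional[int] = None
    # damage-rate interpretation: "per_hu" (each HU an independent Poisson
    # process) or "per_mito" (one Poisson process per mitochondrion damaging
    # a random healthy unit) -- exposed for sensitivity checks
    damage_mode: str = "per_hu"
    # numerics
    contact_tol: float = 1e-2     # um, touching tolerance (2% of radius)
    record_every: float = 10.0    # min, trajectory sampling interval
    placement_budget: int = 100_000  # rejection attempts per mitochondrion
    seed: int = 0                 # master RNG seed

    # window length for the event-rate caps, min
    CAP_WINDOW: float = dataclasses.field(default=180.0, repr=False)

    def replace(self, **kwargs) -> "Params":
        return validate_params(dataclasses.replace(self, **kwargs))

    @property
    def filling_fraction(self) -> float:
        return self.n_init * math.pi * self.r**2 / self.L**2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("CAP_WINDOW")
        return d


_RATE_FIELDS = ("k_damage", "k_fus", "k_fis", "k_aut", "k_rep", "k_on", "k_off", "v")


def validate_params(p: Params | dict | None = None, **overrides) -> Params:
    """Normalise and validate a parameter set.

    Accepts a ``Params``, a plain mapping of field names, or nothing (pure
    defaults).  Every violated invariant is reported with the offending
    field named; all violations are collected into a single error.
    """
    if p is None:
        p = Params(**overrides)
    elif isinstance(p, dict):
        unknown = set(p) - {f.name for f in dataclasses.fields(Params)}
        if unknown:
            raise ParamError(f"unknown parameter(s): {sorted(unknown)}")
        p = Params(**{**p, **overrides})
    elif overrides:
        p = dataclasses.replace(p, **overrides)

    errors = []
    for name in _RATE_FIELDS:
        if getattr(p, name) < 0:
            errors.append(f"{name}: rate must be >= 0")
    for name in ("dt", "t_sim", "L", "r"):
        if getattr(p, name) < 0 or (name in ("dt", "L", "r") and getattr(p, name) == 0):
            errors.append(f"{name}: must be positive")
    for name in ("h_aut", "h_fus"):
        if not 0.0 <= getattr(p, name) <= 1.0:
            errors.append(f"{name}: threshold must lie in [0, 1]")
    if p.n_HU < 1:
        errors.append("n_HU: need at least one health unit")
    if not 0 <= p.n_exchange <= p.n_HU:
        errors.append(f"n_exchange: must lie in [0, n_HU] = [0, {p.n_HU}]")
    if not 0.0 <= p.beta <= p.alpha <= 1.0:
        errors.append("alpha/beta: require 0 <= beta <= alpha <= 1")
    if p.L <= 2 * p.r:
        errors.append("L: cell side must exceed the mitochondrial diameter 2r")
    else:
        # hexagonal close packing of disks tops out at ~0.9069 of the plane;
        # demand a margin so that placement is actually realisable
        if p.n_init * math.pi * p.r**2 > 0.9 * p.L**2:
            errors.append(
                f"n_init: filling fraction {p.filling_fraction:.3f} exceeds the "
                "packing feasibility bound (0.9 of the cell area)"
            )
    for name in ("n_cells", "n_init"):
        if getattr(p, name) < 1:
            errors.append(f"{name}: must be >= 1")
    for name in ("cap_autophagy", "cap_replication"):
        val = getattr(p, name)
        if val is not None and val < 0:
            errors.append(f"{name}: cap must be >= 0 or unlimited (None)")
    if p.damage_mode not in ("per_hu", "per_mito"):
        errors.append("damage_mode: must be 'per_hu' or 'per_mito'")
    if p.replication_form not in ("linear", "logistic"):
        errors.append("replication_form: must be 'linear' or 'logistic'")
    if p.on_block not in ("stall", "detach"):
        errors.append("on_block: must be 'stall' or 'detach'")
    if p.sigma_N <= 0:
        errors.append("sigma_N: must be positive")
    if errors:
        raise ParamError("; ".join(errors))
    return p


def read_config(path) -> Params:
    """Read a flat ``key: value`` configuration file (YAML subset)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParamError(f"config {path!r} is not a flat key: value mapping")
    return validate_params(data)


def write_config(p: Params, path) -> None:
    """Write a configuration that round-trips bit-exactly through read_config."""
    lines = []
    for key, val in p.to_dict().items():
        if val is None:
            lines.append(f"{key}: null")
        elif isinstance(val, float):
            lines.append(f"{key}: {val!r}")  # repr round-trips exactly
        else:
            lines.append(f"{key}: {val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def mito_health(hu) -> float:
    """Health of a mitochondrion: fraction of undamaged health units.

    ``hu`` is the boolean/0-1 unit vector; returns ``sum(hu) / len(hu)``.
    """
    hu = np.asarray(hu)
    if hu.size == 0:
        raise ValueError("health of an empty unit vector is undefined")
    return float(np.count_nonzero(hu)) / hu.size


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

# motility classes of a contact pair (by whether each partner moved in the
# transport sub-step preceding contact evaluation)
NEITHER_MOVING, ONE_MOVING, BOTH_MOVING = 0, 1, 2
MOTILITY_CLASS_NAMES = {NEITHER_MOVING: "neither", ONE_MOVING: "one", BOTH_MOVING: "both"}


@dataclass(frozen=True)
class Mitochondrion:
    """Read-only view of a single mitochondrion."""

    id: int
    position: tuple[float, float]
    hu: np.ndarray
    moving: bool
    direction: Optional[float]   # filament angle, radians, None if stationary
    network_id: Optional[int]    # fused-component label, None if unfused

    @property
    def health(self) -> float:
        return mito_health(self.hu)


@dataclass(slots=True)
class EventRecord:
    time: float
    kind: str         # damage | fusion | fission | autophagy | replication
    participants: tuple
    detail: object = None

    def as_line(self) -> str:
        parts = ",".join(str(i) for i in self.participants)
        return f"time={self.time:g} kind={self.kind} participants={parts} detail={self.detail}"


class CellState:
    """Mutable state of one simulated cell (struct-of-arrays layout).

    Mitochondria are stored in parallel arrays indexed compactly; each also
    carries a persistent integer id used in the fusion-bond set and event
    log, so that removals do not invalidate logged identities.
    """

    __slots__ = (
        "time", "pos", "hu", "bound", "theta", "was_moving", "ids",
        "bonds", "next_id", "_id2idx", "aut_times", "rep_times",
        "n_autophagy", "n_replication", "n_fusion", "n_fission", "log",
        "contact_class", "_deg",
    )

    def __init__(self, pos: np.ndarray, hu: np.ndarray, time: float = 0.0):
        n = len(pos)
        self.time = float(time)
        self.pos = np.asarray(pos, dtype=np.float64).copy()
        self.hu = np.asarray(hu, dtype=np.uint8).copy()
        self.bound = np.zeros(n, dtype=bool)
        self.theta = np.zeros(n, dtype=np.float64)
        self.was_moving = np.zeros(n, dtype=bool)
        self.ids = np.arange(n, dtype=np.int64)
        self.bonds: set[tuple[int, int]] = set()
        self.next_id = n
        self._id2idx = {int(i): i for i in range(n)}
        self.aut_times: deque = deque()
        self.rep_times: deque = deque()
        self.n_autophagy = 0
        self.n_replication = 0
        self.n_fusion = 0
        self.n_fission = 0
        self.log: list[EventRecord] = []
        # motility class of each live contact, keyed by id pair, recorded
        # when the pair came into contact and kept while the contact lasts
        self.contact_class: dict[tuple[int, int], int] = {}
        self._deg = np.zeros(n, dtype=np.int64)

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.pos)

    def healths(self) -> np.ndarray:
        if self.n == 0:
            return np.empty(0)
        return self.hu.sum(axis=1) / self.hu.shape[1]

    def degree(self) -> np.ndarray:
        """Number of fusion bonds per mitochondrion (0 = unfused).

        Maintained incrementally; treat the returned array as read-only.
        """
        return self._deg

    def index_of(self, mito_id: int) -> int:
        return self._id2idx[mito_id]

    def bond_indices(self) -> np.ndarray:
        """Bonds as an (m, 2) array of current compact indices."""
        if not self.bonds:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(
            [(self._id2idx[a], self._id2idx[b]) for a, b in self.bonds], dtype=np.int64
        )

    def network_ids(self) -> np.ndarray:
        """Connected-component label per mitochondrion; -1 for unfused."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        labels = np.full(self.n, -1, dtype=np.int64)
        if not self.bonds:
            return labels
        bi = self.bond_indices()
        m = coo_matrix(
            (np.ones(len(bi)), (bi[:, 0], bi[:, 1])), shape=(self.n, self.n)
        )
        _, comp = connected_components(m, directed=False)
        deg = self.degree()
        labels[deg > 0] = comp[deg > 0]
        return labels

    def mitochondria(self) -> Iterator[Mitochondrion]:
        nets = self.network_ids()
        for i in range(self.n):
            fused = nets[i] >= 0
            # fused mitochondria are anchored: they may cycle motor
            # engagement internally but are never in translational motion
            moving = bool(self.bound[i]) and not fused
            yield Mitochondrion(
                id=int(self.ids[i]),
                position=(float(self.pos[i, 0]), float(self.pos[i, 1])),
                hu=self.hu[i].copy(),
                moving=moving,
                direction=float(self.theta[i]) if moving else None,
                network_id=int(nets[i]) if fused else None,
            )

    # -- mutation -----------------------------------------------------------

    def add_mito(self, position, hu_row) -> int:
        new_id = self.next_id
        self.next_id += 1
        self.pos = np.vstack([self.pos, np.asarray(position, dtype=np.float64)])
        self.hu = np.vstack([self.hu, np.asarray(hu_row, dtype=np.uint8)])
        self.bound = np.append(self.bound, False)
        self.theta = np.append(self.theta, 0.0)
        self.was_moving = np.append(self.was_moving, False)
        self.ids = np.append(self.ids, new_id)
        self._deg = np.append(self._deg, 0)
        self._id2idx[new_id] = self.n - 1
        return new_id

    def remove_mitos(self, indices) -> None:
        indices = sorted(set(int(i) for i in indices))
        if not indices:
            return
        removed_ids = {int(self.ids[i]) for i in indices}
        if any(a in removed_ids or b in removed_ids for a, b in self.bonds):
            raise ValueError("cannot remove a bonded (fused) mitochondrion")
        keep = np.ones(self.n, dtype=bool)
        keep[indices] = False
        self.pos = self.pos[keep]
        self.hu = self.hu[keep]
        self.bound = self.bound[keep]
        self.theta = self.theta[keep]
        self.was_moving = self.was_moving[keep]
        self.ids = self.ids[keep]
        self._deg = self._deg[keep]
        self._id2idx = {int(mid): i for i, mid in enumerate(self.ids)}

    def add_bond(self, id_a: int, id_b: int) -> None:
        if id_a == id_b:
            raise ValueError("a mitochondrion cannot fuse with itself")
        bond = (min(id_a, id_b), max(id_a, id_b))
        if bond not in self.bonds:
            self.bonds.add(bond)
            self._deg[self._id2idx[id_a]] += 1
            self._deg[self._id2idx[id_b]] += 1

    def remove_bond(self, id_a: int, id_b: int) -> None:
        bond = (min(id_a, id_b), max(id_a, id_b))
        if bond in self.bonds:
            self.bonds.discard(bond)
            self._deg[self._id2idx[id_a]] -= 1
            self._deg[self._id2idx[id_b]] -= 1

    def has_bond(self, id_a: int, id_b: int) -> bool:
        return (min(id_a, id_b), max(id_a, id_b)) in self.bonds

    def copy(self) -> "CellState":
        import copy as _copy

        new = CellState.__new__(CellState)
        for name in self.__slots__:
            val = getattr(self, name)
            if isinstance(val, np.ndarray):
                val = val.copy()
            elif isinstance(val, (set, dict, deque)):
                val = _copy.copy(val)
            elif isinstance(val, list):
                val = list(val)
            setattr(new, name, val)
        return new
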