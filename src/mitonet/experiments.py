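"""Config-driven parameter scans, transport calibration, and test fixtures.

Each preset reproduces one of the model's in-silico experiments: nested
model comparisons (damage only, +autophagy, +biogenesis, +fusion/fission),
the exchange-count scan, the threshold grid, the density scan, the motility
scan, the capped-rate scan, and the health-unit discreteness scan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .core import Params, validate_params
from .engine import run_ensemble
from .spatial import side_for_filling

__all__ = [
    "ExperimentSpec",
    "steady_window",
    "apply_point",
    "run_experiment",
    "preset",
    "PRESETS",
    "calibrate_transport",
    "make_fixture",
]

# steady-state window: final fifth of the run (last 2000 min of the default
# 10000-min simulation)
STEADY_FRACTION = 0.2


def steady_window(p: Params) -> tuple[float, float]:
    return (p.t_sim * (1 - STEADY_FRACTION), p.t_sim)


@dataclass
class ExperimentSpec:
    """A Cartesian parameter scan over a base configuration.

    Axis keys are Params field names, plus pseudo-fields: ``phi`` (target
    filling fraction, realised by adjusting the cell side at fixed n_init),
    ``n_HU_coupled`` (sets n_HU and scales n_exchange to n_HU / 5), ``ab``
    (an (alpha, beta) pair), and ``variant`` (a (label, overrides-dict) pair
    for non-factorial scans).
    """

    name: str
    base: Params
    axes: dict = field(default_factory=dict)
    n_cells: int | None = None
    window: tuple[float, float] | None = None

    def __post_init__(self):
        valid = set(Params.__dataclass_fields__) | {"phi", "n_HU_coupled", "ab", "variant"}
        bad = set(self.axes) - valid
        if bad:
            raise ValueError(f"scan axes reference unknown fields: {sorted(bad)}")
        if self.n_cells is not None and self.n_cells < 1:
            raise ValueError("ensemble size must be >= 1")


def apply_point(base: Params, point: dict) -> Params:
    """Materialise one scan point into a validated Params."""
    updates = {}
    for key, val in point.items():
        if key == "phi":
            updates["L"] = side_for_filling(base.n_init, base.r, val)
        elif key == "n_HU_coupled":
            updates["n_HU"] = int(val)
            updates["n_exchange"] = max(int(round(val / 5)), 0)
        elif key == "ab":
            updates["alpha"], updates["beta"] = val
        elif key == "variant":
            updates.update(val[1])
        else:
            updates[key] = val
    return base.replace(**updates)


def run_experiment(spec: ExperimentSpec, master_seed=None):
    """Run the full scan; returns (per-cell table, aggregated table).

    One ensemble per grid point, each with an independent RNG stream spawned
    from the master seed, so the scan is reproducible and restartable.
    The per-cell table has one row per (point, cell); the aggregate one row
    per point with pooled steady-state statistics.
    """
    base = validate_params(spec.base)
    master_seed = base.seed if master_seed is None else master_seed
    if not isinstance(master_seed, np.random.SeedSequence):
        master_seed = np.random.SeedSequence(master_seed)
    axes = spec.axes or {"_": [None]}
    names = [k for k in axes if k != "_"]
    grid = list(itertools.product(*axes.values()))
    seeds = master_seed.spawn(len(grid))
    cell_rows, agg_rows = [], []
    n_cells = spec.n_cells if spec.n_cells is not None else base.n_cells
    try:
        _run_points(spec, base, axes, grid, seeds, n_cells, cell_rows, agg_rows)
    except Exception as exc:
        err = RuntimeError(
            f"experiment {spec.name!r} failed after {len(agg_rows)}/{len(grid)} "
            f"points: {exc}"
        )
        # completed grid points stay available on the raised error
        err.partial = (pd.DataFrame(cell_rows), pd.DataFrame(agg_rows))
        raise err from exc
    cols = names + [c for c in (cell_rows[0] if cell_rows else {}) if c not in names]
    return pd.DataFrame(cell_rows, columns=cols or None), pd.DataFrame(agg_rows)


def _run_points(spec, base, axes, grid, seeds, n_cells, cell_rows, agg_rows):
    for point_idx, values in enumerate(grid):
        raw = {k: v for k, v in zip(axes.keys(), values) if k != "_"}
        p = apply_point(base, raw)
        # tables record human-readable point coordinates
        point = {k: (v[0] if k == "variant" else v) for k, v in raw.items()}
        window = spec.window or steady_window(p)
        trajs = run_ensemble(p, n_cells=n_cells, master_seed=seeds[point_idx])
        for cid, tr in enumerate(trajs):
            s = metrics.steady_state_summary(tr, window)
            cell_rows.append(
                {**point, "cell_id": cid, "mean_health": s.mean_health,
                 "mean_population": s.mean_population,
                 "fusion_per_hour": s.fusion_per_hour}
            )
        s = metrics.steady_state_summary(trajs, window)
        row = {**point,
               "mean_health": s.mean_health,
               "p25_health": s.p25_health,
               "p75_health": s.p75_health,
               "mean_population": s.mean_population,
               "fusion_per_hour": s.fusion_per_hour,
               "n_empty_samples": s.n_empty_samples}
        if s.motility_fractions:
            for k, v in s.motility_fractions.items():
                row[f"frac_{k}"] = v
        agg_rows.append(row)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _presets(base: Params) -> dict[str, ExperimentSpec]:
    return {
        # nested models: damage alone, +autophagy, +biogenesis, +fusion/fission
        "knockouts": ExperimentSpec(
            "knockouts", base,
            axes={"variant": [
                ("damage", dict(k_aut=0.0, k_rep=0.0, k_fus=0.0, k_fis=0.0)),
                ("damage+autophagy", dict(k_rep=0.0, k_fus=0.0, k_fis=0.0)),
                ("damage+autophagy+replication", dict(k_fus=0.0, k_fis=0.0)),
                ("full", {}),
            ]},
        ),
        # exchange-count scan at several fusion rates
        "exchange-scan": ExperimentSpec(
            "exchange-scan", base,
            axes={"n_exchange": list(range(0, base.n_HU + 1)),
                  "k_fus": [0.01, 0.1, 1.0]},
        ),
        # threshold grid
        "threshold-grid": ExperimentSpec(
            "threshold-grid", base,
            axes={"h_aut": [round(0.1 * i, 1) for i in range(1, 9)],
                  "h_fus": [round(0.1 * i, 1) for i in range(0, 10)]},
        ),
        # density scan at fixed population (cell side varies)
        "density-scan": ExperimentSpec(
            "density-scan", base,
            axes={"phi": [0.01, 0.02, 0.05, 0.10, 0.19, 0.30, 0.42, 0.55]},
        ),
        # motility scaling scan over valid (alpha, beta) pairs
        "motility-scan": ExperimentSpec(
            "motility-scan", base,
            axes={"ab": [(1.0, 1.0), (1.0, 0.5), (1.0, 0.1), (0.5, 0.5),
                         (0.5, 0.1), (0.1, 0.1)],
                  "k_fus": [0.01, 0.1, 1.0], "v": [0.05, 0.5]},
        ),
        # windowed caps on autophagy / replication
        "cap-scan": ExperimentSpec(
            "cap-scan", base,
            axes={"cap_autophagy": [None, 40, 20, 10, 5, 2],
                  "cap_replication": [None, 40, 20, 10, 5, 2]},
        ),
        # health-unit discreteness scan (n_exchange locked to n_HU / 5)
        "discreteness-scan": ExperimentSpec(
            "discreteness-scan", base,
            axes={"n_HU_coupled": [5, 10, 25, 50, 100, 200],
                  "k_fus": [0.0, base.k_fus]},
        ),
    }


# short aliases, numbered in the order the presets are usually run
PRESET_ALIASES = {
    "fig3": "knockouts",
    "fig4": "exchange-scan",
    "fig5": "threshold-grid",
    "fig6": "density-scan",
    "fig7": "motility-scan",
    "fig8": "cap-scan",
    "fig9": "discreteness-scan",
}


def preset(name: str, base: Params | None = None) -> ExperimentSpec:
    base = validate_params(base) if base is not None else validate_params()
    name = PRESET_ALIASES.get(name, name)
    try:
        return _presets(base)[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_presets(base))}")


PRESETS = tuple(sorted(_presets(validate_params())))


# ---------------------------------------------------------------------------
# transport calibration
# ---------------------------------------------------------------------------

def calibrate_transport(
    targets: dict | None = None,
    p: Params | None = None,
    k_on_grid=(0.8, 1.0, 1.2, 1.6, 2.4),
    k_off_grid=(0.03, 0.05, 0.1, 0.2, 0.4),
    n_cells: int = 6,
    t_sim: float = 4000.0,
    master_seed: int = 2013,
    rel_tol: float = 0.15,
):
    """Grid-search (k_on, k_off) against the fusion-accounting observables.

    Targets default to an overall fusion frequency of 168 events/hr with a
    70/25/5% both/one/neither motility-class split.  Minimises the summed
    squared relative error of the four observables over the grid; returns
    ``(best (k_on, k_off), achieved dict, table, converged flag)``.
    """
    targets = targets or {"fusion_per_hour": 168.0, "both": 0.70, "one": 0.25,
                          "neither": 0.05}
    fr = [targets["both"], targets["one"], targets["neither"]]
    if min(fr) <= 0 or abs(sum(fr) - 1.0) > 1e-6 or targets["fusion_per_hour"] <= 0:
        raise ValueError("class-fraction targets must be positive and sum to 1")
    base = validate_params(p) if p is not None else validate_params()
    base = base.replace(t_sim=t_sim, alpha=1.0, beta=1.0)
    rows = []
    seeds = np.random.SeedSequence(master_seed).spawn(len(k_on_grid) * len(k_off_grid))
    for idx, (k_on, k_off) in enumerate(itertools.product(k_on_grid, k_off_grid)):
        pt = base.replace(k_on=k_on, k_off=k_off)
        trajs = run_ensemble(pt, n_cells=n_cells, master_seed=seeds[idx])
        s = metrics.steady_state_summary(trajs, steady_window(pt))
        obs = {
            "fusion_per_hour": s.fusion_per_hour,
            "both": (s.motility_fractions or {}).get("both", 0.0),
            "one": (s.motility_fractions or {}).get("one", 0.0),
            "neither": (s.motility_fractions or {}).get("neither", 0.0),
        }
        err = sum(((obs[k] - targets[k]) / targets[k]) ** 2 for k in targets)
        rows.append({"k_on": k_on, "k_off": k_off, **obs, "objective": err})
    table = pd.DataFrame(rows).sort_values("objective").reset_index(drop=True)
    best = table.iloc[0]
    achieved = {k: float(best[k]) for k in targets}
    converged = all(
        abs(achieved[k] - targets[k]) / targets[k] <= rel_tol for k in targets
    )
    return (float(best["k_on"]), float(best["k_off"])), achieved, table, converged


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str) -> Params:
    """Small, fast configurations preserving the dimensionless ratios of the
    default model (filling fraction, rate x dt products)."""
    base = validate_params()
    if name == "tiny-default":
        # 20 mitochondria at the default filling fraction
        return base.replace(
            n_init=20, t_sim=500.0, n_cells=3, N0=20.0, sigma_N=2.0,
            L=side_for_filling(20, base.r, base.filling_fraction),
        )
    if name == "damage-only":
        return base.replace(
            n_init=20, t_sim=500.0, n_cells=3,
            L=side_for_filling(20, base.r, base.filling_fraction),
            k_fus=0.0, k_fis=0.0, k_aut=0.0, k_rep=0.0, k_on=0.0, k_off=0.0,
        )
    if name == "crowded":
        return base.replace(
            n_init=30, t_sim=500.0, n_cells=3, N0=30.0, sigma_N=3.0,
            L=side_for_filling(30, base.r, 0.55),
        )
    raise KeyError(f"unknown fixture {name!r}; available: "
                   "'tiny-default', 'damage-only', 'crowded'")
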