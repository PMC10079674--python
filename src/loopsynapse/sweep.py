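"""Parameter sweeps and in-silico knockouts over the five synapsis mechanisms.

The five axes are: BE stabilization fold ``w``, long-lived LEF fraction
``alpha0``, DSB-end stabilization fold ``r``, targeted loading fold ``F``,
and the processivity/separation ratio ``lambda/d`` (separation held
fixed).  Each grid point is simulated with independent replicate seeds
derived from the master seed, so tables are reproducible and extendable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig, spawn_seeds
from .lattice import run_simulation

__all__ = ["AXES", "SweepPoint", "run_point", "run_grid", "minimal_parameters", "knockout"]

# axis name -> (config field, null/knockout value)
AXES = {
    "w": ("be_stabilization_fold", 1.0),
    "alpha0": ("longlived_fraction", 0.0),
    "r": ("dsb_stabilization_fold", 1.0),
    "F": ("targeted_loading_fold", 1.0),
    "lam_over_d": (None, 0.5),    # sets lef_processivity_kb = ratio * separation
}


def _apply_axis(config: SimConfig, axis: str, value: float) -> SimConfig:
    if axis not in AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; known: {sorted(AXES)}")
    fld, _ = AXES[axis]
    if fld is None:
        return config.replace(lef_processivity_kb=value * config.lef_separation_kb)
    return config.replace(**{fld: value})


def point_values(config: SimConfig) -> dict:
    return {
        "w": config.be_stabilization_fold,
        "alpha0": config.longlived_fraction,
        "r": config.dsb_stabilization_fold,
        "F": config.targeted_loading_fold,
        "lam_over_d": config.lef_processivity_kb / config.lef_separation_kb,
    }


@dataclass
class SweepPoint:
    values: dict
    efficiencies: list = field(default_factory=list)
    mean_times_min: list = field(default_factory=list)

    @property
    def efficiency(self) -> float:
        return float(np.mean(self.efficiencies))

    @property
    def efficiency_sem(self) -> float:
        n = len(self.efficiencies)
        return float(np.std(self.efficiencies, ddof=1) / np.sqrt(n)) if n > 1 else np.nan

    @property
    def mean_time_min(self) -> float:
        vals = [t for t in self.mean_times_min if np.isfinite(t)]
        return float(np.mean(vals)) if vals else np.nan


def run_point(config: SimConfig, reps: int = 3, stream: str = "") -> SweepPoint:
    """Simulate one parameter point with ``reps`` independent replicates."""
    vals = point_values(config)
    key = stream or ",".join(f"{k}={vals[k]:g}" for k in sorted(vals))
    seeds = spawn_seeds(config.seed, reps, f"sweep:{key}")
    pt = SweepPoint(vals)
    for s in seeds:
        res = run_simulation(config, seed=int(s))
        pt.efficiencies.append(res.efficiency)
        pt.mean_times_min.append(res.mean_synapsis_time_min)
    return pt


def run_grid(grid: dict, config: SimConfig, reps: int = 3,
             progress=None) -> pd.DataFrame:
    """Run the cartesian product of ``grid`` (axis name -> list of values).

    Returns one row per point with replicate efficiencies, the mean +- SEM
    and the mean synapsis time.  Identical seeds give identical tables.
    """
    if not grid:
        raise ValueError("empty sweep grid")
    axes = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[a] for a in axes)):
        cfg = config
        for a, v in zip(axes, combo):
            cfg = _apply_axis(cfg, a, v)
        pt = run_point(cfg, reps=reps)
        row = dict(pt.values)
        row["efficiency"] = pt.efficiency
        row["efficiency_sem"] = pt.efficiency_sem
        row["mean_time_min"] = pt.mean_time_min
        row["rep_efficiencies"] = tuple(pt.efficiencies)
        rows.append(row)
        if progress is not None:
            progress(row)
    return pd.DataFrame(rows)


def minimal_parameters(table: pd.DataFrame, threshold: float = 0.95) -> dict:
    """Minimum value used on each axis among points whose mean efficiency
    meets the threshold; empty dict when no point survives."""
    if len(table) == 0:
        raise ValueError("empty sweep table")
    ok = table[table["efficiency"] >= threshold]
    if len(ok) == 0:
        import warnings

        warnings.warn(f"no sweep point reaches efficiency >= {threshold}")
        return {}
    return {a: float(ok[a].min()) for a in AXES if a in ok.columns}


def knockout(config: SimConfig, axis: str, reps: int = 3,
             reference: SweepPoint | None = None) -> pd.DataFrame:
    """Re-run ``config`` with one mechanism reset to its null value.

    Returns a one-row table with reference and knockout efficiency and
    mean synapsis time plus their changes (percentage points for
    efficiency, percent for the mean time).
    """
    if axis not in AXES:
        raise ValueError(f"unknown knockout axis {axis!r}; known: {sorted(AXES)}")
    _, null = AXES[axis]
    if reference is None:
        reference = run_point(config, reps=reps)
    ko_cfg = _apply_axis(config, axis, null)
    ko = run_point(ko_cfg, reps=reps)
    dt = np.nan
    if np.isfinite(reference.mean_time_min) and reference.mean_time_min > 0:
        dt = 100.0 * (ko.mean_time_min - reference.mean_time_min) / reference.mean_time_min
    return pd.DataFrame(
        [
            {
                "axis": axis,
                "ref_efficiency": reference.efficiency,
                "ko_efficiency": ko.efficiency,
                "delta_efficiency": ko.efficiency - reference.efficiency,
                "ref_mean_time_min": reference.mean_time_min,
                "ko_mean_time_min": ko.mean_time_min,
                "mean_time_increase_pct": dt,
                "ko_efficiency_sem": ko.efficiency_sem,
            }
        ]
    )
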