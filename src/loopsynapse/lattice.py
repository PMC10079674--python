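"""1D lattice Monte Carlo engine for LEF-mediated DSB end synapsis.

The engine advances a fixed population of ``floor(G/d)`` loop-extruding
factors (LEFs) on a 1-kb lattice.  Each LEF has two motors that step
outward one site per Monte Carlo step (2 kb total extrusion per step,
i.e. 2 s of real time at a total speed of 1 kb/s).  Motors stall
permanently at convergently oriented boundary elements with probability
``b``, refuse to bypass other motors or broken DSB ends, and the whole LEF
unbinds with per-step probability ``2/lambda`` divided by the applicable
stabilization folds, reloading immediately at a random free site (with
``F``-fold weight on broken DSB-end sites).

After a configurable burn-in all DSBs are introduced simultaneously and
per-DSB synapsis outcomes are recorded: a DSB is *constrained* if at least
one LEF spans both ends; synapsis succeeds once the unextruded gaps between
the innermost constraining LEF and both DSB ends are each at most two
sites while a constraining LEF remains; it fails when the last constraining
LEF unbinds first; initially unconstrained DSBs fail at time zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .config import SimConfig, spawn_seeds
from .genome import GenomeLayout, place_boundaries, place_dsbs

__all__ = ["LatticeSimulation", "SimResult", "run_simulation", "loop_coverage_from_snapshot"]

_CONS_CAP = 256
_STACK_CAP = 1024


@dataclass
class SimResult:
    config: SimConfig
    layout: GenomeLayout
    outcomes: pd.DataFrame
    snapshots: dict = field(default_factory=dict)
    loading_events: int = 0
    loading_events_at_ends: int = 0

    @property
    def efficiency(self) -> float:
        """Fraction of all DSBs that achieved synapsis."""
        return float((self.outcomes["result"] == "success").mean())

    @property
    def mean_synapsis_time_min(self) -> float:
        ok = self.outcomes.loc[self.outcomes["result"] == "success", "time_min"]
        return float(ok.mean()) if len(ok) else float("nan")

    @property
    def constrained_fraction(self) -> float:
        return float(self.outcomes["constrained"].mean())


class LatticeSimulation:
    """Mutable simulation state with explicit stepping, for tests and drivers.

    Most users should call :func:`run_simulation` instead.
    """

    def __init__(self, config: SimConfig, layout: GenomeLayout | None = None,
                 seed: int | None = None):
        config.validate()
        self.config = config
        seed = config.seed if seed is None else seed
        placement_seed, kernel_seed = (int(s) for s in spawn_seeds(seed, 2, "lattice"))
        rng = np.random.default_rng(placement_seed)
        if layout is None:
            layout = place_boundaries(config, rng)
            place_dsbs(layout, config, rng)
        self.layout = layout
        G = config.genome_length_kb
        N = config.n_lefs
        self.n_lefs = N

        self.left = np.full(N, -1, dtype=np.int64)
        self.right = np.full(N, -1, dtype=np.int64)
        self.stall_l = np.zeros(N, dtype=np.uint8)
        self.stall_r = np.zeros(N, dtype=np.uint8)
        self.longlived = np.zeros(N, dtype=np.uint8)
        n_ll = int(round(config.longlived_fraction * N))
        self.longlived[:n_ll] = 1

        self.pack = np.zeros(G, dtype=np.int32)
        self.flags = np.zeros(G, dtype=np.uint8)
        for be in layout.boundary_elements:
            self.flags[be.site] |= K.F_BE
            # a left-facing BE is convergent with rightward-stepping motors
            self.flags[be.site] |= K.F_BLK_R if be.orientation == "left" else K.F_BLK_L
        self.end_idx = np.full(G, -1, dtype=np.int32)

        n_dsb = len(layout.dsbs)
        self.end_sites = np.zeros(2 * n_dsb, dtype=np.int64)
        self.end_stack = np.zeros((max(2 * n_dsb, 1), _STACK_CAP), dtype=np.int32)
        self.end_stack_n = np.zeros(max(2 * n_dsb, 1), dtype=np.int32)
        self.perm = np.zeros(2 * N, dtype=np.int32)
        self.meta = np.zeros(8, dtype=np.int64)
        self.meta[K.META_FREE] = G - int((self.flags & K.F_BE > 0).sum())

        self.dsb_left = np.asarray([d.left_end_site for d in layout.dsbs], dtype=np.int64)
        self.dsb_state = np.full(n_dsb, -1, dtype=np.int8)
        self.dsb_time = np.zeros(n_dsb, dtype=np.int64)
        self.cons = np.zeros((max(n_dsb, 1), _CONS_CAP), dtype=np.int32)
        self.cons_n = np.zeros(max(n_dsb, 1), dtype=np.int32)
        self.cons_map = np.full(N, -1, dtype=np.int32)
        self.initially_constrained = np.zeros(n_dsb, dtype=np.uint8)

        self.broken = False
        self.post_dsb_steps = 0
        self.rng_state = K.make_rng_state(kernel_seed)
        K.init_load(self._F, G, self.left, self.right, self.pack, self.flags,
                    self._active_end_sites, self.end_idx,
                    self.end_stack, self.end_stack_n, self.meta, self.rng_state)

    # -- kernel parameter helpers ------------------------------------------
    @property
    def _p_off(self) -> float:
        return min(1.0, 2.0 / self.config.lef_processivity_kb)

    @property
    def _F(self) -> float:
        return float(self.config.targeted_loading_fold)

    @property
    def _active_end_sites(self) -> np.ndarray:
        return self.end_sites if self.broken else self.end_sites[:0]

    def step(self, n_steps: int, monitor: bool | None = None) -> int:
        """Advance ``n_steps``; returns the number actually executed (the
        kernel exits early once every monitored DSB is resolved)."""
        if monitor is None:
            monitor = self.broken
        c = self.config
        done = K.run_steps(
            n_steps, self.post_dsb_steps if self.broken else 0,
            self.left, self.right, self.stall_l, self.stall_r, self.longlived,
            self.pack, self.flags, self._active_end_sites,
            self.end_idx, self.end_stack, self.end_stack_n, self.perm, self.meta,
            self.rng_state,
            self.dsb_left if monitor else self.dsb_left[:0],
            self.dsb_state, self.dsb_time, self.cons, self.cons_n, self.cons_map,
            self._p_off, c.boundary_strength, c.be_stabilization_fold,
            c.dsb_stabilization_fold, c.longlived_fold, self._F, monitor)
        if self.broken:
            self.post_dsb_steps += done
        if self.meta[K.META_LOADFAIL]:
            raise RuntimeError("LEF reloading failed: no free lattice site")
        return int(done)

    def introduce_dsbs(self) -> None:
        if self.broken:
            raise RuntimeError("DSBs already introduced")
        if not len(self.dsb_left):
            raise RuntimeError("layout contains no DSB sites")
        K.introduce_breaks(
            self.dsb_left, self.left, self.right, self.pack, self.flags,
            self.end_sites, self.end_idx, self.end_stack, self.end_stack_n,
            self.meta, self.cons, self.cons_n, self.cons_map,
            self.dsb_state, self.dsb_time, self.initially_constrained)
        self.broken = True
        self.post_dsb_steps = 0

    @property
    def n_active_dsbs(self) -> int:
        return int(self.meta[K.META_ACTIVE])

    def reset_loading_counters(self) -> None:
        self.meta[K.META_LOADS] = 0
        self.meta[K.META_LOADS_END] = 0

    def snapshot(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lef_id": np.arange(self.n_lefs),
                "left": self.left.copy(),
                "right": self.right.copy(),
                "stalled_left": self.stall_l.astype(bool),
                "stalled_right": self.stall_r.astype(bool),
                "longlived": self.longlived.astype(bool),
            }
        )

    def finalize_outcomes(self) -> pd.DataFrame:
        """Per-DSB outcome table; unresolved DSBs are recorded as censored."""
        n = len(self.dsb_left)
        result = np.empty(n, dtype=object)
        time_steps = self.dsb_time.copy()
        for k in range(n):
            s = self.dsb_state[k]
            if s == 1:
                result[k] = "success"
            elif s == 2:
                result[k] = "failure"
            else:
                result[k] = "censored"
                time_steps[k] = self.post_dsb_steps
        step_min = self.config.step_seconds / 60.0
        return pd.DataFrame(
            {
                "dsb_id": np.arange(n),
                "site": self.dsb_left,
                "constrained": self.initially_constrained.astype(bool),
                "result": result,
                "time_steps": time_steps,
                "time_min": time_steps * step_min,
            }
        )


def run_simulation(config: SimConfig, seed: int | None = None,
                   snapshot_minutes_post: tuple = (),
                   keep_pre_snapshot: bool = False) -> SimResult:
    """Burn in, break all DSBs simultaneously, and step until every DSB is
    resolved (or the censoring cap is hit).

    ``snapshot_minutes_post`` requests LEF-position snapshots at the given
    times after DSB introduction (for the simulated ChIP-seq / Hi-C
    observables); a pre-break snapshot is kept when ``keep_pre_snapshot``.
    """
    sim = LatticeSimulation(config, seed=seed)
    sim.step(config.burnin_steps, monitor=False)
    snapshots: dict = {}
    if keep_pre_snapshot:
        snapshots["pre"] = sim.snapshot()
    sim.introduce_dsbs()
    sim.reset_loading_counters()
    steps_per_min = 60.0 / config.step_seconds
    marks = sorted(int(round(m * steps_per_min)) for m in snapshot_minutes_post)
    cap = config.max_post_dsb_steps
    chunk = 4096
    while sim.post_dsb_steps < cap:
        nxt = cap
        for m in marks:
            if m > sim.post_dsb_steps:
                nxt = min(nxt, m)
                break
        n = min(chunk, nxt - sim.post_dsb_steps)
        if n <= 0:
            break
        sim.step(n, monitor=sim.n_active_dsbs > 0)
        for m, minutes in zip(marks, sorted(snapshot_minutes_post)):
            if sim.post_dsb_steps == m and ("post", minutes) not in snapshots:
                snapshots[("post", minutes)] = sim.snapshot()
        if sim.n_active_dsbs == 0 and all(("post", mm) in snapshots for mm in snapshot_minutes_post):
            break
    outcomes = sim.finalize_outcomes()
    return SimResult(config, sim.layout, outcomes, snapshots,
                     int(sim.meta[K.META_LOADS]), int(sim.meta[K.META_LOADS_END]))


def loop_coverage_from_snapshot(snapshot: pd.DataFrame, genome_length_kb: int) -> float:
    """Fraction of the lattice lying strictly inside at least one LEF loop."""
    left = snapshot["left"].to_numpy()
    right = snapshot["right"].to_numpy()
    keep = right > left + 1
    if not keep.any():
        return 0.0
    starts = np.sort(left[keep] + 1)
    ends = (right[keep] - 1) + 1  # half-open
    order = np.argsort(left[keep] + 1)
    ends = ends[order]
    covered = 0
    cur_s, cur_e = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / genome_length_kb
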