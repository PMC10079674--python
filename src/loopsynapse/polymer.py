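"""Reduced-scale 3D bead-spring chromosome with live LEF bonds.

One monomer represents 1 kb (~30 nm); adjacent monomers and the two
monomers held by each LEF are connected by harmonic springs
``U = k/2 (r - b0)^2`` with ``k = 2 kT / delta^2`` (``delta`` = 0.1
monomer); excluded volume is the weak polynomial repulsion

    U_exc(r) = (eps_exc / eps_m) (r sqrt(6/7) / sigma)^12
               ((r sqrt(6/7) / sigma)^2 - 1) + eps_exc      for r < sigma

with ``eps_m = 46656/823543`` and ``eps_exc = 50 kT``, zero beyond
``sigma = 1.05``.  Dynamics are overdamped Langevin steps of 0.014 s
calibrated to the chromatin diffusion coefficient 0.7e-3 um^2/s, inside a
harmonic spherical confinement at 20% volume fraction.

LEF bonds are ported from the 1D lattice engine and refreshed every
``lef_refresh_steps`` (~143) dynamics steps, i.e. one 1D translocation
step per refresh.  A DSB removes the backbone bond between its two end
monomers; synapsis is recorded when the end monomers first come within
the capture radius (4 monomers by default), after a 1-minute lag
(4286 steps) that models repair-factor recruitment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _pkernels as PK
from .config import PolymerConfig, SimConfig, spawn_seeds
from .lattice import LatticeSimulation

__all__ = [
    "bond_energy",
    "excluded_energy",
    "EPS_M",
    "PolymerSystem",
    "run_synapsis_experiment",
]

EPS_M = 46656.0 / 823543.0


def bond_energy(r, k: float = 200.0, b0: float = 1.0):
    """Harmonic bond energy ``k/2 (r - b0)^2`` (kT; r in monomers)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be nonnegative")
    return 0.5 * k * (r - b0) ** 2


def excluded_energy(r, eps: float = 50.0, sigma: float = 1.05):
    """Weak polynomial repulsion; zero at and beyond ``sigma``, ``eps`` at 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be nonnegative")
    x = r * math.sqrt(6.0 / 7.0) / sigma
    u = (eps / EPS_M) * x**12 * (x * x - 1.0) + eps
    return np.where(r < sigma, u, 0.0)


def _compact_lattice_conformation(n: int) -> np.ndarray:
    """Space-filling boustrophedon walk on a cubic lattice, centered at 0."""
    m = int(math.ceil(n ** (1.0 / 3.0)))
    pos = np.empty((n, 3))
    i = 0
    for z in range(m):
        for yy in range(m):
            y = yy if z % 2 == 0 else m - 1 - yy
            for xx in range(m):
                x = xx if yy % 2 == 0 else m - 1 - xx
                if i < n:
                    pos[i] = (x, y, z)
                    i += 1
    return pos - pos.mean(axis=0)


class PolymerSystem:
    """Mutable 3D polymer state advanced in 0.014-s steps."""

    def __init__(self, config: PolymerConfig, seed: int | None = None):
        self.config = config
        seed = config.seed if seed is None else seed
        (kseed,) = (int(s) for s in spawn_seeds(seed, 1, "polymer"))
        self._noise_rng = np.random.default_rng(kseed)
        n = config.n_monomers
        self.pos = _compact_lattice_conformation(n)
        self.backbone_ok = np.ones(n - 1, dtype=np.uint8)
        self.lef_bonds = np.zeros((max(1, n // 2), 2), dtype=np.int64)
        self.n_lef = 0
        self._pairs = np.zeros((n * 24, 2), dtype=np.int32)
        self._forces = np.zeros((n, 3))
        self.steps_done = 0

    def set_lef_bonds(self, bonds: np.ndarray) -> None:
        m = len(bonds)
        if m > self.lef_bonds.shape[0]:
            self.lef_bonds = np.zeros((2 * m, 2), dtype=np.int64)
        self.lef_bonds[:m] = bonds
        self.n_lef = m

    def break_backbone(self, left_end: int) -> None:
        """Sever the bond between monomers ``left_end`` and ``left_end+1``."""
        self.backbone_ok[left_end] = 0

    def advance(self, n_steps: int, mon_pairs=None, capture_radius=None):
        """Advance ``n_steps`` timesteps, optionally monitoring end pairs.

        Returns (steps_done, captured, capture_times) where times are in
        steps since this system's step counter origin.
        """
        c = self.config
        if mon_pairs is None:
            mon_pairs = np.zeros((0, 2), dtype=np.int64)
            captured = np.zeros(0, dtype=np.uint8)
            capture_t = np.zeros(0, dtype=np.int64)
        else:
            mon_pairs = np.asarray(mon_pairs, dtype=np.int64)
            if not hasattr(self, "_captured") or len(self._captured) != len(mon_pairs):
                self._captured = np.zeros(len(mon_pairs), dtype=np.uint8)
                self._capture_t = np.zeros(len(mon_pairs), dtype=np.int64)
            captured = self._captured
            capture_t = self._capture_t
        radius = c.capture_radius if capture_radius is None else capture_radius
        n = c.n_monomers
        block = 16
        remaining = n_steps
        total_done = 0
        while remaining > 0:
            nb = min(block, remaining)
            xi = self._noise_rng.standard_normal((nb * c.substeps, n, 3))
            done, diverged = PK.advance(
                self.pos, self.backbone_ok, self.lef_bonds, self.n_lef,
                nb, c.substeps, c.timestep_s, c.diffusion_monomer2_per_s,
                c.bond_k, 1.0, c.eps_exc_kt, c.sigma,
                c.confinement_k, c.confinement_radius,
                mon_pairs, captured, capture_t, self.steps_done, float(radius),
                self._pairs, self._forces, xi)
            if diverged:
                raise FloatingPointError("polymer dynamics diverged (NaN coordinate)")
            self.steps_done += done
            total_done += done
            remaining -= nb
            if done < nb:   # early exit: every monitored pair captured
                break
        return total_done, captured.copy() if len(captured) else captured, \
            capture_t.copy() if len(capture_t) else capture_t

    def radius_of_gyration(self) -> float:
        d = self.pos - self.pos.mean(axis=0)
        return float(np.sqrt((d**2).sum(axis=1).mean()))


def _lef_bonds_from_sim(sim: LatticeSimulation) -> np.ndarray:
    keep = sim.right > sim.left
    return np.stack([sim.left[keep], sim.right[keep]], axis=1)


def run_synapsis_experiment(config: PolymerConfig, mode: str = "extrusion",
                            sim_config: SimConfig | None = None,
                            seed: int | None = None,
                            horizon_steps: int = 60_000,
                            relax_bonded_steps: int = 400,
                            burnin_1d_steps: int = 10_000) -> pd.DataFrame:
    """Break DSBs on a relaxed chain and record 3D first-passage synapsis.

    Modes: ``extrusion`` (live 1D-coupled LEF bonds), ``frozen_loops``
    (post-DSB, LEFs freeze; only constraining LEFs may unload, without
    reloading), ``diffusion_only`` (no LEF bonds at all).  Times are
    recorded after a 1-minute lag from DSB introduction; DSBs not captured
    within ``horizon_steps`` are censored.
    """
    if mode not in ("extrusion", "frozen_loops", "diffusion_only"):
        raise ValueError(f"unknown mode {mode!r}")
    seed = config.seed if seed is None else seed
    s1d, s3d = (int(x) for x in spawn_seeds(seed, 2, f"polymer3d:{mode}"))
    n = config.n_monomers
    if sim_config is None:
        sim_config = SimConfig(
            genome_length_kb=n, lef_separation_kb=125.0, lef_processivity_kb=250.0,
            boundary_strength=0.5, dsb_spacing_kb=3000,
            be_stabilization_fold=16.0, longlived_fraction=0.2,
            dsb_stabilization_fold=2.0, targeted_loading_fold=1000.0,
            burnin_steps=burnin_1d_steps, seed=s1d)
    sim = LatticeSimulation(sim_config, seed=s1d)
    sim.step(burnin_1d_steps, monitor=False)

    system = PolymerSystem(config, seed=s3d)
    system.advance(config.relax_steps)
    use_bonds = mode != "diffusion_only"
    if use_bonds:
        system.set_lef_bonds(_lef_bonds_from_sim(sim))
        system.advance(relax_bonded_steps)

    # introduce DSBs in 1D and 3D simultaneously
    sim.introduce_dsbs()
    ends = [(int(d.left_end_site), int(d.right_end_site)) for d in sim.layout.dsbs]
    for e, _ in ends:
        system.break_backbone(e)
    mon = np.asarray(ends, dtype=np.int64)

    refresh = config.lef_refresh_steps
    frozen_cons = None
    if mode == "frozen_loops":
        # survivors: constraining LEFs may still unload (no reloading)
        frozen_cons = {}
        for k in range(len(sim.dsb_left)):
            frozen_cons[k] = list(sim.cons[k, : sim.cons_n[k]])
        rng = np.random.default_rng(s3d ^ 0x5EED)

    lag = config.lag_steps
    step_in_run = 0
    # lag phase: dynamics only (bonds still refresh in extrusion mode)
    def run_block(n_steps, monitoring):
        nonlocal step_in_run
        while n_steps > 0:
            chunk = min(refresh, n_steps)
            if monitoring:
                system.advance(chunk, mon_pairs=mon)
            else:
                system.advance(chunk)
            step_in_run += chunk
            n_steps -= chunk
            if mode == "extrusion":
                sim.step(1)
                system.set_lef_bonds(_lef_bonds_from_sim(sim))
            elif mode == "frozen_loops":
                _frozen_unload(sim, frozen_cons, rng)
                system.set_lef_bonds(_frozen_bonds(sim, frozen_cons))
            if monitoring and len(system._captured) and system._captured.all():
                break

    system._captured = np.zeros(len(mon), dtype=np.uint8)
    system._capture_t = np.zeros(len(mon), dtype=np.int64)
    t_origin = system.steps_done
    run_block(lag, monitoring=False)
    run_block(horizon_steps - lag, monitoring=True)

    rows = []
    for q, (e, e2) in enumerate(ends):
        cap = bool(system._captured[q])
        t_steps = int(system._capture_t[q] - t_origin) if cap else horizon_steps
        rows.append(
            {
                "dsb_id": q,
                "site": e,
                "result": "success" if cap else "censored",
                "time_steps": t_steps,
                "time_min": t_steps * config.timestep_s / 60.0,
                "mode": mode,
            }
        )
    return pd.DataFrame(rows)


def _frozen_unload(sim: LatticeSimulation, frozen_cons: dict, rng) -> None:
    """One 1D-step's worth of unloading draws for constraining LEFs only."""
    c = sim.config
    p0 = min(1.0, 2.0 / c.lef_processivity_kb)
    for k, lefs in frozen_cons.items():
        for l in list(lefs):
            f = 1.0
            if sim.longlived[l]:
                f *= c.longlived_fold
            if rng.random() < p0 / f:
                lefs.remove(l)


def _frozen_bonds(sim: LatticeSimulation, frozen_cons: dict) -> np.ndarray:
    alive = set()
    for lefs in frozen_cons.values():
        alive.update(lefs)
    keep = np.ones(sim.n_lefs, dtype=bool)
    # constraining LEFs that unloaded lose their bond; all others stay frozen
    for k in range(len(sim.dsb_left)):
        for l in sim.cons[k, : sim.cons_n[k]]:
            if l not in alive:
                keep[l] = False
    keep &= sim.right > sim.left
    return np.stack([sim.left[keep], sim.right[keep]], axis=1)
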