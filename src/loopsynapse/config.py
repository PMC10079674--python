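"""Run configuration: lattice and polymer parameter sets, presets, YAML parsing.

A :class:`SimConfig` is the single source of truth for a 1D lattice run; a
:class:`PolymerConfig` wraps it for the reduced-scale 3D module.  Seeds are
managed through :func:`spawn_seeds` so that every stochastic stage of a run
draws from its own deterministic stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "SimConfig",
    "PolymerConfig",
    "RunManifest",
    "PRESETS",
    "parse_config",
    "spawn_seeds",
]


@dataclass
class SimConfig:
    """Parameters of a 1D loop-extrusion / DSB-synapsis lattice simulation.

    Lengths are in kb (1 lattice site = 1 kb).  One Monte Carlo step advances
    every unobstructed motor by one site, i.e. 2 kb of total extrusion per LEF
    per step; at the default total extrusion speed of 1 kb/s one step
    corresponds to 2 seconds of real time.
    """

    genome_length_kb: int = 2_164_800
    lef_separation_kb: float = 240.0          # d: genome length / LEF count
    lef_processivity_kb: float = 300.0        # lambda: mean DNA extruded unobstructed
    boundary_strength: float = 0.5            # b: stall probability at a convergent BE
    be_spacing_range_kb: tuple[int, int] = (200, 1200)
    dsb_spacing_kb: int = 10_000
    be_stabilization_fold: float = 1.0        # w: residence fold when a motor is on a BE site
    dsb_stabilization_fold: float = 1.0       # r: residence fold when a motor is on a DSB end
    longlived_fraction: float = 0.0           # alpha0: fraction of long-lived LEFs
    longlived_fold: float = 20.0              # residence fold of long-lived LEFs
    targeted_loading_fold: float = 1.0        # F: loading weight on broken DSB-end sites
    burnin_steps: int = 100_000
    max_post_dsb_steps: int = 1_000_000       # censoring cap after DSB introduction
    extrusion_speed_kb_per_s: float = 1.0     # total speed (0.5 kb/s per motor)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_lefs(self) -> int:
        return int(self.genome_length_kb // self.lef_separation_kb)

    @property
    def step_seconds(self) -> float:
        """Real time represented by one Monte Carlo step (2 kb / total speed)."""
        return 2.0 / self.extrusion_speed_kb_per_s

    def validate(self) -> None:
        errors = []
        if self.genome_length_kb <= 0:
            errors.append("genome_length_kb must be positive")
        if self.lef_processivity_kb <= 0:
            errors.append("lef_processivity_kb must be positive")
        if self.lef_separation_kb <= 0:
            errors.append("lef_separation_kb must be positive")
        if not 0.0 <= self.boundary_strength <= 1.0:
            errors.append("boundary_strength must lie in [0, 1]")
        lo, hi = self.be_spacing_range_kb
        if not (0 < lo <= hi):
            errors.append("be_spacing_range_kb must satisfy 0 < min <= max")
        for name in ("be_stabilization_fold", "dsb_stabilization_fold",
                     "longlived_fold", "targeted_loading_fold"):
            if getattr(self, name) < 1.0:
                errors.append(f"{name} must be >= 1")
        if not 0.0 <= self.longlived_fraction <= 1.0:
            errors.append("longlived_fraction must lie in [0, 1]")
        if self.extrusion_speed_kb_per_s <= 0:
            errors.append("extrusion_speed_kb_per_s must be positive")
        if self.genome_length_kb > 0 and self.lef_separation_kb > 0 and self.n_lefs < 1:
            errors.append("genome must hold at least one LEF (genome_length_kb >= lef_separation_kb)")
        if errors:
            raise ValueError("invalid SimConfig: " + "; ".join(errors))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["be_spacing_range_kb"] = list(self.be_spacing_range_kb)
        return d


@dataclass
class PolymerConfig:
    """Reduced-scale 3D bead-spring chromosome parameters.

    Units: lengths in monomers (1 monomer = 1 kb = 30 nm), time in seconds.
    The diffusion coefficient is the calibrated chromatin value 0.7e-3 um^2/s,
    expressed per monomer^2 (0.03 um per monomer).
    """

    n_monomers: int = 5000
    monomer_size_nm: float = 30.0
    timestep_s: float = 0.014
    substeps: int = 6                       # force substeps per 0.014-s step
                                            # (interior monomers see ~2k spring
                                            # stiffness; mu*2k*dt/6 ~ 0.7 keeps
                                            # explicit integration stable)
    diffusion_um2_per_s: float = 0.7e-3
    bond_delta: float = 0.1                 # spring constant k = 2 kT / delta^2
    sigma: float = 1.05                     # excluded-volume cutoff (monomers)
    eps_exc_kt: float = 50.0
    density: float = 0.20                   # DNA volume fraction in confinement
    confinement_k: float = 5.0              # harmonic penalty outside sphere, kT/monomer^2
    capture_radius: float = 4.0             # monomers; 3 or 5 as variants
    lag_steps: int = 4286                   # 1 min before synapsis monitoring starts
    relax_steps: int = 5000
    lef_refresh_steps: int = 143            # dynamics steps per 1D translocation step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_monomers < 2:
            raise ValueError("n_monomers must be >= 2")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0, 1)")
        if self.capture_radius not in (3.0, 4.0, 5.0):
            raise ValueError("capture_radius must be 3, 4 or 5 monomers")

    @property
    def diffusion_monomer2_per_s(self) -> float:
        size_um = self.monomer_size_nm * 1e-3
        return self.diffusion_um2_per_s / size_um**2

    @property
    def bond_k(self) -> float:
        return 2.0 / self.bond_delta**2

    @property
    def confinement_radius(self) -> float:
        """Sphere radius giving the configured monomer volume fraction."""
        monomer_volume = np.pi / 6.0  # diameter 1
        total = self.n_monomers * monomer_volume / self.density
        return float((3.0 * total / (4.0 * np.pi)) ** (1.0 / 3.0))

    def replace(self, **kwargs) -> "PolymerConfig":
        return dataclasses.replace(self, **kwargs)


# Parameter presets.  "baseline" is the experimentally constrained reference
# dynamics (Fbn2-locus estimates: processivity 300 kb, separation 240 kb,
# boundary strength 0.5, fourfold BE stabilization).  "combined" is the
# minimal combined-mechanism set that achieves >=95% synapsis efficiency
# (16x BE stabilization, 20% long-lived LEFs at 20x, 2x DSB stabilization,
# 1000x targeted loading, processivity/separation ratio 2 at separation 125 kb).
PRESETS: dict[str, dict] = {
    "baseline": dict(
        lef_processivity_kb=300.0,
        lef_separation_kb=240.0,
        boundary_strength=0.5,
        be_stabilization_fold=4.0,
    ),
    "combined": dict(
        lef_processivity_kb=250.0,
        lef_separation_kb=125.0,
        boundary_strength=0.5,
        be_stabilization_fold=16.0,
        longlived_fraction=0.20,
        longlived_fold=20.0,
        dsb_stabilization_fold=2.0,
        targeted_loading_fold=1000.0,
    ),
}


def parse_config(path_or_dict) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file (or a dict).

    An empty file yields all defaults.  A ``preset`` key applies a named
    preset before the remaining keys override it.  Unknown keys raise a
    ``ValueError`` listing the offending names.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path_or_dict!r} must contain a mapping")
    preset = raw.pop("preset", None)
    params: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
        params.update(PRESETS[preset])
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params.update(raw)
    if "be_spacing_range_kb" in params:
        params["be_spacing_range_kb"] = tuple(params["be_spacing_range_kb"])
    return SimConfig(**params)


def spawn_seeds(master_seed: int, n: int, stream: str = "") -> np.ndarray:
    """Derive ``n`` independent 31-bit seeds from a master seed.

    A named stream keeps e.g. replicate seeds independent of placement seeds,
    so changing the replicate count never perturbs earlier draws.
    """
    digest = hashlib.sha256(f"{master_seed}:{stream}".encode()).digest()
    root = int.from_bytes(digest[:4], "little")
    ss = np.random.SeedSequence(root)
    return np.asarray(ss.generate_state(n), dtype=np.uint64) % np.uint64(2**31 - 1)


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI run's outputs."""

    config: dict
    seed: int
    outputs: list[str] = field(default_factory=list)
    wall_seconds: float = 0.0

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "outputs": self.outputs,
                    "wall_seconds": round(self.wall_seconds, 3),
                },
                fh,
                indent=2,
            )
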