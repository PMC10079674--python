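"""Shared fixtures.

Heavy, session-scoped simulation fixtures live here so that the acceptance
tests (reference model, knockouts, enrichment) share runs instead of
re-simulating.  Scales are desk-sized: genomes of a few hundred Mb with
DSBs every 10 Mb, three replicates per condition.
"""

import numpy as np
import pytest

from loopsynapse.config import PRESETS, SimConfig

# desk-scale problem sizes for the session fixtures
KO_GENOME_KB = 400_000          # 40 DSBs per replicate, 3 reps -> 120 events/condition
ENRICH_GENOME_KB = 200_000      # 20 DSBs per replicate


def combined_config(genome_kb=KO_GENOME_KB, **over):
    base = dict(
        genome_length_kb=genome_kb,
        dsb_spacing_kb=10_000,
        burnin_steps=100_000,
        max_post_dsb_steps=200_000,
        seed=1,
    )
    base.update(PRESETS["combined"])
    base.update(over)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def reference_and_knockouts():
    """Combined-mechanism reference and the five single-mechanism knockouts."""
    from loopsynapse.sweep import AXES, _apply_axis, run_point

    base = combined_config()
    out = {"ref": run_point(base, reps=3, stream="ref")}
    for axis in ("w", "alpha0", "F"):
        cfg = _apply_axis(base, axis, AXES[axis][1])
        out[axis] = run_point(cfg, reps=3, stream=f"ko:{axis}")
    # the two mild knockouts enter only the rank-order comparison; a smaller
    # genome (20 DSBs x 2 reps) is enough for their means
    small = combined_config(genome_kb=200_000)
    for axis in ("lam_over_d", "r"):
        cfg = _apply_axis(small, axis, AXES[axis][1])
        out[axis] = run_point(cfg, reps=2, stream=f"ko:{axis}")
    return out


@pytest.fixture(scope="session")
def enrichment_runs():
    """F=250 and F=750 runs with pre/post snapshots for the ChIP observable."""
    from loopsynapse.lattice import run_simulation
    from loopsynapse.config import spawn_seeds

    results = {}
    for F in (250.0, 750.0):
        runs = []
        cfg = SimConfig(
            genome_length_kb=ENRICH_GENOME_KB, dsb_spacing_kb=10_000,
            lef_separation_kb=125.0, lef_processivity_kb=300.0,
            boundary_strength=0.5, targeted_loading_fold=F,
            burnin_steps=100_000, max_post_dsb_steps=20_000, seed=2)
        for s in spawn_seeds(cfg.seed, 3, f"enrich:{F}"):
            runs.append(run_simulation(cfg, seed=int(s),
                                       snapshot_minutes_post=(10.0,),
                                       keep_pre_snapshot=True))
        results[F] = runs
    return results


@pytest.fixture(scope="session")
def polymer_mode_comparison():
    """Synapsis first-passage times, extrusion vs diffusion-only, 5-Mb chain."""
    from loopsynapse.config import PolymerConfig
    from loopsynapse.polymer import run_synapsis_experiment

    horizon = 15_000  # ~3.5 min of real time at 0.014 s/step
    cfg = PolymerConfig(n_monomers=5000, relax_steps=2000, seed=3)
    sim_cfg = combined_config(genome_kb=5000, dsb_spacing_kb=3000,
                              burnin_steps=5000, max_post_dsb_steps=10**6)
    times = {}
    for mode in ("extrusion", "diffusion_only"):
        vals = []
        for rep in range(4):
            out = run_synapsis_experiment(cfg, mode=mode, sim_config=sim_cfg,
                                          seed=50 + rep, horizon_steps=horizon,
                                          burnin_1d_steps=5000)
            vals.extend(out["time_min"].tolist())
        times[mode] = np.asarray(vals)
    return times
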