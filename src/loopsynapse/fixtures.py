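"""Deterministic miniature inputs for tests and examples."""

from __future__ import annotations

import numpy as np

from .config import PolymerConfig, SimConfig
from .genome import GenomeLayout, place_boundaries, place_dsbs

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("toy_tad", "toy_dsb", "toy_polymer")


def make_fixture(kind: str, seed: int = 0):
    """Build a tiny, deterministic test genome or polymer configuration.

    * ``toy_tad``: 5-Mb genome tiled with 10 fixed-size 500-kb TADs.
    * ``toy_dsb``: a single DSB centred in one 500-kb TAD.
    * ``toy_polymer``: a 200-monomer chain configuration.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    if kind == "toy_tad":
        config = SimConfig(genome_length_kb=5000, be_spacing_range_kb=(500, 500),
                           lef_separation_kb=250, lef_processivity_kb=300,
                           burnin_steps=500, dsb_spacing_kb=1000, seed=seed)
        layout = place_boundaries(config, rng)
        place_dsbs(layout, config, rng)
        return config, layout
    if kind == "toy_dsb":
        config = SimConfig(genome_length_kb=500, be_spacing_range_kb=(500, 500),
                           lef_separation_kb=125, lef_processivity_kb=300,
                           burnin_steps=500, dsb_spacing_kb=500, seed=seed)
        layout = place_boundaries(config, rng)
        mid = config.genome_length_kb // 2
        from .genome import DSBSite

        layout.dsbs = [DSBSite(0, mid, mid + 1, layout.tads[0])]
        return config, layout
    config = PolymerConfig(n_monomers=200, relax_steps=200, seed=seed)
    return config, None
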