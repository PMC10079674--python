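"""Genome layout: boundary-element placement, TADs and DSB sites.

Boundary elements (BEs) come in divergently oriented pairs that delimit
TADs.  At a TAD boundary at lattice position ``p`` the site ``p - 1`` carries
a left-facing BE (it stalls rightward-extruding motors arriving from the TAD
on its left) and the site ``p`` carries a right-facing BE (stalling leftward
motors from the TAD on its right).  A DSB occupies two adjacent lattice
sites, one per broken end, placed inside a single TAD and never on a BE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoundaryElement", "DSBSite", "GenomeLayout", "place_boundaries", "place_dsbs"]


@dataclass(frozen=True)
class BoundaryElement:
    site: int
    orientation: str  # "left" stalls rightward-moving motors; "right" stalls leftward
    strength: float


@dataclass
class DSBSite:
    dsb_id: int
    left_end_site: int
    right_end_site: int
    containing_tad: tuple[int, int]
    broken: bool = False

    def __post_init__(self) -> None:
        if self.right_end_site != self.left_end_site + 1:
            raise ValueError("DSB ends must occupy adjacent lattice sites")


@dataclass
class GenomeLayout:
    genome_length_kb: int
    boundaries: np.ndarray          # boundary positions, ascending, first at 0
    boundary_elements: list[BoundaryElement]
    dsbs: list[DSBSite]

    @property
    def tads(self) -> list[tuple[int, int]]:
        """Half-open [start, end) intervals between consecutive boundaries."""
        b = self.boundaries
        out = [(int(b[i]), int(b[i + 1])) for i in range(len(b) - 1)]
        if len(b) and b[-1] < self.genome_length_kb:
            out.append((int(b[-1]), self.genome_length_kb))
        return out

    def be_site_mask(self) -> np.ndarray:
        mask = np.zeros(self.genome_length_kb, dtype=bool)
        for be in self.boundary_elements:
            mask[be.site] = True
        return mask


def place_boundaries(config, rng: np.random.Generator) -> GenomeLayout:
    """Tile the genome with divergent BE pairs.

    Inter-boundary spacing (the TAD size) is drawn uniformly from
    ``config.be_spacing_range_kb``; the first boundary sits at position 0.
    Deterministic under a fixed generator state.
    """
    G = config.genome_length_kb
    lo, hi = config.be_spacing_range_kb
    if G <= 0:
        raise ValueError("cannot place boundary elements on an empty genome")
    if G < lo:
        raise ValueError(
            f"genome of {G} kb is shorter than the minimum BE pair spacing {lo} kb"
        )
    positions = [0]
    while True:
        spacing = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        nxt = positions[-1] + spacing
        if nxt >= G:
            break
        positions.append(nxt)
    boundaries = np.asarray(positions, dtype=np.int64)
    b = config.boundary_strength
    elements: list[BoundaryElement] = []
    for p in positions:
        if p - 1 >= 0:
            elements.append(BoundaryElement(p - 1, "left", b))
        if p < G:
            elements.append(BoundaryElement(p, "right", b))
    return GenomeLayout(G, boundaries, elements, [])


def place_dsbs(layout: GenomeLayout, config, rng: np.random.Generator) -> list[DSBSite]:
    """Place DSB sites roughly every ``dsb_spacing_kb`` along the genome.

    The first DSB is uniform inside the first TAD; each subsequent DSB is
    uniform inside the TAD lying ``dsb_spacing_kb`` to the right of the
    previous one.  Placement stops when the offset falls past the last TAD.
    DSB ends never coincide with BE sites.
    """
    tads = layout.tads
    if not tads:
        raise ValueError("layout has no TADs")
    spacing = config.dsb_spacing_kb
    starts = np.asarray([t[0] for t in tads])

    def tad_of(pos: int):
        idx = int(np.searchsorted(starts, pos, side="right") - 1)
        if idx < 0 or idx >= len(tads):
            return None
        lo, hi = tads[idx]
        return (lo, hi) if lo <= pos < hi else None

    def draw_in_tad(tad) -> int | None:
        lo, hi = tad
        # keep both end sites strictly inside the TAD and off the BE sites:
        # interior sites are lo+1 .. hi-2 (hi-1 is the left-facing BE of the
        # next boundary when one exists); the pair needs e and e+1 free.
        a, b_hi = lo + 1, hi - 3
        if b_hi < a:
            return None
        return int(rng.integers(a, b_hi + 1))

    dsbs: list[DSBSite] = []
    tad = tads[0]
    while True:
        e = draw_in_tad(tad)
        if e is None:
            break
        dsbs.append(DSBSite(len(dsbs), e, e + 1, tad))
        tad = tad_of(e + spacing)
        if tad is None:
            break
        if dsbs and tad[0] <= dsbs[-1].left_end_site:
            break  # spacing shorter than the current TAD: stop rather than stack
    layout.dsbs = dsbs
    return dsbs
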