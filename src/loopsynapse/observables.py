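"""Simulated ChIP-seq tracks and Hi-C-like contact maps from LEF snapshots.

The ChIP-seq analogue counts LEF motor subunits in genomic bins (default
5 kb) and, per DSB-containing TAD, reports the fold enrichment of motor
counts after versus before DSB induction.  The Hi-C analogue computes a
Gaussian-chain contact map around each DSB from the LEF positions alone:
loops collapse the effective backbone distance between two loci, contact
probability decays as (effective distance)^(-3/2), and the map is balanced
by iterative correction (ICE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout

__all__ = [
    "BinnedTrack",
    "ContactMap",
    "chip_track",
    "tad_enrichment",
    "contact_map",
    "ice_balance",
    "write_bedgraph",
    "write_dsb_bed",
]


@dataclass
class BinnedTrack:
    bin_size_kb: int
    starts: np.ndarray            # bin start coordinates (kb)
    counts: np.ndarray            # motor subunits per bin
    normalization: str = "raw"

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _motor_positions(snapshot: pd.DataFrame) -> np.ndarray:
    return np.concatenate([snapshot["left"].to_numpy(), snapshot["right"].to_numpy()])


def chip_track(snapshot: pd.DataFrame, layout: GenomeLayout, bin_kb: int = 5) -> BinnedTrack:
    """Bin LEF motor-subunit counts along the genome (ChIP-seq analogue)."""
    G = layout.genome_length_kb
    n_bins = (G + bin_kb - 1) // bin_kb
    pos = _motor_positions(snapshot)
    counts = np.bincount(pos // bin_kb, minlength=n_bins)
    starts = np.arange(n_bins, dtype=np.int64) * bin_kb
    return BinnedTrack(bin_kb, starts, counts)


def tad_enrichment(pre_snapshots, post_snapshots, layout: GenomeLayout) -> pd.DataFrame:
    """Fold enrichment of motor counts in each DSB-containing TAD.

    ``pre_snapshots`` / ``post_snapshots`` are lists of snapshots taken
    before and after DSB induction; counts are averaged within each group
    and the ratio reported per DSB.  TADs with zero pre-DSB counts yield a
    missing enrichment.
    """
    if not pre_snapshots or not post_snapshots:
        raise ValueError("need at least one pre- and one post-DSB snapshot")

    def mean_counts(snaps, lo, hi):
        vals = []
        for s in snaps:
            pos = _motor_positions(s)
            vals.append(int(((pos >= lo) & (pos < hi)).sum()))
        return float(np.mean(vals))

    rows = []
    for dsb in layout.dsbs:
        lo, hi = dsb.containing_tad
        pre = mean_counts(pre_snapshots, lo, hi)
        post = mean_counts(post_snapshots, lo, hi)
        rows.append(
            {
                "dsb_id": dsb.dsb_id,
                "tad_start": lo,
                "tad_end": hi,
                "pre_count": pre,
                "post_count": post,
                "enrichment": post / pre if pre > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ContactMap:
    matrix: np.ndarray
    bin_kb: int
    window_kb: int
    balanced: bool = False


def _collapsed_coordinate(snapshot: pd.DataFrame, lo: int, hi: int,
                          break_edge: int | None) -> np.ndarray:
    """Backbone coordinate with loop interiors collapsed to zero length.

    For non-crossing loops the shortest backbone path between two loci
    equals the number of edges not inside any loop, so contact probability
    depends only on differences of this coordinate.  If the break edge is
    not covered by a (constraining) loop the two sides are disconnected
    and a large offset pushes cross-break contacts to zero.
    """
    n_edges = hi - lo - 1
    covered = np.zeros(n_edges + 1, dtype=np.int32)
    left = snapshot["left"].to_numpy()
    right = snapshot["right"].to_numpy()
    keep = (right > left) & (right > lo) & (left < hi - 1)
    for l, r in zip(left[keep], right[keep]):
        a = max(l, lo) - lo          # loop (l, r) covers edges l .. r-1
        b = min(r, hi - 1) - lo
        covered[a] += 1
        covered[b] -= 1
    covered = np.cumsum(covered[:-1]) > 0
    w = np.ones(n_edges)
    w[covered] = 0.0
    if break_edge is not None:
        be = break_edge - lo
        if 0 <= be < n_edges and not covered[be]:
            w[be] = 1e12
    u = np.zeros(hi - lo)
    np.cumsum(w, out=u[1:])
    return u


def contact_map(snapshots, layout: GenomeLayout, window_kb: int = 2500,
                bin_kb: int = 25, exponent: float = -1.5,
                broken: bool = True, balance: bool = True) -> ContactMap:
    """Average Gaussian-chain contact map in a +-window around each DSB.

    Only LEFs within the window contribute.  The map is accumulated over
    all snapshots and DSBs on DSB-relative coordinates and optionally
    ICE-balanced.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    if not layout.dsbs:
        raise ValueError("layout contains no DSB sites")
    n_bins = 2 * (window_kb // bin_kb)
    acc = np.zeros((n_bins, n_bins))
    count = 0
    for snap in snapshots:
        for dsb in layout.dsbs:
            e = dsb.left_end_site
            lo = e - window_kb
            hi = e + window_kb
            if lo < 0 or hi > layout.genome_length_kb:
                continue
            u = _collapsed_coordinate(snap, lo, hi, e if broken else None)
            centers = np.arange(n_bins) * bin_kb + bin_kb // 2
            ub = u[centers]
            d = np.abs(ub[:, None] - ub[None, :]) + 1.0
            acc += d ** exponent
            count += 1
    if count == 0:
        raise ValueError("no DSB had a full window inside the genome")
    m = acc / count
    m = 0.5 * (m + m.T)
    if balance:
        m = ice_balance(m)
    return ContactMap(m, bin_kb, window_kb, balanced=balance)


def ice_balance(matrix: np.ndarray, max_iter: int = 50, tol: float = 1e-4) -> np.ndarray:
    """Iterative correction: scale rows/columns until row sums are equal.

    Stops after ``max_iter`` rounds or when the relative variance of the
    row sums drops below ``tol``.
    """
    m = matrix.astype(float).copy()
    for _ in range(max_iter):
        s = m.sum(axis=1)
        s = np.where(s > 0, s, 1.0)
        s = s / s.mean()
        m = m / np.outer(s, s)
        rs = m.sum(axis=1)
        if rs.mean() > 0 and rs.var() / rs.mean() ** 2 < tol:
            break
    return m / m.mean()


def write_bedgraph(track: BinnedTrack, path, chrom: str = "chr1") -> None:
    """Write the track as bedGraph (coordinates in bp: 1 site = 1 kb)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="LEF motor count"\n')
        for s, c in zip(track.starts, track.counts):
            fh.write(f"{chrom}\t{s * 1000}\t{(s + track.bin_size_kb) * 1000}\t{int(c)}\n")


def write_dsb_bed(layout: GenomeLayout, path, chrom: str = "chr1") -> None:
    with open(path, "w") as fh:
        for dsb in layout.dsbs:
            fh.write(f"{chrom}\t{dsb.left_end_site * 1000}\t"
                     f"{(dsb.right_end_site + 1) * 1000}\tdsb_{dsb.dsb_id}\n")
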