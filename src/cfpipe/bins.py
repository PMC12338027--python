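"""Genome tiling into fixed-width bins with GC and usability annotations.

Two tilings are used downstream: 5 Mb bins for the fragmentation-ratio
profile and 0.5 Mb bins for copy-number log2 ratios. A bin is unusable when
the blacklist covers more than a configured fraction of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import MiniGenome

__all__ = ["BinScheme", "tile_genome"]


@dataclass
class BinScheme:
    """An ordered, non-overlapping tiling of the genome.

    ``bins`` holds one row per bin with columns ``chrom``, ``start``,
    ``end``, ``gc`` and ``usable``, in genome order. The last bin of each
    chromosome may be shorter than ``bin_width``.
    """

    bins: pd.DataFrame
    bin_width: int
    _offsets: dict[str, tuple[int, int]] | None = None  # chrom -> (first bin idx, n bins)

    def __post_init__(self) -> None:
        if self._offsets is None:
            offsets: dict[str, tuple[int, int]] = {}
            for chrom, grp in self.bins.groupby("chrom", sort=False):
                offsets[str(chrom)] = (int(grp.index[0]), len(grp))
            self._offsets = offsets

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def usable(self) -> np.ndarray:
        return self.bins["usable"].to_numpy(dtype=bool)

    @property
    def gc(self) -> np.ndarray:
        return self.bins["gc"].to_numpy(dtype=float)

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def feature_names(self, prefix: str) -> list[str]:
        return [
            f"{prefix}_{r.chrom}:{r.start}-{r.end}"
            for r in self.bins.itertuples()
        ]

    def assign(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Map genomic positions to global bin indices (-1 if off-scheme).

        Tiling is uniform-width per chromosome, so the bin index is an
        offset plus ``position // bin_width``.
        """
        out = np.full(len(positions), -1, dtype=np.int64)
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        for chrom, (first, count) in self._offsets.items():
            mask = chroms == chrom
            if not mask.any():
                continue
            idx = positions[mask] // self.bin_width
            ok = (idx >= 0) & (idx < count)
            vals = np.where(ok, first + idx, -1)
            out[mask] = vals
        return out

    def same_scheme(self, other: "BinScheme") -> bool:
        if self.bin_width != other.bin_width or self.n_bins != other.n_bins:
            return False
        a, b = self.bins, other.bins
        return bool(
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        )


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def tile_genome(
    genome: MiniGenome,
    bin_width: int,
    blacklist_max_overlap: float = 0.1,
) -> BinScheme:
    """Tile every chromosome into ``bin_width`` bins, in genome order.

    Per-bin GC is the mean of the genome's GC windows overlapping the bin
    (weighted by overlap). A bin is flagged unusable when blacklisted
    intervals cover more than ``blacklist_max_overlap`` of it.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rows = []
    for chrom, length in genome.chromosomes:
        track = genome.gc_track[chrom]
        win = genome.gc_window
        bl = genome.blacklist_for(chrom)
        n_bins = -(-length // bin_width)
        for b in range(n_bins):
            start = b * bin_width
            end = min(length, start + bin_width)
            w_lo = start // win
            w_hi = -(-end // win)
            weights = np.array(
                [_overlap(start, end, w * win, min(length, (w + 1) * win)) for w in range(w_lo, w_hi)],
                dtype=float,
            )
            gc = float(np.average(track[w_lo:w_hi], weights=weights))
            bl_bp = sum(_overlap(start, end, s, e) for s, e in bl)
            usable = (end > start) and (bl_bp / (end - start) <= blacklist_max_overlap)
            rows.append((chrom, start, end, gc, usable))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "usable"])
    return BinScheme(bins=bins, bin_width=int(bin_width))
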