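"""Miniature reference genomes for desk-scale cfDNA analysis.

A :class:`MiniGenome` bundles everything the feature pipeline needs to know
about a reference: chromosome sizes, a windowed GC track, a blacklist of
excluded intervals, and a catalog of transcription-factor binding sites
(TFBS) with per-site peak points and sample-support scores, mirroring the
shape of GTRD-style meta-cluster BED files.

:func:`make_reference` draws a random but reproducible mini genome so the
whole pipeline runs in minutes without any download.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TfbsSite",
    "TfbsCatalog",
    "MiniGenome",
    "make_reference",
    "write_genome",
    "read_genome",
]


@dataclass(frozen=True)
class TfbsSite:
    """One TF binding site: an interval with the ChIP-signal peak point and
    the number of samples supporting the site (GTRD-style support count)."""

    chrom: str
    start: int
    end: int
    peak_point: int
    support_score: int

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_point < self.end):
            raise ValueError(
                f"peak_point {self.peak_point} outside [{self.start}, {self.end})"
            )
        if self.support_score < 0:
            raise ValueError("support_score must be >= 0")


@dataclass
class TfbsCatalog:
    """Per-TF lists of binding sites."""

    sites: dict[str, list[TfbsSite]] = field(default_factory=dict)

    def tf_names(self) -> list[str]:
        return list(self.sites)

    def n_sites(self, tf: str) -> int:
        return len(self.sites[tf])

    def __len__(self) -> int:
        return len(self.sites)

    def all_sites(self) -> list[TfbsSite]:
        return [s for sites in self.sites.values() for s in sites]


@dataclass
class MiniGenome:
    """A small synthetic reference.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    gc_window
        Width in bp of the fixed windows of ``gc_track``.
    gc_track
        Per-chromosome arrays of GC fraction in [0, 1], one value per
        ``gc_window``-sized window (last window may be short).
    blacklist
        Half-open ``(chrom, start, end)`` intervals excluded from binned
        analyses, in the spirit of the Duke/ENCODE blacklist.
    tfbs_catalog
        TF binding-site catalog.
    """

    chromosomes: list[tuple[str, int]]
    gc_window: int
    gc_track: dict[str, np.ndarray]
    blacklist: list[tuple[str, int, int]]
    tfbs_catalog: TfbsCatalog

    def __post_init__(self) -> None:
        sizes = self.sizes()
        if not sizes:
            raise ValueError("genome must have at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for chrom, start, end in self.blacklist:
            if chrom not in sizes or not (0 <= start < end <= sizes[chrom]):
                raise ValueError(f"blacklist interval {(chrom, start, end)} out of bounds")
        for tf, sites in self.tfbs_catalog.sites.items():
            for s in sites:
                if s.chrom not in sizes or not (0 <= s.start < s.end <= sizes[s.chrom]):
                    raise ValueError(f"TFBS {tf}:{(s.chrom, s.start, s.end)} out of bounds")
        for chrom, track in self.gc_track.items():
            if np.any((track < 0) | (track > 1)):
                raise ValueError(f"gc_track for {chrom} outside [0, 1]")

    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def blacklist_for(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.blacklist if c == chrom]


def _random_gc_track(length: int, window: int, rng: np.random.Generator) -> np.ndarray:
    n_win = -(-length // window)
    steps = rng.normal(0.0, 0.012, size=n_win)
    track = 0.5 + np.cumsum(steps)
    return np.clip(track, 0.3, 0.7)


def _place_blacklist(
    length: int, target_fraction: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    if target_fraction <= 0:
        return []
    interval_len = max(1, min(200_000, int(length * target_fraction / 4) or 1))
    intervals: list[tuple[int, int]] = []
    covered = 0
    attempts = 0
    while covered < target_fraction * length and attempts < 10_000:
        attempts += 1
        start = int(rng.integers(0, max(1, length - interval_len)))
        end = min(length, start + interval_len)
        if any(s < end and start < e for s, e in intervals):
            continue
        intervals.append((start, end))
        covered += end - start
    return sorted(intervals)


def make_reference(
    n_chrom: int = 2,
    chrom_length: int = 50_000_000,
    gc_window: int = 50_000,
    n_tfs: int = 3,
    sites_per_tf: int = 120,
    seed: int = 0,
    blacklist_fraction: float = 0.02,
    site_width: int = 200,
) -> MiniGenome:
    """Draw a reproducible mini reference genome.

    GC content follows a smooth random walk clipped to [0.3, 0.7]; blacklist
    intervals cover roughly ``blacklist_fraction`` of each chromosome; TFBS
    are placed uniformly outside the blacklist, each with a random
    sample-support score.
    """
    if n_chrom <= 0 or chrom_length <= 0 or gc_window <= 0 or n_tfs < 0:
        raise ValueError("sizes must be positive")
    if chrom_length < 10 * gc_window:
        raise ValueError("chrom_length must be at least 10x gc_window")
    if n_tfs > 0 and sites_per_tf < 1:
        raise ValueError("sites_per_tf must be >= 1")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))
    chromosomes = [(f"chr{i + 1}", int(chrom_length)) for i in range(n_chrom)]
    gc_track = {name: _random_gc_track(length, gc_window, rng) for name, length in chromosomes}
    blacklist = [
        (name, s, e)
        for name, length in chromosomes
        for s, e in _place_blacklist(length, blacklist_fraction, rng)
    ]

    catalog = TfbsCatalog()
    bl_by_chrom = {name: [(s, e) for c, s, e in blacklist if c == name] for name, _ in chromosomes}
    for t in range(n_tfs):
        tf = f"TF{t + 1}"
        sites: list[TfbsSite] = []
        while len(sites) < sites_per_tf:
            ci = int(rng.integers(0, n_chrom))
            name, length = chromosomes[ci]
            start = int(rng.integers(0, length - site_width))
            end = start + site_width
            if any(s < end and start < e for s, e in bl_by_chrom[name]):
                continue
            peak = start + int(rng.integers(0, site_width))
            support = int(rng.integers(1, 500))
            sites.append(TfbsSite(name, start, end, peak, support))
        catalog.sites[tf] = sites

    return MiniGenome(chromosomes, int(gc_window), gc_track, blacklist, catalog)


# ---------------------------------------------------------------------------
# plain-text on-disk layout: chrom.sizes TSV, GC bedGraph, blacklist BED,
# and one BED-like file per TF (chrom, start, end, peak_point, support_score)


def write_genome(genome: MiniGenome, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "chrom.sizes"), "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")
    with open(os.path.join(out_dir, "gc.bedgraph"), "w") as fh:
        fh.write(f"#gc_window={genome.gc_window}\n")
        for name, length in genome.chromosomes:
            track = genome.gc_track[name]
            for i, gc in enumerate(track):
                s = i * genome.gc_window
                e = min(length, s + genome.gc_window)
                fh.write(f"{name}\t{s}\t{e}\t{gc:.6f}\n")
    with open(os.path.join(out_dir, "blacklist.bed"), "w") as fh:
        for chrom, s, e in genome.blacklist:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    tf_dir = os.path.join(out_dir, "tfbs")
    os.makedirs(tf_dir, exist_ok=True)
    for tf, sites in genome.tfbs_catalog.sites.items():
        with open(os.path.join(tf_dir, f"{tf}.bed"), "w") as fh:
            for s in sites:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.peak_point}\t{s.support_score}\n")


def read_tfbs_catalog(tf_dir: str) -> TfbsCatalog:
    """Load a directory of per-TF BED-like files (GTRD meta-cluster shape)."""
    catalog = TfbsCatalog()
    for fname in sorted(os.listdir(tf_dir)):
        if not fname.endswith(".bed"):
            continue
        tf = fname[:-4]
        df = pd.read_csv(
            os.path.join(tf_dir, fname),
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "peak_point", "support_score"],
        )
        catalog.sites[tf] = [
            TfbsSite(str(r.chrom), int(r.start), int(r.end), int(r.peak_point), int(r.support_score))
            for r in df.itertuples()
        ]
    return catalog


def read_genome(in_dir: str) -> MiniGenome:
    sizes = pd.read_csv(
        os.path.join(in_dir, "chrom.sizes"), sep="\t", header=None, names=["chrom", "length"]
    )
    chromosomes = [(str(r.chrom), int(r.length)) for r in sizes.itertuples()]
    with open(os.path.join(in_dir, "gc.bedgraph")) as fh:
        header = fh.readline().strip()
        gc_window = int(header.split("=", 1)[1])
        gc = pd.read_csv(fh, sep="\t", header=None, names=["chrom", "start", "end", "gc"])
    gc_track = {
        name: grp.sort_values("start")["gc"].to_numpy(dtype=float)
        for name, grp in gc.groupby("chrom", sort=False)
    }
    bl_path = os.path.join(in_dir, "blacklist.bed")
    blacklist: list[tuple[str, int, int]] = []
    if os.path.getsize(bl_path) > 0:
        bl = pd.read_csv(bl_path, sep="\t", header=None, names=["chrom", "start", "end"])
        blacklist = [(str(r.chrom), int(r.start), int(r.end)) for r in bl.itertuples()]
    catalog = read_tfbs_catalog(os.path.join(in_dir, "tfbs"))
    return MiniGenome(chromosomes, gc_window, gc_track, blacklist, catalog)
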