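"""Coverage footprints around transcription-factor binding sites.

TF-bound DNA is protected from nuclease digestion, so cfDNA coverage dips
around occupied binding sites. For each TF passing a minimum-site filter,
the top-k sites by sample support are recentered at their ChIP-signal peak
and the mean fragment coverage is profiled over +/- 1000 bp, normalized by
the subject's genome-wide average depth and the local copy-number state,
then reduced to three scalars: central mean, flank mean, and their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnv import CnvProfile
from .genome import TfbsCatalog, TfbsSite
from .io import FeatureBlock

__all__ = [
    "select_tfs",
    "select_top_sites",
    "coverage_profile",
    "TfbsProfile",
    "normalize_profile",
    "tfbs_features",
    "mean_coverage_depth",
    "tfbs_feature_block",
]


def select_tfs(catalog: TfbsCatalog, min_sites: int = 1000) -> TfbsCatalog:
    """Keep TFs with strictly more than ``min_sites`` binding sites."""
    kept = {tf: sites for tf, sites in catalog.sites.items() if len(sites) > min_sites}
    if not kept:
        raise ValueError(
            f"no TF has more than {min_sites} sites; lower min_sites "
            "(mini genomes host far fewer sites than a full reference)"
        )
    return TfbsCatalog(sites=kept)


def select_top_sites(sites: list[TfbsSite], k: int = 1000) -> list[TfbsSite]:
    """The ``min(k, n)`` sites with highest sample support ("msTFBS"
    selection). Ties break by genome order of the peak point."""
    if not sites:
        raise ValueError("no sites to select from")
    ranked = sorted(sites, key=lambda s: (-s.support_score, s.chrom, s.peak_point))
    return ranked[: min(k, len(ranked))]


def coverage_profile(
    frags: pd.DataFrame,
    sites: list[TfbsSite],
    flank: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
    max_fragment_length: int = 1000,
) -> tuple[np.ndarray, int]:
    """Raw mean fragment coverage per position relative to site peaks.

    For each relative position p in [-flank, +flank], depth(p) is the mean
    over sites of the number of fragments overlapping ``peak + p``. Sites
    truncated by a chromosome edge contribute only their defined positions
    (the per-position denominator shrinks accordingly). Returns the
    ``2 * flank + 1`` profile and the number of sites used.
    """
    if not sites:
        raise ValueError("no usable sites")
    width = 2 * flank + 1
    depth = np.zeros(width, dtype=float)
    n_defined = np.zeros(width, dtype=float)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in frags.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        by_chrom[str(chrom)] = (starts[order], ends[order])

    for site in sites:
        lo = site.peak_point - flank
        hi = site.peak_point + flank  # inclusive
        c_lo, c_hi = lo, hi
        if chrom_sizes is not None:
            size = chrom_sizes.get(site.chrom)
            if size is not None:
                c_lo = max(lo, 0)
                c_hi = min(hi, size - 1)
        if c_hi < c_lo:
            continue
        n_defined[c_lo - lo : c_hi - lo + 1] += 1.0
        if site.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[site.chrom]
        i0 = np.searchsorted(starts, c_lo - max_fragment_length, side="left")
        i1 = np.searchsorted(starts, c_hi, side="right")
        s = starts[i0:i1]
        e = ends[i0:i1]
        near = e > c_lo
        s, e = s[near], e[near]
        if s.size == 0:
            continue
        a = np.clip(s, c_lo, c_hi + 1) - lo
        b = np.clip(e, c_lo, c_hi + 1) - lo
        np.add.at(depth, a, 1.0)
        ends_acc = np.zeros(width + 1)
        np.add.at(ends_acc, b, 1.0)
        depth -= ends_acc[:width]
    # depth currently holds per-position "starts minus ends" deltas summed
    # over sites; cumulative sum yields coverage counts
    profile = np.cumsum(depth)
    if np.all(n_defined == 0):
        raise ValueError("no usable sites")
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(n_defined > 0, profile / np.maximum(n_defined, 1), 0.0)
    return profile, int(max(n_defined))


def mean_coverage_depth(frags: pd.DataFrame, genome_length: int) -> float:
    """Genome-wide expected coverage depth: total fragment bases divided by
    genome length (fragments per bp overlapping a random position)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    lengths = (frags["end"] - frags["start"]).to_numpy(dtype=np.int64)
    return float(lengths.sum() / genome_length)


@dataclass
class TfbsProfile:
    """Normalized coverage around one TF's sites; ~1 away from footprints
    for a copy-neutral subject."""

    tf_name: str
    positions: np.ndarray  # -flank .. +flank
    depth: np.ndarray
    n_sites_used: int

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.depth):
            raise ValueError("positions and depth must align")
        if np.any(self.depth < 0):
            raise ValueError("depth must be nonnegative")


def normalize_profile(
    raw: np.ndarray,
    tf_name: str,
    n_sites_used: int,
    mean_depth: float,
    sites: list[TfbsSite] | None = None,
    cnv: CnvProfile | None = None,
    flank: int = 1000,
) -> TfbsProfile:
    """Divide the raw profile by the subject's average depth and, when a CNV
    profile is supplied, by the mean local copy-state multiplier
    ``2^log2ratio`` of the bins containing the used sites."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    factor = mean_depth
    if cnv is not None and sites:
        local = np.array(
            [cnv.bin_log2_at(s.chrom, s.peak_point) for s in sites], dtype=float
        )
        local = np.where(np.isfinite(local), local, 0.0)  # off-scheme bins: neutral
        factor *= float(np.mean(2.0 ** local))
    positions = np.arange(-flank, flank + 1)
    return TfbsProfile(
        tf_name=tf_name,
        positions=positions,
        depth=np.asarray(raw, dtype=float) / factor,
        n_sites_used=n_sites_used,
    )


def tfbs_features(
    profile: TfbsProfile,
    central_halfwidth: int = 150,
    flank_range: tuple[int, int] = (750, 1000),
) -> dict[str, float]:
    """Reduce a profile to (central mean, flank mean, central/flank ratio).

    Central positions satisfy ``|p| <= central_halfwidth``; flank positions
    ``flank_range[0] <= |p| <= flank_range[1]``, far enough out to sit past
    the footprint.
    """
    p = profile.positions
    central = np.abs(p) <= central_halfwidth
    flank = (np.abs(p) >= flank_range[0]) & (np.abs(p) <= flank_range[1])
    central_mean = float(profile.depth[central].mean())
    flank_mean = float(profile.depth[flank].mean())
    # zero flank coverage leaves the ratio undefined; impute the neutral
    # value so sparse subjects still yield a complete feature block
    ratio = central_mean / flank_mean if flank_mean > 0 else 1.0
    tf = profile.tf_name
    return {
        f"{tf}_central_mean": central_mean,
        f"{tf}_flank_mean": flank_mean,
        f"{tf}_central_flank_ratio": ratio,
    }


def tfbs_feature_block(
    frags: pd.DataFrame,
    catalog: TfbsCatalog,
    genome_length: int,
    chrom_sizes: dict[str, int] | None = None,
    cnv: CnvProfile | None = None,
    min_sites: int = 1000,
    top_k: int = 1000,
    flank: int = 1000,
    central_halfwidth: int = 150,
    subject: str = "sample",
) -> FeatureBlock:
    """Full TFBS feature dimension for one subject: filter TFs, take the
    top-support sites, profile, normalize, and reduce to scalars."""
    selected = select_tfs(catalog, min_sites=min_sites)
    depth = mean_coverage_depth(frags, genome_length)
    names: list[str] = []
    values: list[float] = []
    for tf in sorted(selected.sites):
        sites = select_top_sites(selected.sites[tf], k=top_k)
        raw, n_used = coverage_profile(frags, sites, flank=flank, chrom_sizes=chrom_sizes)
        prof = normalize_profile(raw, tf, n_used, depth, sites=sites, cnv=cnv, flank=flank)
        feats = tfbs_features(prof, central_halfwidth=central_halfwidth)
        for k_, v in feats.items():
            names.append(k_)
            values.append(v)
    return FeatureBlock(
        block_name="tfbs",
        feature_names=names,
        values=np.asarray(values, dtype=float)[None, :],
        subjects=[subject],
    )
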