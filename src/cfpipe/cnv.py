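"""Bin-level copy-number log2 ratios from low-pass WGS fragment counts.

Fragments are counted in 0.5 Mb bins, corrected for GC bias with a locally
weighted (LOWESS) fit of count on bin GC, normalized to median 1, and
compared against a healthy-reference baseline as per-bin log2 ratios:
0 means copy-neutral, log2((2 + t) / 2) is the expectation over a clonal
one-copy gain at tumor fraction t.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .bins import BinScheme
from .io import FeatureBlock

logger = logging.getLogger(__name__)

__all__ = [
    "bin_counts",
    "gc_correct",
    "Baseline",
    "build_baseline",
    "log2_ratio",
    "CnvProfile",
    "cnv_profile",
    "estimate_tumor_fraction",
]


def bin_counts(frags: pd.DataFrame, scheme: BinScheme) -> np.ndarray:
    """Fragment midpoints counted per bin; unusable bins are NaN."""
    n = scheme.n_bins
    if len(frags) == 0:
        counts = np.zeros(n, dtype=float)
    else:
        starts = frags["start"].to_numpy(dtype=np.int64)
        ends = frags["end"].to_numpy(dtype=np.int64)
        mids = (starts + ends) // 2
        idx = scheme.assign(frags["chrom"].to_numpy(), mids)
        counts = np.bincount(idx[idx >= 0], minlength=n).astype(float)
    counts[~scheme.usable] = np.nan
    return counts


def gc_correct(
    counts: np.ndarray,
    gc: np.ndarray,
    span: float = 0.3,
    floor_frac: float = 1e-3,
) -> np.ndarray:
    """GC-correct and normalize per-bin counts.

    A LOWESS curve of count on GC (span = fraction of bins in each local
    fit) estimates the GC bias; each bin is divided by the fitted value
    (floored at ``floor_frac`` x its median to avoid blow-ups) and the
    result rescaled so the median over usable bins is 1. Scale-invariant:
    multiplying all counts by a constant leaves the output unchanged.

    NaN entries (unusable bins) stay NaN. With degenerate GC (all equal)
    the correction is skipped and counts are simply median-normalized.
    """
    counts = np.asarray(counts, dtype=float)
    gc = np.asarray(gc, dtype=float)
    usable = ~np.isnan(counts)
    if usable.sum() < 20:
        raise ValueError("need at least 20 usable bins for GC correction")
    if np.any(counts[usable] < 0):
        raise ValueError("counts must be nonnegative")
    x = gc[usable]
    y = counts[usable]
    corrected = np.full_like(counts, np.nan)
    if np.ptp(x) < 1e-9:
        warnings.warn("degenerate GC track; skipping GC correction", stacklevel=2)
        fit = np.full(y.shape, np.median(y))
    else:
        with warnings.catch_warnings():
            # statsmodels' robust iterations emit spurious divide warnings
            # on sparse counts; the returned fit is still finite there
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = lowess(y, x, frac=span, return_sorted=False)
        if not np.isfinite(fit).all():
            fit = np.where(np.isfinite(fit), fit, np.median(y))
    floor = floor_frac * max(np.median(fit), np.finfo(float).tiny)
    corrected[usable] = y / np.maximum(fit, floor)
    med = np.nanmedian(corrected)
    if med <= 0:
        raise ValueError("median corrected depth is non-positive")
    return corrected / med


@dataclass
class Baseline:
    """Per-bin median corrected depth across a healthy reference cohort."""

    scheme: BinScheme
    median_depth: np.ndarray
    n_reference: int
    usable: np.ndarray  # bins with a strictly positive, defined median

    def __post_init__(self) -> None:
        self.median_depth = np.asarray(self.median_depth, dtype=float)
        if len(self.median_depth) != self.scheme.n_bins:
            raise ValueError("baseline length does not match scheme")


def build_baseline(
    reference: list[np.ndarray], scheme: BinScheme, floor: float = 1e-3
) -> Baseline:
    """Median of >= 3 corrected-depth vectors on the same scheme."""
    if len(reference) < 3:
        raise ValueError("baseline requires at least 3 reference subjects")
    for v in reference:
        if len(v) != scheme.n_bins:
            raise ValueError("reference vector does not match the bin scheme")
    stack = np.vstack(reference)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        med = np.nanmedian(stack, axis=0)
    usable = scheme.usable & np.isfinite(med) & (med > floor)
    return Baseline(scheme=scheme, median_depth=med, n_reference=len(reference), usable=usable)


def log2_ratio(sample: np.ndarray, baseline: Baseline) -> np.ndarray:
    """Per-bin ``log2(sample / baseline median)``; NaN where either side is
    unusable or the sample depth is non-positive (counted in the log)."""
    sample = np.asarray(sample, dtype=float)
    if len(sample) != baseline.scheme.n_bins:
        raise ValueError("sample vector does not match the baseline scheme")
    out = np.full_like(sample, np.nan)
    ok = baseline.usable & np.isfinite(sample) & (sample > 0)
    out[ok] = np.log2(sample[ok] / baseline.median_depth[ok])
    n_dropped = int(baseline.usable.sum() - ok.sum())
    if n_dropped:
        logger.info("log2_ratio: %d usable bins had non-positive sample depth", n_dropped)
    return out


@dataclass
class CnvProfile:
    """Raw counts, corrected depth and log2 ratios for one subject."""

    scheme: BinScheme
    raw_counts: np.ndarray
    corrected: np.ndarray
    log2: np.ndarray

    def feature_block(self, subject: str = "sample", impute: float = 0.0) -> FeatureBlock:
        values = np.where(np.isfinite(self.log2), self.log2, impute)
        return FeatureBlock(
            block_name="cnv",
            feature_names=self.scheme.feature_names("log2"),
            values=values[None, :],
            subjects=[subject],
        )

    def bin_log2_at(self, chrom: str, position: int) -> float:
        """log2 ratio of the bin containing a genomic position (NaN if
        off-scheme or unusable)."""
        idx = self.scheme.assign(np.array([chrom], dtype=object), np.array([position]))[0]
        return float(self.log2[idx]) if idx >= 0 else float("nan")


def cnv_profile(
    frags: pd.DataFrame,
    scheme: BinScheme,
    baseline: Baseline,
    span: float = 0.3,
) -> CnvProfile:
    counts = bin_counts(frags, scheme)
    corrected = gc_correct(counts, scheme.gc, span=span)
    return CnvProfile(
        scheme=scheme,
        raw_counts=counts,
        corrected=corrected,
        log2=log2_ratio(corrected, baseline),
    )


def estimate_tumor_fraction(mean_log2: float, copy_state: int) -> float:
    """Invert the clonal-mixture depth model on a known segment.

    A segment at integer copy number ``c`` in a tumor of fraction ``t``
    mixed with diploid background has relative depth
    ``m = (2 (1 - t) + c t) / 2``, so from the segment-mean log2 ratio ``r``:
    ``t = (2^(r+1) - 2) / (c - 2)``. ``c = 2`` is degenerate (no signal).
    """
    if copy_state == 2:
        raise ValueError("a copy-neutral segment carries no tumor-fraction information")
    t = (2.0 ** (mean_log2 + 1.0) - 2.0) / (copy_state - 2.0)
    return float(np.clip(t, 0.0, 1.0))
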