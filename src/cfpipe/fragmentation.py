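"""DELFI-style fragmentation-ratio profiles.

Short cfDNA fragments (100-150 bp) are enriched for tumor-derived
molecules; long fragments (151-220 bp) reflect the background
mononucleosomal population. The per-bin ratio of short to long counts in
large (5 Mb) bins, centered on its genome-wide mean, is the fragmentation
feature vector.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bins import BinScheme
from .io import FeatureBlock

__all__ = [
    "SHORT_RANGE",
    "LONG_RANGE",
    "classify_length",
    "fragmentation_profile",
    "center_profile",
]

# canonical fragment-length classes (bp, both ends inclusive)
SHORT_RANGE = (100, 150)
LONG_RANGE = (151, 220)


def classify_length(
    length: int,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
) -> str:
    """Classify a fragment length as ``short``, ``long`` or ``neither``."""
    if length <= 0:
        raise ValueError("length must be positive")
    if short_range[0] <= length <= short_range[1]:
        return "short"
    if long_range[0] <= length <= long_range[1]:
        return "long"
    return "neither"


def _bin_class_counts(
    frags: pd.DataFrame,
    scheme: BinScheme,
    short_range: tuple[int, int],
    long_range: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    starts = frags["start"].to_numpy(dtype=np.int64)
    ends = frags["end"].to_numpy(dtype=np.int64)
    mids = (starts + ends) // 2
    lengths = ends - starts
    idx = scheme.assign(frags["chrom"].to_numpy(), mids)
    in_scheme = idx >= 0
    short = (lengths >= short_range[0]) & (lengths <= short_range[1])
    long_ = (lengths >= long_range[0]) & (lengths <= long_range[1])
    n = scheme.n_bins
    short_counts = np.bincount(idx[in_scheme & short], minlength=n).astype(float)
    long_counts = np.bincount(idx[in_scheme & long_], minlength=n).astype(float)
    return short_counts, long_counts


def fragmentation_profile(
    frags: pd.DataFrame,
    scheme: BinScheme,
    eps: float = 0.5,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
    subject: str = "sample",
) -> FeatureBlock:
    """Per-usable-bin short/long fragment-count ratio for one subject.

    A fragment is assigned to the bin containing its midpoint. The ratio is
    the Haldane-Anscombe smoothed ``(short + eps) / (long + eps)`` so sparse
    bins stay finite; ``eps=0`` recovers the raw ratio.
    """
    if len(frags) == 0:
        raise ValueError("cannot form a fragmentation profile without fragments")
    if scheme.n_usable < 1:
        raise ValueError("bin scheme has no usable bins")
    short_counts, long_counts = _bin_class_counts(frags, scheme, short_range, long_range)
    usable = scheme.usable
    ratios = (short_counts[usable] + eps) / (long_counts[usable] + eps)
    names = [n for n, u in zip(scheme.feature_names("ratio"), usable) if u]
    return FeatureBlock(
        block_name="fragmentation",
        feature_names=names,
        values=ratios[None, :],
        subjects=[subject],
    )


def center_profile(block: FeatureBlock) -> FeatureBlock:
    """Subtract each subject's mean ratio across bins (the quantity usually
    plotted: deviation from the genome-wide average). Idempotent; centered
    rows sum to zero."""
    if block.n_features == 0:
        raise ValueError("empty profile")
    centered = block.values - block.values.mean(axis=1, keepdims=True)
    return FeatureBlock(
        block_name=block.block_name,
        feature_names=list(block.feature_names),
        values=centered,
        subjects=list(block.subjects),
    )
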