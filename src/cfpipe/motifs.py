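"""5' end-motif spectra.

The first four sequenced bases of each cfDNA fragment (the R1 5' end)
reflect the nuclease cleavage preferences of the tissue of origin. Each
subject is summarised by the proportions of the 4^4 = 256 possible 4-mers,
in fixed lexicographic order (A < C < G < T).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .io import FeatureBlock

__all__ = ["MOTIFS", "MOTIF_INDEX", "enumerate_motifs", "MotifSpectrum", "motif_spectrum", "spectrum_table"]


def enumerate_motifs() -> list[str]:
    """All 256 4-mers over {A, C, G, T} in lexicographic order."""
    return ["".join(p) for p in product("ACGT", repeat=4)]


MOTIFS: list[str] = enumerate_motifs()
MOTIF_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOTIFS)}


@dataclass
class MotifSpectrum:
    """Proportions of the 256 end motifs for one subject."""

    proportions: np.ndarray
    n_counted: int
    n_excluded: int = 0  # fragments whose 4-mer contained N

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (256,):
            raise ValueError("spectrum must have exactly 256 entries")
        if self.n_counted <= 0:
            raise ValueError("spectrum requires at least one counted fragment")
        if np.any(self.proportions < 0) or abs(self.proportions.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must be nonnegative and sum to 1")

    def to_block(self, subject: str = "sample") -> FeatureBlock:
        return FeatureBlock(
            block_name="motif",
            feature_names=list(MOTIFS),
            values=self.proportions[None, :],
            subjects=[subject],
        )


def motif_spectrum(frags: pd.DataFrame) -> MotifSpectrum:
    """Count the stored 5' 4-mer of every fragment.

    Motifs containing N carry no information and are excluded (tallied in
    ``n_excluded``); an input where every motif contains N is an error.
    """
    idx = frags["motif4"].map(MOTIF_INDEX)
    valid = idx.notna()
    n_excluded = int((~valid).sum())
    kept = idx[valid].to_numpy(dtype=np.int64)
    if kept.size == 0:
        raise ValueError("no fragment has an N-free 4-mer; cannot form a motif spectrum")
    counts = np.bincount(kept, minlength=256).astype(float)
    return MotifSpectrum(
        proportions=counts / counts.sum(),
        n_counted=int(kept.size),
        n_excluded=n_excluded,
    )


def spectrum_table(
    cohorts: dict[str, list[MotifSpectrum]], top_k: int = 10
) -> pd.DataFrame:
    """Per-cohort mean proportions of the ``top_k`` motifs overall.

    Motifs are ranked by their grand-mean proportion over all subjects of
    all cohorts; ties break lexicographically. Rows are motifs (in rank
    order), columns are cohort labels.
    """
    if top_k > 256:
        raise ValueError("top_k cannot exceed 256")
    if not cohorts or any(len(v) == 0 for v in cohorts.values()):
        raise ValueError("every cohort needs at least one spectrum")
    all_props = np.vstack(
        [s.proportions for specs in cohorts.values() for s in specs]
    )
    grand_mean = all_props.mean(axis=0)
    # stable sort on lexicographic index, then stable sort by -mean -> ties lexicographic
    order = np.argsort(-grand_mean, kind="stable")[:top_k]
    data = {
        label: np.vstack([s.proportions for s in specs]).mean(axis=0)[order]
        for label, specs in cohorts.items()
    }
    return pd.DataFrame(data, index=[MOTIFS[i] for i in order])
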