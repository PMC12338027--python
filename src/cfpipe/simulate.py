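"""Synthetic cfDNA cohort generator.

Generates labeled cohorts of aligned-fragment sets carrying the four signal
dimensions the feature pipeline measures:

* fragment length: a two-component (short / long) Gaussian mixture whose
  weights shift between cohorts (tumor-derived cfDNA is shorter);
* 5' end motifs: a 256-weight multinomial over 4-mers, with cohort-specific
  tilts (e.g. C-rich motifs depleted in cancer);
* copy number: fragment positions are drawn with density proportional to
  the clonal-mixture multiplier m = (2 (1 - t) + c t) / 2 on segments of
  copy state c at tumor fraction t;
* TFBS footprints: fragments whose midpoint falls near a binding-site peak
  are thinned by 1 - d * k(x), where k is a triangular kernel of half-width
  150 bp and d the cohort's dip depth.

All draws are reproducible: each subject's RNG is seeded from
(cohort seed, subject index) via numpy's SeedSequence, so cohorts can be
generated independently and in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genome import MiniGenome
from .io import FRAGMENT_COLUMNS
from .motifs import MOTIFS

__all__ = [
    "LengthMixture",
    "CohortSpec",
    "simulate_subject",
    "SimulatedCohorts",
    "simulate_cohorts",
    "triangular_kernel",
    "expected_relative_depth",
    "expected_central_flank_ratio",
]

KERNEL_HALFWIDTH = 150  # bp, half-width of the TFBS protection kernel

_MOTIF_ARRAY = np.array(MOTIFS)


@dataclass
class LengthMixture:
    """Two-component Gaussian fragment-length mixture (bp).

    ``w_short`` is the weight of the short component; lengths are rounded
    to integers and clipped to ``support``.
    """

    w_short: float = 0.25
    short_loc: float = 133.0
    short_scale: float = 12.0
    long_loc: float = 168.0
    long_scale: float = 16.0
    support: tuple[int, int] = (50, 400)

    def __post_init__(self) -> None:
        if not 0 <= self.w_short <= 1:
            raise ValueError("w_short must lie in [0, 1]")
        if self.short_scale <= 0 or self.long_scale <= 0:
            raise ValueError("scales must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        is_short = rng.random(n) < self.w_short
        lengths = np.where(
            is_short,
            rng.normal(self.short_loc, self.short_scale, n),
            rng.normal(self.long_loc, self.long_scale, n),
        )
        return np.clip(np.rint(lengths), *self.support).astype(np.int64)

    def prob_in(self, lo: int, hi: int) -> float:
        """P(rounded, clipped length in [lo, hi]), exact from the normal CDF
        (interior ranges only; clipping piles mass on the support ends)."""
        s_lo, s_hi = self.support
        lo_eff, hi_eff = max(lo, s_lo), min(hi, s_hi)
        if hi_eff < lo_eff:
            return 0.0

        def comp(loc: float, scale: float) -> float:
            a = -np.inf if lo_eff <= s_lo else lo_eff - 0.5
            b = np.inf if hi_eff >= s_hi else hi_eff + 0.5
            return float(norm.cdf(b, loc, scale) - norm.cdf(a, loc, scale))

        return self.w_short * comp(self.short_loc, self.short_scale) + (
            1 - self.w_short
        ) * comp(self.long_loc, self.long_scale)

    def pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer lengths over the support and their probabilities."""
        lo, hi = self.support
        lengths = np.arange(lo, hi + 1)
        edges = np.concatenate(([-np.inf], lengths[:-1] + 0.5, [np.inf]))

        def comp(loc: float, scale: float) -> np.ndarray:
            cdf = norm.cdf(edges, loc, scale)
            return np.diff(cdf)

        p = self.w_short * comp(self.short_loc, self.short_scale) + (
            1 - self.w_short
        ) * comp(self.long_loc, self.long_scale)
        return lengths, p / p.sum()


@dataclass
class CohortSpec:
    """Everything that defines one simulated cohort."""

    label: str
    n_subjects: int
    fragments_per_subject: int
    length_params: LengthMixture = field(default_factory=LengthMixture)
    motif_weights: np.ndarray = field(default_factory=lambda: np.ones(256))
    cnv_segments: list[tuple[str, int, int, int]] = field(default_factory=list)
    tumor_fraction: float = 0.0
    tfbs_dip: float = 0.0
    seed: int = 0
    mapq: int = 60
    dup_rate: float = 0.0
    lowq_rate: float = 0.0

    def __post_init__(self) -> None:
        self.motif_weights = np.asarray(self.motif_weights, dtype=float)
        if self.motif_weights.shape != (256,):
            raise ValueError("motif_weights must have exactly 256 entries")
        if np.any(self.motif_weights < 0) or self.motif_weights.sum() <= 0:
            raise ValueError("motif_weights must be nonnegative with positive sum")
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if not 0 <= self.tfbs_dip <= 1:
            raise ValueError("tfbs_dip must lie in [0, 1]")
        if self.n_subjects <= 0 or self.fragments_per_subject <= 0:
            raise ValueError("counts must be positive")
        for chrom, start, end, copy_state in self.cnv_segments:
            if end <= start or copy_state not in (1, 2, 3):
                raise ValueError(f"bad CNV segment {(chrom, start, end, copy_state)}")

    @property
    def motif_probs(self) -> np.ndarray:
        return self.motif_weights / self.motif_weights.sum()


def triangular_kernel(x: np.ndarray, halfwidth: int = KERNEL_HALFWIDTH) -> np.ndarray:
    """max(0, 1 - |x| / halfwidth): the footprint protection shape."""
    return np.maximum(0.0, 1.0 - np.abs(np.asarray(x, dtype=float)) / halfwidth)


def _copy_regions(
    genome: MiniGenome, spec: CohortSpec
) -> tuple[list[tuple[str, int, int]], np.ndarray]:
    """Partition the genome into regions of constant copy multiplier.

    With tumor_fraction = 0 every region is neutral (multiplier 1)
    regardless of the declared segments.
    """
    t = spec.tumor_fraction
    regions: list[tuple[str, int, int]] = []
    mults: list[float] = []
    for chrom, length in genome.chromosomes:
        cuts = {0, length}
        seg_states: list[tuple[int, int, int]] = []
        if t > 0:
            for c, s, e, state in spec.cnv_segments:
                if c == chrom:
                    s, e = max(0, s), min(length, e)
                    if e > s:
                        cuts.update((s, e))
                        seg_states.append((s, e, state))
        edges = sorted(cuts)
        for lo, hi in zip(edges[:-1], edges[1:]):
            state = 2
            for s, e, st in seg_states:
                if s <= lo and hi <= e:
                    state = st
                    break
            m = (2.0 * (1.0 - t) + state * t) / 2.0
            regions.append((chrom, lo, hi))
            mults.append(m)
    return regions, np.asarray(mults)


def simulate_subject(
    genome: MiniGenome,
    spec: CohortSpec,
    subject_index: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one subject's fragment frame. Deterministic given
    (seed, subject_index); ``seed`` defaults to ``spec.seed``."""
    if not genome.chromosomes:
        raise ValueError("empty genome")
    if subject_index < 0 or subject_index >= spec.n_subjects:
        raise ValueError("subject_index out of range for this cohort spec")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))
    n = spec.fragments_per_subject

    regions, mults = _copy_regions(genome, spec)
    lengths_bp = np.array([hi - lo for _, lo, hi in regions], dtype=float)
    weights = mults * lengths_bp
    weights /= weights.sum()
    region_chroms = np.array([c for c, _, _ in regions], dtype=object)
    region_lo = np.array([lo for _, lo, _ in regions], dtype=np.int64)
    region_hi = np.array([hi for _, _, hi in regions], dtype=np.int64)

    peaks_by_chrom: dict[str, np.ndarray] = {}
    for site in genome.tfbs_catalog.all_sites():
        peaks_by_chrom.setdefault(site.chrom, [])
    for site in genome.tfbs_catalog.all_sites():
        peaks_by_chrom[site.chrom].append(site.peak_point)
    peaks_by_chrom = {c: np.sort(np.asarray(p)) for c, p in peaks_by_chrom.items()}

    d = spec.tfbs_dip
    chroms_acc: list[np.ndarray] = []
    mids_acc: list[np.ndarray] = []
    n_acc = 0
    while n_acc < n:
        batch = int((n - n_acc) * 1.25) + 64
        ridx = rng.choice(len(regions), size=batch, p=weights)
        span = (region_hi - region_lo)[ridx]
        pos = region_lo[ridx] + np.floor(rng.random(batch) * span).astype(np.int64)
        chroms = region_chroms[ridx]
        if d > 0 and peaks_by_chrom:
            kern = np.zeros(batch)
            for chrom, peaks in peaks_by_chrom.items():
                if peaks.size == 0:
                    continue
                mask = chroms == chrom
                if not mask.any():
                    continue
                p = pos[mask]
                i = np.searchsorted(peaks, p)
                left = np.abs(p - peaks[np.clip(i - 1, 0, peaks.size - 1)])
                right = np.abs(peaks[np.clip(i, 0, peaks.size - 1)] - p)
                kern[mask] = triangular_kernel(np.minimum(left, right))
            accept = rng.random(batch) < 1.0 - d * kern
        else:
            accept = np.ones(batch, dtype=bool)
        chroms_acc.append(chroms[accept])
        mids_acc.append(pos[accept])
        n_acc += int(accept.sum())
    chroms = np.concatenate(chroms_acc)[:n]
    mids = np.concatenate(mids_acc)[:n]

    lengths = spec.length_params.sample(rng, n)
    starts = mids - lengths // 2
    sizes = genome.sizes()
    chrom_len = np.array([sizes[c] for c in chroms], dtype=np.int64)
    starts = np.clip(starts, 0, np.maximum(chrom_len - lengths, 0))
    ends = starts + lengths

    motif_idx = rng.choice(256, size=n, p=spec.motif_probs)
    motifs = _MOTIF_ARRAY[motif_idx]
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    mapq = np.full(n, spec.mapq, dtype=np.int64)
    if spec.lowq_rate > 0:
        low = rng.random(n) < spec.lowq_rate
        mapq[low] = rng.integers(0, 30, size=int(low.sum()))
    dup = (
        rng.random(n) < spec.dup_rate
        if spec.dup_rate > 0
        else np.zeros(n, dtype=bool)
    )
    names = [f"{spec.label}_{subject_index}_{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "chrom": chroms.astype(str),
            "start": starts,
            "end": ends,
            "name": names,
            "mapq": mapq,
            "strand": strands,
            "motif4": motifs,
            "duplicate": dup,
        },
        columns=FRAGMENT_COLUMNS,
    )


@dataclass
class SimulatedCohorts:
    """Labeled fragment sets for a set of cohorts."""

    subjects: list[str]
    labels: list[str]
    fragments: dict[str, pd.DataFrame]

    def by_label(self, label: str) -> list[str]:
        return [s for s, l in zip(self.subjects, self.labels) if l == label]


def simulate_cohorts(
    genome: MiniGenome, specs: list[CohortSpec], seed: int = 0
) -> SimulatedCohorts:
    """Simulate every cohort with per-spec, per-subject seeds derived from
    the master seed."""
    if len({s.label for s in specs}) < 2:
        raise ValueError("need at least two distinct cohort labels")
    subjects: list[str] = []
    labels: list[str] = []
    fragments: dict[str, pd.DataFrame] = {}
    for si, spec in enumerate(specs):
        spec_seed = int(
            np.random.SeedSequence([int(seed), si]).generate_state(1)[0] % (2**31)
        )
        for i in range(spec.n_subjects):
            sid = f"{spec.label}_{i:03d}"
            if sid in fragments:
                raise ValueError(f"duplicate subject identifier {sid}")
            fragments[sid] = simulate_subject(genome, spec, i, seed=spec_seed)
            subjects.append(sid)
            labels.append(spec.label)
    return SimulatedCohorts(subjects=subjects, labels=labels, fragments=fragments)


# ---------------------------------------------------------------------------
# closed-form expectations for the TFBS dip (used as an independent check of
# the measured footprint)


def expected_relative_depth(
    dip: float,
    mixture: LengthMixture,
    halfwidth: int = KERNEL_HALFWIDTH,
    flank: int = 1000,
) -> np.ndarray:
    """Expected coverage around a site peak, relative to far-flank depth.

    A fragment of length L with midpoint m covers position p iff
    m - L//2 <= p < m - L//2 + L; midpoints are uniform and thinned by
    1 - dip * k(m). Summing the thinning factor over the L contributing
    midpoints for each length, weighted by the length pmf, gives the
    expected depth exactly (up to pmf discretisation).
    """
    lengths, pmf = mixture.pmf()
    max_l = int(lengths.max())
    grid_lo = -flank - max_l - 1
    grid = np.arange(grid_lo, flank + max_l + 2)
    g = 1.0 - dip * triangular_kernel(grid, halfwidth)
    G = np.concatenate(([0.0], np.cumsum(g)))  # G[i] = sum g[:i]
    p = np.arange(-flank, flank + 1)
    depth = np.zeros_like(p, dtype=float)
    for L, w in zip(lengths, pmf):
        if w == 0:
            continue
        hi_m = p + L // 2  # inclusive upper midpoint
        lo_m = hi_m - L + 1
        depth += w * (G[hi_m - grid_lo + 1] - G[lo_m - grid_lo])
    norm_depth = float(np.sum(pmf * lengths))
    return depth / norm_depth


def expected_central_flank_ratio(
    dip: float,
    mixture: LengthMixture,
    central_halfwidth: int = 150,
    flank_range: tuple[int, int] = (750, 1000),
    halfwidth: int = KERNEL_HALFWIDTH,
    flank: int = 1000,
) -> float:
    """Predicted central/flank coverage ratio for a given dip depth."""
    prof = expected_relative_depth(dip, mixture, halfwidth=halfwidth, flank=flank)
    p = np.arange(-flank, flank + 1)
    central = np.abs(p) <= central_halfwidth
    fl = (np.abs(p) >= flank_range[0]) & (np.abs(p) <= flank_range[1])
    return float(prof[central].mean() / prof[fl].mean())
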