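# Methods

This note records the models behind `cfpipe`, the conventions and numerical
choices that are not visible from the API alone, and what the synthetic
experiments do and do not demonstrate.

## Fragment model and conventions

A fragment is an aligned, deduplicated paired-end insert: a half-open
0-based interval with strand, a Phred mapping quality, a PCR-duplicate
flag, and the first four sequenced bases of the R1 read (the molecule's 5′
end as the sequencer saw it — stored on the record, never re-derived from
the reference, so no reverse-complementing is applied downstream).
Fragment length is `end − start`. Everywhere a fragment must be assigned
to a single genomic bin, the bin containing its midpoint
`(start + end) // 2` is used; a midpoint on a bin edge belongs to the
right-hand half-open bin.

Filtering keeps fragments with `mapq ≥ mapq_min` (default 30, inclusive —
the dominant convention for "quality above 30"; the strict reading is one
flag away via `mapq_min=31`) and without the duplicate flag. For paired
SAM/BAM input the fragment mapq is the minimum over the two reads, the
conservative reading of a per-pair threshold. Filtering is idempotent and
order-preserving.

## Feature dimensions

**Fragmentation profile (5 Mb bins).** Short is 100–150 bp and long is
151–220 bp, both inclusive, so 150/151 is the exact class edge. The
per-bin ratio uses a Haldane–Anscombe pseudocount ε = 0.5 on both counts
so sparse bins stay finite; ε is configurable and ε = 0 recovers the raw
ratio. The model consumes the *centered* profile (per-subject deviation
from the genome-wide mean ratio), which removes the global short/long
level and leaves the positional pattern; centering is idempotent and
centered rows sum to zero. GC correction of these counts is deliberately
not applied by default. Bins whose blacklist overlap exceeds 10% are
dropped; bin counts are configuration outputs, not constants.

**End-motif spectrum.** The 256 4-mers over {A,C,G,T} in lexicographic
order are the fixed feature contract. 4-mers containing N carry no motif
information and are excluded from the denominator (but tallied); an input
with no informative motif at all is an error rather than a zero vector.

**Copy-number profile (0.5 Mb bins).** Raw midpoint counts are corrected
by a robust LOWESS fit of count on bin GC (span 0.3 of the usable bins,
statsmodels implementation), divided by the fitted value floored at
10⁻³ × its median, and rescaled to median 1 — making the corrected depth
scale-invariant. The baseline is the per-bin median corrected depth over a
simulated healthy reference panel (≥ 3 subjects; default 8, drawn from a
seed branch disjoint from the study cohorts so no subject informs its own
baseline). The feature is `log₂(sample/baseline)` per usable bin, with
non-positive or unusable bins imputed to 0 (copy-neutral) to keep the
matrix dense. Under the clonal-mixture model, a segment at integer copy
number c and tumor fraction t has relative depth m = (2(1−t)+ct)/2, so a
segment-mean log₂ ratio inverts to t̂ = (2^(r+1) − 2)/(c − 2); this
estimator is exercised by the parameter-recovery suite.

*Known limitation:* fitting the GC curve on the sample itself lets the fit
absorb copy-number signal when aberrant bins dominate a GC neighborhood —
on mini genomes this depends on where the GC random walk places the
segment, and it grows with the fraction of the genome that is aberrant.
This is shared with self-normalizing low-pass CNV pipelines; recovery
experiments therefore keep simulated segments a modest fraction (~10%) of
the genome, which is also the realistic regime.

**TFBS footprints.** TFs with strictly more than `min_sites` catalog sites
are kept (the catalog-scale default is 1000; mini-genome configs scale it
to 50); per TF, sites are ranked by sample-support score (ties broken by
genome order of the peak) and the top k taken, each recentered at its
ChIP-signal peak. The raw profile is, for every offset p ∈ [−1000, 1000],
the mean over sites of the fragment coverage at `peak + p`; edge-truncated
sites contribute only their defined offsets. Normalization divides by the
subject's genome-wide depth (total fragment bases / genome length) times
the mean local copy multiplier `2^log₂ratio` of the bins holding the used
sites, so a copy-neutral subject sits near 1 away from footprints. The
scalar features are the central mean (|p| ≤ 150), flank mean
(750 ≤ |p| ≤ 1000) and their ratio; a subject with zero flank coverage
gets the neutral ratio 1.0 rather than a missing value. Whether models see
the 2001-point profiles or these summaries was an open design choice;
summaries are the default because they are depth-robust at desk-scale
coverage, and the full profile remains available.

## Classifier

The four blocks are concatenated in fixed order (fragmentation, motif,
cnv, tfbs) with stable `block:feature` column names. Each contrast is an
independent binary XGBoost model — 150 estimators, max depth 2, learning
rate 0.1, `scale_pos_weight = n_negative/n_positive` computed on the
training labels, single-threaded histogram trees for bit-reproducibility
at fixed seed. Subjects are split 7:3 into train/validation, stratified
within cohort label, by a seeded permutation; train size per label is
`round(0.7 n)` clamped to `[floor(0.7 n), n−1]`. ROC curves sweep all
distinct score thresholds; AUC is trapezoidal, which equals the
Mann–Whitney pair statistic with ties counted one half (a property the
tests verify against an O(n²) oracle). The reported operating point is the
maximum of Youden's J on the validation ROC (first maximum, i.e. the most
stringent threshold, on ties); a fixed 0.5 threshold is available. All
metrics are reported on the validation split only.

## Synthetic cohorts

The generator is the package's data contract, not a fixture. A mini
genome (default 2 chromosomes × 50 Mb, GC as a random walk in 50 kb
windows clipped to [0.3, 0.7], ~2% blacklist, a TFBS catalog with
support scores) hosts cohorts defined by:

- a two-component Gaussian length mixture (short ~N(133, 12²), long
  ~N(168, 16²), rounded and clipped to 50–400 bp) whose short weight
  rises from 0.25 (healthy) to 0.40 (NPC);
- a 256-weight motif multinomial, uniform except a tilt on C-C–prefixed
  4-mers (factor 3.0 healthy, 2.4 benign, 1.6 NPC), giving the
  healthy > benign > NPC ordering on C-rich motifs;
- copy-number segments with density multiplier m = (2(1−t)+ct)/2
  (NPC default: two gains and one loss at t = 0.2; t = 0 makes any
  declared segment inert);
- thinning of fragments whose midpoint lies near a binding-site peak by
  `1 − d·k(x)`, k a triangular kernel of half-width 150 bp (d = 0.15
  healthy, 0.10 benign, 0.50 NPC — the benign cohort's shallower dip
  yields the higher central coverage of that group).

Effect sizes are simulation choices: no published quantitative effect
sizes exist for these cohort differences, so defaults were fixed once to
give clearly separated cohorts at desk scale and are labeled as such in
`configs/default.yaml`. Default cohort sizes are 360/72/72
(healthy/benign/NPC) at 12 000 fragments per subject; reduced sizes used
by individual tests and examples are stated inline. Determinism: every
subject's RNG is seeded via `SeedSequence([cohort_seed, subject_index])`,
with cohort and reference-panel seeds derived from one master seed, so any
subject can be regenerated independently.

The expected footprint attenuation has a closed form: a fragment of
length L with midpoint m covers p iff m − L//2 ≤ p < m − L//2 + L, so the
expected relative depth at p is the length-pmf-weighted window sum of
`1 − d·k(·)` — computed numerically (`expected_relative_depth`) and used
as the independent prediction the measured central/flank ratios are tested
against.

What the generator does **not** emulate: sequencing errors, GC-dependent
fragment recovery (coverage is GC-flat by construction, so the GC
correction is validated on synthetically biased counts instead),
chromatin-dependent fragment positioning beyond the TFBS kernel,
subclonal or allele-specific copy number, and inter-subject biological
variance beyond sampling noise. Consequently the perfect separation of
the default strong-signal cohorts demonstrates correct signal plumbing,
not expected clinical performance; the null configuration (all effects
off) complements it by showing the pipeline manufactures no spurious
signal (validation AUC centered on 0.5 across seeds).

## Numerical and engineering choices

- Bin assignment is O(1) per fragment (uniform-width tiling per
  chromosome); coverage profiles accumulate start/end deltas and cumsum,
  validated against a brute-force overlap oracle.
- Feature matrices round-trip through TSV at 12 significant digits;
  manifests record SHA-256 of every artifact, and a repeated `run-all`
  with the same config and seed is bit-identical.
- Degenerate inputs fail loudly: empty fragment sets for a profile,
  all-N motifs, single-class evaluation sets, sub-3-subject baselines,
  mismatched subject orderings. An in-flight run directory carries an
  `INCOMPLETE` marker (left behind on failure); stage-level resume was
  deliberately left out since a desk-scale run completes in under a
  minute.
- Problem sizes in the test suite (e.g. 300–500 k fragments for
  parameter-recovery checks, 20 seeds × 120 subjects for null
  calibration, one full-scale 504-subject run) were chosen so the whole
  suite completes in a few minutes while keeping the statistical checks
  at 3-SE resolution.
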