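# Default desk-scale configuration for the synthetic cfDNA experiment.
#
# The analysis constants (fragment-length classes, bin widths, MAPQ cutoff,
# TFBS catalog filters, boosted-tree hyperparameters, split ratio) are the
# canonical values of the assay this package models. Cohort effect sizes
# (length-mixture shifts, motif tilts, tumor fraction, footprint dip) are
# package defaults chosen to produce clearly separated synthetic cohorts;
# no published quantitative effect sizes exist for the cohort differences
# they emulate, so they are labeled here as simulation choices.

genome:
  n_chrom: 2
  chrom_length: 50000000     # bp per chromosome (2 x 50 Mb mini genome)
  gc_window: 50000           # bp per GC-track window
  n_tfs: 3
  sites_per_tf: 120
  blacklist_fraction: 0.02

bins:
  fragmentation_width: 5000000   # 5 Mb bins for the short/long ratio profile
  cnv_width: 500000              # 0.5 Mb bins for copy-number log2 ratios
  blacklist_max_overlap: 0.1

filters:
  mapq_min: 30
  drop_duplicates: true

lengths:
  short_range: [100, 150]    # bp, inclusive
  long_range: [151, 220]     # bp, inclusive

fragmentation:
  eps: 0.5                   # Haldane-Anscombe pseudocount on both counts
  center: true               # model consumes mean-centered ratios

cnv:
  loess_span: 0.3
  n_reference: 8             # healthy subjects behind the depth baseline

tfbs:
  min_sites: 50              # desk-scale stand-in for the catalog-scale 1000
  top_k: 50                  # desk-scale stand-in for the catalog-scale 1000
  flank: 1000                # bp profiled on each side of the site peak
  central_halfwidth: 150     # bp, footprint kernel half-width
  flank_range: [750, 1000]   # bp band treated as footprint-free flank

model:
  n_estimators: 150
  max_depth: 2
  learning_rate: 0.1
  train_fraction: 0.7        # 7:3 train/validation split, stratified
  threshold_rule: youden

cohorts:
  healthy:
    n_subjects: 360
    fragments_per_subject: 12000
    length: {w_short: 0.25, short_loc: 133, short_scale: 12, long_loc: 168, long_scale: 16}
    motif_tilt: {prefix: CC, factor: 3.0}
    tumor_fraction: 0.0
    cnv_segments: []
    tfbs_dip: 0.15
  benign:
    n_subjects: 72
    fragments_per_subject: 12000
    length: {w_short: 0.28, short_loc: 133, short_scale: 12, long_loc: 168, long_scale: 16}
    motif_tilt: {prefix: CC, factor: 2.4}
    tumor_fraction: 0.0
    cnv_segments: []
    tfbs_dip: 0.10
  npc:
    n_subjects: 72
    fragments_per_subject: 12000
    length: {w_short: 0.40, short_loc: 133, short_scale: 12, long_loc: 168, long_scale: 16}
    motif_tilt: {prefix: CC, factor: 1.6}
    tumor_fraction: 0.2
    cnv_segments:
      - [chr1, 10000000, 20000000, 3]
      - [chr1, 30000000, 38000000, 1]
      - [chr2, 5000000, 15000000, 3]
    tfbs_dip: 0.5
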