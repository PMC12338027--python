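"""End-to-end orchestration: simulate -> features -> train -> evaluate.

The in-memory entry point is :func:`run_experiment`, which takes a config
dictionary (see :mod:`cfpipe.presets`) and a master seed and returns the
assembled feature matrix, labels and one :class:`~cfpipe.model.EvalReport`
per cohort contrast. :func:`run_all` is the on-disk variant behind the
command line: it writes the genome, fragments, feature matrix, reports and
a content-hash manifest into a run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import fragmentation as frag_mod
from .bins import BinScheme, tile_genome
from .genome import MiniGenome, make_reference, write_genome
from .io import FeatureBlock, filter_fragments, write_feature_matrix, write_fragments
from .model import CONTRASTS, EvalReport, assemble_features, run_contrast
from .motifs import motif_spectrum
from .presets import cohort_specs, load_default_config, model_config
from .simulate import CohortSpec, SimulatedCohorts, simulate_cohorts, simulate_subject
from .tfbs import tfbs_feature_block

logger = logging.getLogger(__name__)

__all__ = [
    "build_schemes",
    "build_reference_baseline",
    "featurize_subject",
    "featurize_cohorts",
    "ExperimentResult",
    "run_experiment",
    "run_all",
]

# reference-panel subjects get a seed branch disjoint from cohort subjects
_BASELINE_SEED_TAG = 0xBA5E


def build_schemes(genome: MiniGenome, cfg: dict) -> tuple[BinScheme, BinScheme]:
    b = cfg["bins"]
    scheme_frag = tile_genome(genome, int(b["fragmentation_width"]), float(b["blacklist_max_overlap"]))
    scheme_cnv = tile_genome(genome, int(b["cnv_width"]), float(b["blacklist_max_overlap"]))
    return scheme_frag, scheme_cnv


def build_reference_baseline(
    genome: MiniGenome, scheme_cnv: BinScheme, cfg: dict, seed: int
) -> cnv_mod.Baseline:
    """Simulate a small healthy reference panel (disjoint seed branch from
    the study cohorts) and take per-bin median corrected depth."""
    n_ref = int(cfg["cnv"]["n_reference"])
    healthy = cohort_specs(cfg, labels=["healthy"])[0]
    ref_spec = CohortSpec(
        label="reference",
        n_subjects=n_ref,
        fragments_per_subject=healthy.fragments_per_subject,
        length_params=healthy.length_params,
        motif_weights=healthy.motif_weights,
        tfbs_dip=healthy.tfbs_dip,
    )
    ref_seed = int(
        np.random.SeedSequence([int(seed), _BASELINE_SEED_TAG]).generate_state(1)[0]
        % (2**31)
    )
    span = float(cfg["cnv"]["loess_span"])
    corrected = []
    for i in range(n_ref):
        frags = simulate_subject(genome, ref_spec, i, seed=ref_seed)
        frags = filter_fragments(
            frags, int(cfg["filters"]["mapq_min"]), bool(cfg["filters"]["drop_duplicates"])
        )
        counts = cnv_mod.bin_counts(frags, scheme_cnv)
        corrected.append(cnv_mod.gc_correct(counts, scheme_cnv.gc, span=span))
    return cnv_mod.build_baseline(corrected, scheme_cnv)


def featurize_subject(
    frags: pd.DataFrame,
    genome: MiniGenome,
    scheme_frag: BinScheme,
    scheme_cnv: BinScheme,
    baseline: cnv_mod.Baseline,
    cfg: dict,
    subject: str,
) -> list[FeatureBlock]:
    """All four single-subject feature blocks, in model order."""
    f = cfg["filters"]
    frags = filter_fragments(frags, int(f["mapq_min"]), bool(f["drop_duplicates"]))
    lengths_cfg = cfg["lengths"]
    short_range = tuple(lengths_cfg["short_range"])
    long_range = tuple(lengths_cfg["long_range"])

    frag_block = frag_mod.fragmentation_profile(
        frags,
        scheme_frag,
        eps=float(cfg["fragmentation"]["eps"]),
        short_range=short_range,
        long_range=long_range,
        subject=subject,
    )
    if bool(cfg["fragmentation"]["center"]):
        frag_block = frag_mod.center_profile(frag_block)

    motif_block = motif_spectrum(frags).to_block(subject)

    profile = cnv_mod.cnv_profile(frags, scheme_cnv, baseline, span=float(cfg["cnv"]["loess_span"]))
    cnv_block = profile.feature_block(subject)

    t = cfg["tfbs"]
    tfbs_block = tfbs_feature_block(
        frags,
        genome.tfbs_catalog,
        genome_length=genome.total_length(),
        chrom_sizes=genome.sizes(),
        cnv=profile,
        min_sites=int(t["min_sites"]),
        top_k=int(t["top_k"]),
        flank=int(t["flank"]),
        central_halfwidth=int(t["central_halfwidth"]),
        subject=subject,
    )
    return [frag_block, motif_block, cnv_block, tfbs_block]


def _stack(blocks_per_subject: list[list[FeatureBlock]]) -> list[FeatureBlock]:
    """Stack per-subject single-row blocks into cohort-level blocks."""
    n_blocks = len(blocks_per_subject[0])
    stacked: list[FeatureBlock] = []
    for bi in range(n_blocks):
        first = blocks_per_subject[0][bi]
        for rows in blocks_per_subject[1:]:
            if rows[bi].feature_names != first.feature_names:
                raise ValueError(f"feature names differ across subjects in block {first.block_name}")
        stacked.append(
            FeatureBlock(
                block_name=first.block_name,
                feature_names=list(first.feature_names),
                values=np.vstack([rows[bi].values for rows in blocks_per_subject]),
                subjects=[rows[bi].subjects[0] for rows in blocks_per_subject],
            )
        )
    return stacked


def featurize_cohorts(
    cohorts: SimulatedCohorts,
    genome: MiniGenome,
    scheme_frag: BinScheme,
    scheme_cnv: BinScheme,
    baseline: cnv_mod.Baseline,
    cfg: dict,
) -> list[FeatureBlock]:
    per_subject = [
        featurize_subject(
            cohorts.fragments[sid], genome, scheme_frag, scheme_cnv, baseline, cfg, sid
        )
        for sid in cohorts.subjects
    ]
    return _stack(per_subject)


@dataclass
class ExperimentResult:
    genome: MiniGenome
    cohorts: SimulatedCohorts
    blocks: list[FeatureBlock]
    X: pd.DataFrame
    labels: list[str]
    reports: dict[str, EvalReport]


def run_experiment(
    cfg: dict | None = None,
    seed: int = 0,
    contrasts: list[str] | None = None,
) -> ExperimentResult:
    """Simulate the configured cohorts, extract all features, train one
    boosted-tree model per contrast and evaluate on the validation split."""
    cfg = load_default_config() if cfg is None else cfg
    g = cfg["genome"]
    genome = make_reference(
        n_chrom=int(g["n_chrom"]),
        chrom_length=int(g["chrom_length"]),
        gc_window=int(g["gc_window"]),
        n_tfs=int(g["n_tfs"]),
        sites_per_tf=int(g["sites_per_tf"]),
        seed=seed,
        blacklist_fraction=float(g["blacklist_fraction"]),
    )
    scheme_frag, scheme_cnv = build_schemes(genome, cfg)
    baseline = build_reference_baseline(genome, scheme_cnv, cfg, seed)
    specs = cohort_specs(cfg)
    cohorts = simulate_cohorts(genome, specs, seed=seed)
    blocks = featurize_cohorts(cohorts, genome, scheme_frag, scheme_cnv, baseline, cfg)
    X = assemble_features(blocks)
    labels = cohorts.labels
    mconfig = model_config(cfg, seed=seed)
    rule = str(cfg["model"].get("threshold_rule", "youden"))
    present = set(labels)
    reports: dict[str, EvalReport] = {}
    for contrast in contrasts if contrasts is not None else list(CONTRASTS):
        neg, pos = CONTRASTS[contrast]
        if not (neg & present and pos & present):
            logger.info("skipping contrast %s: cohorts absent", contrast)
            continue
        reports[contrast] = run_contrast(X, labels, contrast, mconfig, threshold_rule=rule)
    return ExperimentResult(genome, cohorts, blocks, X, labels, reports)


# ---------------------------------------------------------------------------
# on-disk run directory


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: dict, out_dir: str, seed: int = 0) -> dict:
    """Run the full pipeline and materialise every artifact under
    ``out_dir``; returns the manifest. An ``INCOMPLETE`` marker is present
    while the run is in flight (and left behind on failure)."""
    os.makedirs(out_dir, exist_ok=True)
    marker = os.path.join(out_dir, "INCOMPLETE")
    with open(marker, "w") as fh:
        fh.write("run in progress\n")

    import yaml as _yaml

    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        _yaml.safe_dump(cfg, fh, sort_keys=False)

    result = run_experiment(cfg, seed=seed)

    genome_dir = os.path.join(out_dir, "genome")
    write_genome(result.genome, genome_dir)
    frag_dir = os.path.join(out_dir, "fragments")
    os.makedirs(frag_dir, exist_ok=True)
    for sid in result.cohorts.subjects:
        write_fragments(result.cohorts.fragments[sid], os.path.join(frag_dir, f"{sid}.tsv"))
    with open(os.path.join(out_dir, "labels.tsv"), "w") as fh:
        fh.write("subject\tlabel\n")
        for sid, label in zip(result.cohorts.subjects, result.cohorts.labels):
            fh.write(f"{sid}\t{label}\n")
    features_path = os.path.join(out_dir, "features.tsv")
    write_feature_matrix(result.blocks, features_path)

    reports = {name: rep.summary() for name, rep in result.reports.items()}
    with open(os.path.join(out_dir, "reports.json"), "w") as fh:
        json.dump(reports, fh, indent=2)
    for name, rep in result.reports.items():
        roc = pd.DataFrame({"fpr": rep.fpr, "tpr": rep.tpr})
        roc.to_csv(os.path.join(out_dir, f"roc_{name}.tsv"), sep="\t", index=False)

    manifest = {"seed": seed, "artifacts": {}}
    for root, _, files in os.walk(out_dir):
        for fname in sorted(files):
            if fname in ("INCOMPLETE", "manifest.json"):
                continue
            path = os.path.join(root, fname)
            rel = os.path.relpath(path, out_dir)
            manifest["artifacts"][rel] = _sha256(path)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    os.remove(marker)
    return manifest
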