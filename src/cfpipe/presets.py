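"""Configuration loading and cohort-spec construction.

All tunables of the experiment live in one YAML document (the packaged
``configs/default.yaml`` is the shipped default); this module turns that
document into :class:`~cfpipe.simulate.CohortSpec` objects and typed
sub-configs.
"""

from __future__ import annotations

import copy
from importlib import resources

import numpy as np
import yaml

from .model import ModelConfig
from .motifs import MOTIFS
from .simulate import CohortSpec, LengthMixture

__all__ = [
    "load_default_config",
    "load_config",
    "null_config",
    "motif_weights_from_tilt",
    "cohort_specs",
    "model_config",
]


def load_default_config() -> dict:
    text = resources.files("cfpipe").joinpath("configs/default.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def null_config() -> dict:
    """The default config with every cohort effect switched off.

    All cohorts share the healthy cohort's length mixture, motif weights
    and footprint dip, with tumor fraction zero: the labels become pure
    noise, which is the calibration condition for null classifiers.
    """
    cfg = copy.deepcopy(load_default_config())
    healthy = cfg["cohorts"]["healthy"]
    for spec in cfg["cohorts"].values():
        spec["length"] = copy.deepcopy(healthy["length"])
        spec["motif_tilt"] = copy.deepcopy(healthy["motif_tilt"])
        spec["tumor_fraction"] = 0.0
        spec["cnv_segments"] = []
        spec["tfbs_dip"] = healthy["tfbs_dip"]
    return cfg


def motif_weights_from_tilt(tilt: dict | None) -> np.ndarray:
    """Uniform 256-weight vector with motifs matching ``prefix`` scaled by
    ``factor``."""
    weights = np.ones(256)
    if tilt:
        prefix = str(tilt.get("prefix", ""))
        factor = float(tilt.get("factor", 1.0))
        for i, m in enumerate(MOTIFS):
            if m.startswith(prefix):
                weights[i] *= factor
    return weights


def cohort_specs(cfg: dict, labels: list[str] | None = None) -> list[CohortSpec]:
    """Build cohort specs from the config, optionally restricted to some
    labels (in the given order)."""
    out: list[CohortSpec] = []
    cohorts = cfg["cohorts"]
    for label in labels if labels is not None else list(cohorts):
        c = cohorts[label]
        out.append(
            CohortSpec(
                label=label,
                n_subjects=int(c["n_subjects"]),
                fragments_per_subject=int(c["fragments_per_subject"]),
                length_params=LengthMixture(**c.get("length", {})),
                motif_weights=motif_weights_from_tilt(c.get("motif_tilt")),
                cnv_segments=[
                    (str(s[0]), int(s[1]), int(s[2]), int(s[3]))
                    for s in c.get("cnv_segments", [])
                ],
                tumor_fraction=float(c.get("tumor_fraction", 0.0)),
                tfbs_dip=float(c.get("tfbs_dip", 0.0)),
            )
        )
    return out


def model_config(cfg: dict, seed: int = 0) -> ModelConfig:
    m = cfg["model"]
    return ModelConfig(
        n_estimators=int(m["n_estimators"]),
        max_depth=int(m["max_depth"]),
        learning_rate=float(m["learning_rate"]),
        train_fraction=float(m["train_fraction"]),
        seed=seed,
    )
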