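"""Boosted-tree cohort classifier and its evaluation.

The four feature dimensions are concatenated into one matrix per subject
and a gradient-boosted tree ensemble (XGBoost: 150 estimators, max depth 2,
learning rate 0.1) is trained per binary cohort contrast, with
``scale_pos_weight`` set to the negative/positive cohort-size ratio to
counter class imbalance. Subjects are split 7:3 into training and
validation sets, stratified within cohort. Evaluation reports the full ROC
curve, trapezoidal AUC, and sensitivity / specificity / accuracy at a
deterministic operating point (maximum Youden index by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "CONTRASTS",
    "ModelConfig",
    "EvalReport",
    "assemble_features",
    "compute_scale_pos_weight",
    "split_cohorts",
    "train_model",
    "roc_auc",
    "evaluate",
    "make_contrast",
    "run_contrast",
]

BLOCK_ORDER = ["fragmentation", "motif", "cnv", "tfbs"]

# positive class is always NPC
CONTRASTS = {
    "healthy_vs_npc": ({"healthy"}, {"npc"}),
    "noncancer_vs_npc": ({"healthy", "benign"}, {"npc"}),
    "benign_vs_npc": ({"benign"}, {"npc"}),
}


@dataclass
class ModelConfig:
    n_estimators: int = 150
    max_depth: int = 2
    learning_rate: float = 0.1
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators <= 0 or self.max_depth <= 0 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def assemble_features(blocks: list) -> pd.DataFrame:
    """Concatenate feature blocks into one subjects x features matrix.

    Blocks are ordered fragmentation, motif, cnv, tfbs (then any others in
    input order); all blocks must carry the same subjects in the same
    order. Column names are ``block:feature``.
    """
    if not blocks:
        raise ValueError("no feature blocks")
    subjects = blocks[0].subjects
    for b in blocks[1:]:
        if b.subjects != subjects:
            raise ValueError(
                f"subject ordering mismatch between blocks "
                f"{blocks[0].block_name!r} and {b.block_name!r}"
            )
    known = [b for name in BLOCK_ORDER for b in blocks if b.block_name == name]
    other = [b for b in blocks if b.block_name not in BLOCK_ORDER]
    return pd.concat([b.to_frame() for b in known + other], axis=1)


def compute_scale_pos_weight(y: np.ndarray) -> float:
    """Negative/positive count ratio for class-imbalance weighting."""
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_neg / n_pos


def split_cohorts(
    labels: list[str] | np.ndarray, ratio: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation index split at ``ratio``.

    Within each label the subject indices are shuffled with a seeded RNG;
    the train size is ``round(ratio * n)`` but never below
    ``floor(ratio * n)`` or above ``n - 1``. Deterministic per seed;
    train and validation partition the subjects.
    """
    labels = np.asarray(labels)
    if len(labels) < 10:
        raise ValueError("need at least 10 subjects to split")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B11]))
    train_idx: list[int] = []
    val_idx: list[int] = []
    for label in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == label)
        if len(idx) < 2:
            raise ValueError(f"label {label!r} has fewer than 2 members")
        perm = rng.permutation(idx)
        n_train = int(np.clip(round(ratio * len(idx)), int(np.floor(ratio * len(idx))), len(idx) - 1))
        n_train = max(n_train, 1)
        train_idx.extend(perm[:n_train].tolist())
        val_idx.extend(perm[n_train:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def train_model(X: pd.DataFrame, y: np.ndarray, config: ModelConfig):
    """Fit the boosted-tree classifier; returns a fitted scorer whose
    ``predict_proba(X)[:, 1]`` is the NPC score."""
    from xgboost import XGBClassifier

    values = np.asarray(X, dtype=float)
    if not np.isfinite(values).all():
        bad = np.flatnonzero(~np.isfinite(values).all(axis=0))
        cols = [X.columns[i] for i in bad[:10]]
        raise ValueError(f"non-finite features in columns: {cols}")
    y = np.asarray(y)
    model = XGBClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        scale_pos_weight=compute_scale_pos_weight(y),
        random_state=config.seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    model.fit(values, y)
    return model


def roc_auc(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (all score thresholds) and trapezoidal AUC.

    The trapezoidal area equals the Mann-Whitney pair statistic with ties
    counted one half. Returns (fpr, tpr, auc).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class EvalReport:
    """Threshold-free ROC/AUC plus one thresholded operating point."""

    contrast: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    threshold_rule: str
    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int
    extra: dict = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    def summary(self) -> dict:
        return {
            "contrast": self.contrast,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "threshold_rule": self.threshold_rule,
            "threshold": self.threshold,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
        }


def evaluate(
    scores: np.ndarray,
    y: np.ndarray,
    contrast: str = "custom",
    threshold_rule: str = "youden",
) -> EvalReport:
    """Confusion-matrix metrics at a deterministic threshold.

    ``youden`` picks the ROC point maximizing sensitivity + specificity - 1
    (first one on ties, i.e. the most stringent threshold); ``fixed``
    classifies at score >= 0.5. ROC and AUC are always threshold-free.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if len(y) == 0 or len(np.unique(y)) < 2:
        raise ValueError("evaluation set must contain both classes")
    fpr, tpr, auc = roc_auc(scores, y)
    if threshold_rule == "youden":
        _, _, thresholds = roc_curve(y, scores)
        j = tpr - fpr
        best = int(np.argmax(j))
        threshold = float(thresholds[best])
        pred = scores >= threshold
    elif threshold_rule == "fixed":
        threshold = 0.5
        pred = scores >= threshold
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return EvalReport(
        contrast=contrast,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        threshold_rule=threshold_rule,
        threshold=threshold,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def make_contrast(labels: list[str] | np.ndarray, contrast: str) -> tuple[np.ndarray, np.ndarray]:
    """Subject mask and binary target (1 = NPC) for a named cohort
    contrast."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    neg, pos = CONTRASTS[contrast]
    labels = np.asarray(labels)
    mask = np.isin(labels, sorted(neg | pos))
    y = np.isin(labels[mask], sorted(pos)).astype(int)
    return mask, y


def run_contrast(
    X: pd.DataFrame,
    labels: list[str] | np.ndarray,
    contrast: str,
    config: ModelConfig,
    threshold_rule: str = "youden",
) -> EvalReport:
    """Train on the 7:3 stratified split for one contrast and evaluate on
    the validation set."""
    labels = np.asarray(labels)
    mask, y = make_contrast(labels, contrast)
    Xc = X.iloc[np.flatnonzero(mask)]
    sub_labels = labels[mask]
    train_idx, val_idx = split_cohorts(sub_labels, ratio=config.train_fraction, seed=config.seed)
    model = train_model(Xc.iloc[train_idx], y[train_idx], config)
    scores = model.predict_proba(np.asarray(Xc.iloc[val_idx], dtype=float))[:, 1]
    report = evaluate(scores, y[val_idx], contrast=contrast, threshold_rule=threshold_rule)
    report.extra.update(
        n_train=int(len(train_idx)),
        n_val=int(len(val_idx)),
        scale_pos_weight=compute_scale_pos_weight(y[train_idx]),
    )
    return report
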