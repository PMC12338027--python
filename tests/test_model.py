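"""Classifier assembly, splitting, training and ROC evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfpipe import (
    FeatureBlock,
    ModelConfig,
    assemble_features,
    compute_scale_pos_weight,
    evaluate,
    make_contrast,
    roc_auc,
    split_cohorts,
    train_model,
)


def block(name, width, n, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureBlock(name, [f"{name}{i}" for i in range(width)],
                        rng.normal(size=(n, width)), [f"s{i}" for i in range(n)])


class TestAssemble:
    def test_width_is_sum_of_blocks(self):
        blocks = [block("fragmentation", 20, 3), block("motif", 256, 3),
                  block("cnv", 200, 3), block("tfbs", 6, 3)]
        X = assemble_features(blocks)
        assert X.shape == (3, 482)
        # canonical block order regardless of input order
        X2 = assemble_features(blocks[::-1])
        assert list(X.columns) == list(X2.columns)

    def test_single_block_passthrough(self):
        b = block("motif", 10, 4)
        X = assemble_features([b])
        np.testing.assert_array_equal(X.to_numpy(), b.values)

    def test_subject_mismatch_rejected(self):
        a = block("motif", 5, 3)
        b = block("cnv", 5, 3)
        b.subjects = ["s2", "s1", "s0"]
        with pytest.raises(ValueError, match="subject"):
            assemble_features([a, b])


class TestScalePosWeight:
    def test_paper_cohort_ratio(self):
        y = np.array([0] * 522 + [1] * 79)
        assert compute_scale_pos_weight(y) == pytest.approx(522 / 79)
        assert compute_scale_pos_weight(y) == pytest.approx(6.608, abs=5e-4)

    def test_balanced(self):
        assert compute_scale_pos_weight(np.array([0] * 50 + [1] * 50)) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_scale_pos_weight(np.zeros(10, dtype=int))

    def test_weight_times_positives_equals_negatives(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_pos = int(rng.integers(1, 100))
            n_neg = int(rng.integers(1, 100))
            y = np.array([0] * n_neg + [1] * n_pos)
            assert compute_scale_pos_weight(y) * n_pos == pytest.approx(n_neg)


class TestSplit:
    def test_seventy_thirty_arithmetic(self):
        labels = ["neg"] * 100 + ["pos"] * 50
        train, val = split_cohorts(labels, ratio=0.7, seed=1)
        labels = np.array(labels)
        assert (labels[train] == "neg").sum() == 70
        assert (labels[train] == "pos").sum() == 35
        assert (labels[val] == "neg").sum() == 30
        assert (labels[val] == "pos").sum() == 15

    def test_deterministic_per_seed(self):
        labels = ["a"] * 40 + ["b"] * 20
        t1, v1 = split_cohorts(labels, seed=5)
        t2, v2 = split_cohorts(labels, seed=5)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(v1, v2)
        t3, _ = split_cohorts(labels, seed=6)
        assert not np.array_equal(t1, t3)

    def test_partition(self):
        labels = ["a"] * 33 + ["b"] * 17
        train, val = split_cohorts(labels, seed=2)
        assert set(train) | set(val) == set(range(50))
        assert set(train) & set(val) == set()

    def test_tiny_label_rejected(self):
        with pytest.raises(ValueError):
            split_cohorts(["a"] * 20 + ["b"], seed=0)


class TestTraining:
    def test_separable_features_learned_perfectly(self):
        rng = np.random.default_rng(7)
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame({"f0": y + rng.normal(0, 0.01, n), "f1": rng.normal(size=n)})
        model = train_model(X, y, ModelConfig(seed=0))
        pred = (model.predict_proba(X.to_numpy())[:, 1] >= 0.5).astype(int)
        assert (pred == y).all()

    def test_same_data_same_seed_identical_scores(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 80)
        X = pd.DataFrame(rng.normal(size=(80, 10)))
        s1 = train_model(X, y, ModelConfig(seed=3)).predict_proba(X.to_numpy())[:, 1]
        s2 = train_model(X, y, ModelConfig(seed=3)).predict_proba(X.to_numpy())[:, 1]
        np.testing.assert_array_equal(s1, s2)

    def test_nonfinite_features_rejected_with_columns(self):
        X = pd.DataFrame({"good": [1.0, 2.0], "bad": [np.inf, 1.0]})
        with pytest.raises(ValueError, match="bad"):
            train_model(X, np.array([0, 1]), ModelConfig())

    def test_permuted_labels_give_chance_auc(self):
        """Validation AUC under label permutation: 95% CI covers 0.5."""
        rng = np.random.default_rng(11)
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 15)))
        aucs = []
        for s in range(20):
            y = rng.permutation([0] * 80 + [1] * 40)
            train, val = split_cohorts(["n" if v == 0 else "p" for v in y], seed=s)
            model = train_model(X.iloc[train], y[train], ModelConfig(seed=s))
            scores = model.predict_proba(X.iloc[val].to_numpy())[:, 1]
            aucs.append(roc_auc(scores, y[val])[2])
        mean = np.mean(aucs)
        ci = 1.96 * np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert mean - ci <= 0.5 <= mean + ci


def auc_pair_counting(scores, y):
    """O(n^2) Mann-Whitney oracle: P(pos > neg) with ties counted half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        fpr, tpr, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert auc == 1.0
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_all_ties_give_half(self):
        y = np.array([0, 1, 0, 1])
        assert roc_auc(np.full(4, 0.5), y)[2] == pytest.approx(0.5)

    def test_trapezoid_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = 200
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            # coarse grid forces plenty of ties
            scores = np.round(rng.random(n), 2)
            auc = roc_auc(scores, y)[2]
            assert auc == pytest.approx(auc_pair_counting(scores, y), abs=1e-12)

    def test_roc_monotone_nondecreasing(self):
        rng = np.random.default_rng(17)
        y = rng.integers(0, 2, 100)
        fpr, tpr, _ = roc_auc(rng.random(100), y)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert (fpr[0], tpr[0]) == (0.0, 0.0) and (fpr[-1], tpr[-1]) == (1.0, 1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.sampled_from([np.exp, np.tanh, lambda x: 3 * x + 1]))
    def test_auc_invariant_under_monotone_transform(self, seed, f):
        rng = np.random.default_rng(seed)
        y = np.concatenate([np.zeros(20, int), np.ones(20, int)])
        scores = rng.random(40)
        assert roc_auc(f(scores), y)[2] == pytest.approx(roc_auc(scores, y)[2], abs=1e-12)


class TestEvaluate:
    def test_oracle_scores_perfect_metrics(self):
        y = np.array([0] * 10 + [1] * 5)
        rep = evaluate(y.astype(float), y)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0 and rep.accuracy == 1.0
        assert rep.auc == 1.0

    def test_all_negative_predictions(self):
        y = np.array([0] * 5 + [1] * 5)
        scores = np.concatenate([np.full(5, 0.2), np.full(5, 0.1)])
        rep = evaluate(scores, y, threshold_rule="fixed")
        assert rep.sensitivity == 0.0 and rep.specificity == 1.0

    def test_constructed_confusion_rates(self):
        # TP=23, FN=1, TN=167, FP=1 -> sens 95.83%, spec 99.40%
        y = np.array([1] * 24 + [0] * 168)
        scores = np.array([0.9] * 23 + [0.1] + [0.9] + [0.1] * 167)
        rep = evaluate(scores, y, threshold_rule="fixed")
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (23, 1, 167, 1)
        assert rep.sensitivity * 100 == pytest.approx(95.83, abs=0.005)
        assert rep.specificity * 100 == pytest.approx(99.40, abs=0.005)
        assert rep.accuracy == (23 + 167) / 192

    def test_metrics_recomputable_from_counts(self):
        rng = np.random.default_rng(19)
        y = np.array([0] * 30 + [1] * 30)
        rep = evaluate(rng.random(60), y)
        assert rep.sensitivity == rep.tp / (rep.tp + rep.fn)
        assert rep.specificity == rep.tn / (rep.tn + rep.fp)
        assert rep.accuracy == (rep.tp + rep.tn) / 60

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))


class TestContrasts:
    def test_masks_and_targets(self):
        labels = ["healthy"] * 3 + ["benign"] * 2 + ["npc"] * 2
        mask, y = make_contrast(labels, "healthy_vs_npc")
        assert mask.sum() == 5 and y.tolist() == [0, 0, 0, 1, 1]
        mask, y = make_contrast(labels, "noncancer_vs_npc")
        assert mask.sum() == 7 and y.sum() == 2
        mask, y = make_contrast(labels, "benign_vs_npc")
        assert mask.sum() == 4

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError):
            make_contrast(["healthy", "npc"], "bogus")
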