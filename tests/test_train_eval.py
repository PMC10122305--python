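import numpy as np
import pytest

from psgrn import (
    ModelConfig,
    TrainSchedule,
    aupr,
    auroc,
    confusion,
    predict_scores,
    stratified_split,
    top_k_threshold,
    train,
)
from psgrn.datasets_io import ValidationError
from psgrn.train_eval import PredictionResult


def brute_force_aupr(labels, scores):
    """Average precision summed over every distinct threshold (oracle)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    thresholds = np.unique(scores)[::-1]
    ap = 0.0
    prev_recall = 0.0
    n_pos = labels.sum()
    for t in thresholds:
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def brute_force_auroc(labels, scores):
    """Mann-Whitney pair counting with half-weight ties (oracle)."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestStratifiedSplit:
    def test_exact_counts_at_prevalence_019(self):
        labels = np.zeros(1000, dtype=int)
        labels[:190] = 1
        split = stratified_split(labels, seed=42)
        tr, te, va = (split.indices(s) for s in ("train", "test", "validation"))
        assert (tr.size, te.size, va.size) == (600, 200, 200)
        assert labels[tr].sum() == 114
        assert labels[te].sum() == 38
        assert labels[va].sum() == 38

    def test_same_seed_reproduces_assignment(self):
        labels = (np.arange(200) % 7 == 0).astype(int)
        a = stratified_split(labels, seed=5)
        b = stratified_split(labels, seed=5)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    @pytest.mark.parametrize("seed", range(10))
    def test_is_a_partition(self, seed):
        labels = (np.arange(300) % 5 == 0).astype(int)
        split = stratified_split(labels, seed=seed)
        parts = [set(split.indices(s)) for s in ("train", "test", "validation")]
        assert sum(len(p) for p in parts) == 300
        assert set().union(*parts) == set(range(300))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            stratified_split(np.ones(50, dtype=int), seed=0)

    def test_too_few_of_one_class_rejected(self):
        labels = np.zeros(50, dtype=int)
        labels[:3] = 1
        with pytest.raises(ValidationError, match="at least 5"):
            stratified_split(labels, seed=0)


class TestRankingMetrics:
    def test_aupr_hand_example(self):
        assert aupr([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(
            (1 + 2 / 3) / 2
        )

    def test_auroc_hand_example(self):
        assert auroc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_perfect_and_reversed_ranking(self):
        assert aupr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auroc([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9]) == 0.0

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=12)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.uniform(size=12), 2)  # force some ties
        assert aupr(labels, scores) == pytest.approx(
            brute_force_aupr(labels, scores), abs=1e-12
        )
        assert auroc(labels, scores) == pytest.approx(
            brute_force_auroc(labels, scores), abs=1e-12
        )

    def test_auroc_negation_antisymmetry(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        scores = rng.uniform(size=50)
        assert auroc(labels, scores) == pytest.approx(1 - auroc(labels, -scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            aupr([1, 1], [0.2, 0.3])
        with pytest.raises(ValidationError):
            auroc([0, 0], [0.2, 0.3])


class TestThresholdAndConfusion:
    def test_kth_largest(self):
        assert top_k_threshold([0.9, 0.8, 0.7, 0.6], 2) == 0.8

    def test_tie_inflation_selects_more(self):
        scores = [0.9, 0.8, 0.8, 0.6]
        mu = top_k_threshold(scores, 2)
        assert mu == 0.8
        assert int(np.sum(np.asarray(scores) >= mu)) == 3

    def test_k_equals_length_selects_all(self):
        scores = [0.5, 0.1, 0.9]
        mu = top_k_threshold(scores, 3)
        assert mu == 0.1
        assert np.all(np.asarray(scores) >= mu)

    def test_k_out_of_range(self):
        with pytest.raises(ValidationError):
            top_k_threshold([0.1, 0.2], 0)
        with pytest.raises(ValidationError):
            top_k_threshold([0.1, 0.2], 3)

    def test_confusion_hand_example(self):
        # at mu=0.75: scores 0.9 (pos) and 0.8 (neg) are selected, 0.7 (pos)
        # and 0.1 (neg) are not -> one of each confusion cell
        assert confusion([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1], 0.75) == (1, 1, 1, 1)

    def test_extreme_thresholds(self):
        labels = [1, 0, 1]
        scores = [0.3, 0.5, 0.9]
        tp, fp, tn, fn = confusion(labels, scores, 0.0)
        assert (fn, tn) == (0, 0)
        tp, fp, tn, fn = confusion(labels, scores, 1.1)
        assert (tp, fp) == (0, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_identities(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        labels = rng.integers(0, 2, size=n)
        scores = rng.uniform(size=n)
        mu = float(rng.uniform())
        tp, fp, tn, fn = confusion(labels, scores, mu)
        assert tp + fp + tn + fn == n
        assert tp + fn == labels.sum()

    def test_prediction_result_from_top_k(self):
        res = PredictionResult.from_scores(
            [("a", "b"), ("a", "c"), ("a", "d")], [1, 0, 1], [0.9, 0.5, 0.2], k=2
        )
        assert res.threshold == 0.5
        assert (res.tp, res.fp, res.tn, res.fn) == (1, 1, 0, 1)


TINY_CONFIG = ModelConfig(
    tl=8,
    hidden_dim=8,
    dense_blocks=2,
    layers_per_block=1,
    growth_rate=4,
    num_init_features=4,
    seed=3,
)


class TestTraining:
    def test_two_epoch_smoke(self, small_dataset):
        split = stratified_split(small_dataset.labels, seed=3)
        model, history = train(
            TINY_CONFIG, small_dataset, split, TrainSchedule(epochs=2, batch_size=32)
        )
        assert len(history) == 2
        assert all(np.isfinite(h["train_loss"]) for h in history)
        assert all(0 <= h["val_aupr"] <= 1 for h in history)

    def test_same_seed_identical_history(self, small_dataset):
        split = stratified_split(small_dataset.labels, seed=3)
        sched = TrainSchedule(epochs=2, batch_size=32)
        _, h1 = train(TINY_CONFIG, small_dataset, split, sched)
        _, h2 = train(TINY_CONFIG, small_dataset, split, sched)
        assert h1 == h2

    def test_predict_scores_deterministic_after_training(self, small_dataset):
        split = stratified_split(small_dataset.labels, seed=3)
        model, _ = train(
            TINY_CONFIG, small_dataset, split, TrainSchedule(epochs=1, batch_size=32)
        )
        idx = split.indices("test")
        s1 = predict_scores(model, small_dataset, idx)
        s2 = predict_scores(model, small_dataset, idx)
        np.testing.assert_array_equal(s1, s2)
        assert np.all((s1 > 0) & (s1 < 1))
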