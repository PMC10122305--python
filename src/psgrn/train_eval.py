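"""Stratified partitioning, training, ranking metrics and network extraction.

Pairs are split into training / test / validation sets at a 3:1:1 ratio
with per-class stratification, the classifier is fit by minimizing binary
cross-entropy with an adaptive-moment optimizer, and ranked predictions
are summarized by AUPR (average precision — the metric of record for the
heavily unbalanced edge-label distribution), AUROC, and the confusion
counts obtained by thresholding at the k-th largest relatedness
coefficient (selection rule: score ≥ μ, so ties at μ may admit more than
k pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .datasets_io import PairLabelSet, ValidationError
from .model import ModelConfig, PSGRNModel, bce_loss

__all__ = [
    "PairDataset",
    "SplitAssignment",
    "TrainSchedule",
    "PredictionResult",
    "stratified_split",
    "train",
    "predict_scores",
    "aupr",
    "auroc",
    "top_k_threshold",
    "confusion",
]

SPLIT_NAMES = ("train", "test", "validation")


@dataclass
class PairDataset:
    """Labeled TF–gene pairs plus the per-gene feature-matrix store.

    ``tf_override`` maps a pair index to a replacement gene whose feature
    matrix is used on the TF side (the noise-injection corruption);
    feature matrices themselves are shared and never mutated.
    """

    features: dict[str, np.ndarray]
    pairs: list[tuple[str, str]]
    labels: np.ndarray
    tf_override: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != self.labels.size:
            raise ValidationError("pairs and labels length mismatch")

    @classmethod
    def from_label_set(
        cls, label_set: PairLabelSet, features: dict[str, np.ndarray]
    ) -> "PairDataset":
        pairs = [(tf, gene) for tf, gene, _ in label_set.pairs]
        return cls(features=features, pairs=pairs, labels=label_set.labels)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def feature_shape(self) -> tuple[int, int]:
        return next(iter(self.features.values())).shape

    def batch(self, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X_tf, X_target, y) arrays for the given pair indices."""
        x_tf = np.stack(
            [
                self.features[self.tf_override.get(int(i), self.pairs[int(i)][0])]
                for i in indices
            ]
        )
        x_tg = np.stack([self.features[self.pairs[int(i)][1]] for i in indices])
        return x_tf, x_tg, self.labels[indices]

    def subset(self, indices: np.ndarray) -> "PairDataset":
        indices = np.asarray(indices, dtype=int)
        old_to_new = {int(o): n for n, o in enumerate(indices)}
        return PairDataset(
            features=self.features,
            pairs=[self.pairs[int(i)] for i in indices],
            labels=self.labels[indices],
            tf_override={
                old_to_new[i]: g for i, g in self.tf_override.items() if i in old_to_new
            },
        )


@dataclass
class SplitAssignment:
    assignment: np.ndarray  # array of split names, one per pair
    seed: int

    def indices(self, split: str) -> np.ndarray:
        if split not in SPLIT_NAMES:
            raise ValidationError(f"split must be one of {SPLIT_NAMES}")
        return np.flatnonzero(self.assignment == split)


def stratified_split(
    labels_or_pairs, ratios: tuple[int, int, int] = (3, 1, 1), seed: int = 0
) -> SplitAssignment:
    """Partition pairs into train/test/validation at ``ratios``, per class.

    Within each label class the pairs are shuffled deterministically and
    allocated so every split's positive prevalence matches the global one
    to within a pair; remainder pairs go to the training split.
    """
    if isinstance(labels_or_pairs, PairLabelSet):
        labels = labels_or_pairs.labels
    else:
        labels = np.asarray(labels_or_pairs, dtype=int)
    n = labels.size
    total = sum(ratios)
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=object)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 5:
            raise ValidationError(
                f"need at least 5 pairs of label {cls}, found {idx.size}"
            )
        rng.shuffle(idx)
        n_test = int(idx.size * ratios[1] / total)
        n_val = int(idx.size * ratios[2] / total)
        assignment[idx[:n_test]] = "test"
        assignment[idx[n_test : n_test + n_val]] = "validation"
        assignment[idx[n_test + n_val :]] = "train"
    return SplitAssignment(assignment=assignment.astype(str), seed=seed)


@dataclass
class TrainSchedule:
    """Optimization protocol; ``augment_sd`` adds Gaussian input noise to
    training batches (a regularizer against gene-identity memorization on
    small pair sets; evaluation always runs on clean features)."""

    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-3
    patience: int = 10
    augment_sd: float = 0.0


def predict_scores(
    model: PSGRNModel,
    dataset: PairDataset,
    indices: np.ndarray | None = None,
    batch_size: int = 256,
) -> np.ndarray:
    """Relatedness coefficients for the given pairs (evaluation mode)."""
    if indices is None:
        indices = np.arange(len(dataset))
    model.set_training(False)
    scores = np.empty(len(indices), dtype=float)
    for start in range(0, len(indices), batch_size):
        chunk = indices[start : start + batch_size]
        x_tf, x_tg, _ = dataset.batch(chunk)
        scores[start : start + len(chunk)] = model.forward(x_tf, x_tg)
    return scores


def train(
    config: ModelConfig,
    dataset: PairDataset,
    split: SplitAssignment,
    schedule: TrainSchedule | None = None,
) -> tuple[PSGRNModel, list[dict]]:
    """Fit the classifier on the train split, early-stopping on validation AUPR.

    Returns the model restored to its best-validation-AUPR checkpoint and
    the per-epoch history of training loss and validation AUPR.  Fully
    deterministic for a fixed config seed on a single device.
    """
    schedule = schedule or TrainSchedule()
    model = PSGRNModel(config)
    n_rows, tl = dataset.feature_shape
    model.build(n_rows, tl)
    optimizer = model.make_optimizer(lr=schedule.lr)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    train_idx = split.indices("train")
    val_idx = split.indices("validation")
    history: list[dict] = []
    best_aupr = -np.inf
    best_params = None
    best_epoch = -1
    for epoch in range(schedule.epochs):
        order = train_idx.copy()
        shuffle_rng.shuffle(order)
        model.set_training(True)
        losses = []
        for start in range(0, order.size, schedule.batch_size):
            chunk = order[start : start + schedule.batch_size]
            x_tf, x_tg, y = dataset.batch(chunk)
            if schedule.augment_sd > 0:
                x_tf = x_tf + shuffle_rng.normal(0, schedule.augment_sd, x_tf.shape)
                x_tg = x_tg + shuffle_rng.normal(0, schedule.augment_sd, x_tg.shape)
            probs = model.forward(x_tf, x_tg)
            loss = bce_loss(y, probs)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            model.zero_grad()
            model.backward(y)
            optimizer.step()
            losses.append(loss)
        val_scores = predict_scores(model, dataset, val_idx)
        val_aupr = aupr(dataset.labels[val_idx], val_scores)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_aupr": val_aupr}
        )
        if val_aupr > best_aupr:
            best_aupr = val_aupr
            best_params = [p.value.copy() for p in model.params()]
            best_bn = [
                (bn.running_mean.copy(), bn.running_var.copy())
                for bn in model._bn_modules()
            ]
            best_epoch = epoch
        elif epoch - best_epoch >= schedule.patience:
            break
    if best_params is not None:
        for p, v in zip(model.params(), best_params):
            p.value[...] = v
        for bn, (m, v) in zip(model._bn_modules(), best_bn):
            bn.running_mean[...] = m
            bn.running_var[...] = v
    model.set_training(False)
    return model, history


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValidationError("labels contain a single class; metric undefined")


def aupr(labels, scores) -> float:
    """Average precision: step-wise area under the precision–recall curve."""
    labels = np.asarray(labels, dtype=int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores length mismatch")
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def auroc(labels, scores) -> float:
    """Area under the ROC curve (Mann–Whitney normalization, ties half-counted)."""
    labels = np.asarray(labels, dtype=int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores length mismatch")
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def top_k_threshold(scores, k: int) -> float:
    """μ = the k-th largest score; the selection rule score ≥ μ may tie-inflate."""
    scores = np.asarray(scores, dtype=float).ravel()
    if not (1 <= k <= scores.size):
        raise ValidationError(f"k={k} out of range [1, {scores.size}]")
    return float(np.partition(scores, scores.size - k)[scores.size - k])


def confusion(labels, scores, mu: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) counts at the threshold rule score ≥ μ."""
    labels = np.asarray(labels, dtype=int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores length mismatch")
    pred = scores >= mu
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


@dataclass
class PredictionResult:
    """Scored pairs with the threshold μ and the confusion counts at μ."""

    pairs: list[tuple[str, str]]
    scores: np.ndarray
    labels: np.ndarray
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_scores(
        cls, pairs, labels, scores, k: int | None = None, threshold: float | None = None
    ) -> "PredictionResult":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if threshold is None:
            if k is None:
                raise ValidationError("provide either k or threshold")
            threshold = top_k_threshold(scores, k)
        tp, fp, tn, fn = confusion(labels, scores, threshold)
        return cls(list(pairs), scores, labels, float(threshold), tp, fp, tn, fn)
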