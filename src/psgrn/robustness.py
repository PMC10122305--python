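"""Robustness protocols (noise injection, resampling) and ablation harness.

Two corruptions probe the classifier's stability, mirroring the standard
validation design for supervised edge classifiers:

* **noise** — a random 5% of the TF–target pairs have their TF-side
  expression series replaced by the series of a uniformly chosen random
  gene while keeping the target series and the original label, breaking
  the input–label association for those pairs;
* **incomplete** — a random label-stratified 70% of the pairs is kept.

Each condition (and each named architecture variant) is evaluated by
repeated experiments: per repeat, a derived seed drives the condition
transform, the stratified split, and training; the test-split AUPR is
recorded and summarized by mean and population variance.  All variants
and conditions at a given repeat index share the same seed, so
comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets_io import ValidationError
from .model import ModelConfig, build_variant
from .train_eval import (
    PairDataset,
    TrainSchedule,
    aupr,
    predict_scores,
    stratified_split,
    train,
)

__all__ = [
    "ExperimentReport",
    "inject_noise",
    "subsample",
    "repeat_experiment",
    "ablation_suite",
    "CONDITIONS",
]

CONDITIONS = ("original", "noise", "incomplete")


@dataclass
class ExperimentReport:
    """Per-repeat AUPR values for one condition or variant, with summary stats."""

    name: str
    auprs: list[float]
    seeds: list[int]
    config: dict = field(default_factory=dict)
    failures: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.auprs))

    @property
    def variance(self) -> float:
        """Population variance over the recorded repeats."""
        return float(np.var(self.auprs))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "auprs": self.auprs,
            "mean": self.mean,
            "variance": self.variance,
            "seeds": self.seeds,
            "config": self.config,
            "failures": self.failures,
        }


def inject_noise(
    dataset: PairDataset, fraction: float = 0.05, seed: int = 0
) -> PairDataset:
    """Corrupt a random fraction of pairs by swapping in a random TF-side series.

    Selected pairs keep their target series and label but read the
    expression of a uniformly chosen random gene on the TF side.  The
    input dataset is untouched; feature matrices are shared, not copied.
    """
    if not (0 < fraction < 1):
        raise ValidationError("fraction must be in (0, 1)")
    n = len(dataset)
    n_corrupt = round(fraction * n)
    if n_corrupt < 1:
        raise ValidationError(
            f"fraction {fraction} selects zero of {n} pairs; nothing to corrupt"
        )
    rng = np.random.default_rng([seed, 10])
    chosen = rng.choice(n, size=n_corrupt, replace=False)
    gene_pool = sorted(dataset.features)
    replacements = rng.choice(len(gene_pool), size=n_corrupt, replace=True)
    override = dict(dataset.tf_override)
    for idx, g in zip(chosen, replacements):
        override[int(idx)] = gene_pool[int(g)]
    return PairDataset(
        features=dataset.features,
        pairs=list(dataset.pairs),
        labels=dataset.labels.copy(),
        tf_override=override,
    )


def subsample(dataset: PairDataset, fraction: float = 0.70, seed: int = 0) -> PairDataset:
    """Keep a label-stratified random fraction of the pairs (incomplete data)."""
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return dataset.subset(np.arange(len(dataset)))
    rng = np.random.default_rng([seed, 11])
    n_keep_total = round(fraction * len(dataset))
    pos = np.flatnonzero(dataset.labels == 1)
    neg = np.flatnonzero(dataset.labels == 0)
    n_pos = round(fraction * pos.size)
    n_neg = n_keep_total - n_pos
    keep = np.concatenate(
        [
            rng.choice(pos, size=n_pos, replace=False),
            rng.choice(neg, size=n_neg, replace=False),
        ]
    )
    keep.sort()
    return dataset.subset(keep)


def _apply_condition(dataset: PairDataset, condition: str, seed: int) -> PairDataset:
    if condition == "original":
        return dataset
    if condition == "noise":
        return inject_noise(dataset, 0.05, seed)
    if condition == "incomplete":
        return subsample(dataset, 0.70, seed)
    raise ValidationError(f"unknown condition {condition!r}; valid: {CONDITIONS}")


def repeat_experiment(
    condition: str,
    base_dataset: PairDataset,
    base_config: ModelConfig,
    n_repeats: int = 10,
    base_seed: int = 0,
    schedule: TrainSchedule | None = None,
) -> ExperimentReport:
    """Run ``n_repeats`` independent condition→split→train→test cycles.

    ``condition`` is either one of the data conditions (original, noise,
    incomplete) or a named architecture variant trained on the unmodified
    data.  Repeat i uses seed ``base_seed + i`` throughout.
    """
    if condition in CONDITIONS:
        data_condition, config = condition, base_config
    else:
        data_condition, config = "original", build_variant(condition, base_config)
    auprs: list[float] = []
    seeds: list[int] = []
    failures: list[int] = []
    for i in range(n_repeats):
        seed = base_seed + i
        try:
            data = _apply_condition(base_dataset, data_condition, seed)
            split = stratified_split(data.labels, seed=seed)
            model, _ = train(replace(config, seed=seed), data, split, schedule)
            test_idx = split.indices("test")
            scores = predict_scores(model, data, test_idx)
            auprs.append(aupr(data.labels[test_idx], scores))
            seeds.append(seed)
        except Exception:  # noqa: BLE001 - a failed repeat is recorded, not fatal
            failures.append(seed)
    from dataclasses import asdict

    return ExperimentReport(
        name=condition,
        auprs=auprs,
        seeds=seeds,
        config=asdict(config),
        failures=failures,
    )


def ablation_suite(
    base_dataset: PairDataset,
    variants: list[str],
    base_config: ModelConfig,
    n_repeats: int = 10,
    base_seed: int = 0,
    schedule: TrainSchedule | None = None,
) -> list[ExperimentReport]:
    """One report per variant, all sharing repeat seeds (paired comparison)."""
    for name in variants:
        build_variant(name, base_config)  # validate names up front
    return [
        repeat_experiment(
            name, base_dataset, base_config, n_repeats, base_seed, schedule
        )
        for name in variants
    ]
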