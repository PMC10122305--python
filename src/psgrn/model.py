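"""The pseudo-Siamese TF–target pair classifier and its ablation variants.

A candidate regulation (TF, gene) is scored by:

1. two branch encoders with identical structure but *independent*
   weights (pseudo-Siamese, not Siamese) that turn each gene's lagged
   difference matrix into a hidden-state sequence,
2. a merge step that row-concatenates the two hidden sequences into one
   single-channel matrix (TF rows first),
3. a densely connected convolutional module that extracts spatial
   features from the merged matrix, and
4. a fully connected head with an internal max-pooling stage and a
   sigmoid output: the relatedness coefficient α ∈ (0, 1).

Every named ablation variant of the architecture is expressible through
``ModelConfig``: swapping the recurrent cell (vanilla RNN, LSTM),
removing it entirely (feature matrices straight into the convolutional
module), swapping the convolutional wiring (VGG-style, residual),
removing it (branch outputs merged by matrix multiplication), or
replacing the sigmoid with a two-class softmax.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from .datasets_io import ValidationError
from .feature_extraction import FeatureMatrix
from .nn import (
    GRU,
    LSTM,
    RNN,
    Adam,
    DenseNetModule,
    Linear,
    MaxPool1d,
    ReLU,
    ResNetModule,
    VGGModule,
    sigmoid,
)
from .nn.core import DTYPE, BatchNorm2d

__all__ = [
    "ModelConfig",
    "PairScore",
    "PSGRNModel",
    "build_variant",
    "bce_loss",
    "encode_branch",
    "merge_branches",
    "spatial_module",
    "predict_pair",
    "VARIANT_NAMES",
]

BRANCH_TYPES = ("gru", "rnn", "lstm", "none")
SPATIAL_TYPES = ("densenet", "vgg", "resnet", "none")
HEADS = ("sigmoid", "softmax")
MERGES = ("concat_rows", "multiply")

VARIANT_NAMES = (
    "PSGRN",
    "FM-DN",
    "RNN-DN",
    "LSTM-DN",
    "FM-GRU",
    "GRU-VGG",
    "GRU-RN",
    "PS-SM",
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the pair classifier."""

    tl: int = 32
    hidden_dim: int = 128
    branch_type: str = "gru"
    spatial_type: str = "densenet"
    head: str = "sigmoid"
    merge: str = "concat_rows"
    dense_blocks: int = 3
    layers_per_block: int = 4
    growth_rate: int = 12
    num_init_features: int = 16
    compression: float = 0.5
    conv_width: int = 16
    head_hidden: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim < 1:
            raise ValidationError("hidden_dim must be >= 1")
        if self.branch_type not in BRANCH_TYPES:
            raise ValidationError(f"branch_type must be one of {BRANCH_TYPES}")
        if self.spatial_type not in SPATIAL_TYPES:
            raise ValidationError(f"spatial_type must be one of {SPATIAL_TYPES}")
        if self.head not in HEADS:
            raise ValidationError(f"head must be one of {HEADS}")
        if self.merge not in MERGES:
            raise ValidationError(f"merge must be one of {MERGES}")
        if self.merge == "multiply" and self.spatial_type != "none":
            raise ValidationError(
                "merge='multiply' is only valid without a spatial module"
            )
        if self.merge == "multiply" and self.branch_type == "none":
            raise ValidationError("merge='multiply' requires a recurrent branch")


@dataclass
class PairScore:
    tf_id: str
    gene_id: str
    score: float


def build_variant(name: str, base: ModelConfig | None = None) -> ModelConfig:
    """Resolve a named architecture variant to a concrete configuration."""
    base = base or ModelConfig()
    table = {
        "PSGRN": {},
        "FM-DN": {"branch_type": "none"},
        "RNN-DN": {"branch_type": "rnn"},
        "LSTM-DN": {"branch_type": "lstm"},
        "FM-GRU": {"spatial_type": "none", "merge": "multiply"},
        "GRU-VGG": {"spatial_type": "vgg"},
        "GRU-RN": {"spatial_type": "resnet"},
        "PS-SM": {"head": "softmax"},
    }
    if name not in table:
        raise ValidationError(
            f"unknown variant {name!r}; valid names: {', '.join(VARIANT_NAMES)}"
        )
    cfg = replace(
        base,
        branch_type="gru",
        spatial_type="densenet",
        head="sigmoid",
        merge="concat_rows",
    )
    return replace(cfg, **table[name])


def bce_loss(labels, probs, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy −(1/N) Σ [y·log p + (1−y)·log(1−p)]."""
    y = np.asarray(labels, dtype=float).ravel()
    p = np.asarray(probs, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValidationError(f"length mismatch: {y.size} labels vs {p.size} probs")
    p = np.clip(p, eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


class _Head:
    """FC → ReLU → max-pool → FC, then sigmoid or two-class softmax."""

    def __init__(self, rng, in_dim: int, hidden: int, head: str):
        self.fc1 = Linear(rng, in_dim, hidden)
        self.relu = ReLU()
        self.pool = MaxPool1d(2)
        self.out_units = 2 if head == "softmax" else 1
        self.fc2 = Linear(rng, hidden // 2, self.out_units)
        self.head = head

    def modules(self):
        return [self.fc1, self.relu, self.pool, self.fc2]

    def forward(self, vec: np.ndarray) -> np.ndarray:
        h = self.fc1.forward(vec)
        h = self.relu.forward(h)
        h = self.pool.forward(h)
        logits = self.fc2.forward(h)
        if self.head == "sigmoid":
            self._probs = sigmoid(logits[:, 0])
            return self._probs
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        self._probs = ez / ez.sum(axis=1, keepdims=True)
        return self._probs[:, 1]

    def backward_from_labels(self, labels: np.ndarray) -> np.ndarray:
        """Gradient of mean BCE/CE w.r.t. the head input, via the logits."""
        B = labels.shape[0]
        if self.head == "sigmoid":
            dlogits = ((self._probs - labels) / B).astype(DTYPE)[:, None]
        else:
            onehot = np.zeros((B, 2), dtype=DTYPE)
            onehot[np.arange(B), labels.astype(int)] = 1
            dlogits = ((self._probs - onehot) / B).astype(DTYPE)
        d = self.fc2.backward(dlogits)
        d = self.pool.backward(d)
        d = self.relu.backward(d)
        return self.fc1.backward(d)


class PSGRNModel:
    """Trainable pair classifier; built lazily from the first input's shape."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.built = False
        self._modules: list = []

    # -- construction -----------------------------------------------------

    def build(self, n_rows: int, tl: int) -> None:
        """Instantiate parameters for inputs of shape (n_rows, tl)."""
        if tl != self.config.tl:
            raise ValidationError(
                f"feature matrices have tl={tl} but the model expects {self.config.tl}"
            )
        cfg = self.config
        rng = self.rng
        self.n_rows = n_rows
        branch_cls = {"gru": GRU, "rnn": RNN, "lstm": LSTM}.get(cfg.branch_type)
        if branch_cls is not None:
            self.tf_branch = branch_cls(rng, tl, cfg.hidden_dim)
            self.target_branch = branch_cls(rng, tl, cfg.hidden_dim)
            merged_cols = cfg.hidden_dim
        else:
            self.tf_branch = self.target_branch = None
            merged_cols = tl
        if cfg.spatial_type == "densenet":
            self.spatial = DenseNetModule(
                rng,
                n_blocks=cfg.dense_blocks,
                layers_per_block=cfg.layers_per_block,
                growth=cfg.growth_rate,
                num_init=cfg.num_init_features,
                compression=cfg.compression,
                input_width=merged_cols,
            )
            head_in = self.spatial.out_dim
        elif cfg.spatial_type == "vgg":
            self.spatial = VGGModule(rng, width=cfg.conv_width)
            head_in = self.spatial.out_dim
        elif cfg.spatial_type == "resnet":
            self.spatial = ResNetModule(rng, width=cfg.conv_width)
            head_in = self.spatial.out_dim
        else:
            self.spatial = None
            head_in = n_rows if cfg.merge == "multiply" else merged_cols
        self.head = _Head(rng, head_in, cfg.head_hidden, cfg.head)
        self._modules = [
            m
            for m in (self.tf_branch, self.target_branch, self.spatial)
            if m is not None
        ] + self.head.modules()
        self.built = True

    def params(self):
        if not self.built:
            raise RuntimeError("model not built; call build() or forward() first")
        out = []
        for m in self._modules:
            out.extend(m.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0

    def set_training(self, flag: bool) -> None:
        """Toggle batch-norm between batch statistics and running averages."""
        for m in self._modules:
            for sub in m.iter_modules():
                if isinstance(sub, BatchNorm2d):
                    sub.training = flag

    def _bn_modules(self) -> list[BatchNorm2d]:
        return [
            sub
            for m in self._modules
            for sub in m.iter_modules()
            if isinstance(sub, BatchNorm2d)
        ]

    # -- forward / backward ----------------------------------------------

    def forward(self, x_tf: np.ndarray, x_target: np.ndarray) -> np.ndarray:
        """Score a batch of pairs: (B, T, tl) × 2 -> probabilities (B,)."""
        x_tf = np.asarray(x_tf, dtype=DTYPE)
        x_target = np.asarray(x_target, dtype=DTYPE)
        if x_tf.shape != x_target.shape:
            raise ValidationError("TF and target feature batches differ in shape")
        B, T, tl = x_tf.shape
        if not self.built:
            self.build(T, tl)
        if T != self.n_rows or tl != self.config.tl:
            raise ValidationError(
                f"input shape ({T},{tl}) does not match built model "
                f"({self.n_rows},{self.config.tl})"
            )
        cfg = self.config
        if self.tf_branch is not None:
            h_tf = self.tf_branch.forward(x_tf)
            h_tg = self.target_branch.forward(x_target)
        else:
            h_tf, h_tg = x_tf, x_target
        if cfg.merge == "concat_rows":
            merged = np.concatenate([h_tf, h_tg], axis=1)  # TF rows first
            if self.spatial is not None:
                vec = self.spatial.forward(merged[:, None, :, :])
                self._merge_cache = ("spatial", h_tf.shape)
            else:
                vec = merged.mean(axis=1)
                self._merge_cache = ("mean", merged.shape)
        else:  # multiply: correlation of the two hidden sequences
            self._mult_cache = (h_tf, h_tg)
            corr = np.einsum("bth,bsh->bts", h_tf, h_tg, optimize=True)
            corr /= cfg.hidden_dim
            vec = corr.mean(axis=2)
            self._merge_cache = ("multiply", corr.shape)
        return self.head.forward(vec)

    def backward(self, labels: np.ndarray) -> None:
        """Accumulate gradients of the mean BCE loss for the last forward batch."""
        cfg = self.config
        dvec = self.head.backward_from_labels(np.asarray(labels, dtype=DTYPE))
        kind, shape = self._merge_cache
        if kind == "spatial":
            dmerged = self.spatial.backward(dvec)[:, 0]
            B, T, H = shape
            dh_tf, dh_tg = dmerged[:, :T], dmerged[:, T:]
        elif kind == "mean":
            B, rows, H = shape
            dmerged = np.broadcast_to(dvec[:, None, :], shape).astype(DTYPE) / rows
            T = rows // 2
            dh_tf, dh_tg = dmerged[:, :T], dmerged[:, T:]
        else:  # multiply
            B, T, S = shape
            dcorr = np.broadcast_to(dvec[:, :, None], shape).astype(DTYPE) / S
            dcorr = dcorr / cfg.hidden_dim
            h_tf, h_tg = self._mult_cache
            dh_tf = np.einsum("bts,bsh->bth", dcorr, h_tg, optimize=True)
            dh_tg = np.einsum("bts,bth->bsh", dcorr, h_tf, optimize=True)
        if self.tf_branch is not None:
            self.tf_branch.backward(np.ascontiguousarray(dh_tf))
            self.target_branch.backward(np.ascontiguousarray(dh_tg))

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params(), lr=lr)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        if not self.built:
            raise RuntimeError("cannot save an unbuilt model")
        cfg_json = json.dumps(asdict(self.config), sort_keys=True)
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bn_modules()):
            arrays[f"bn_{i}_mean"] = bn.running_mean
            arrays[f"bn_{i}_var"] = bn.running_var
        np.savez(
            path,
            config_json=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
            config_hash=np.frombuffer(
                hashlib.sha256(cfg_json.encode()).digest(), dtype=np.uint8
            ),
            n_rows=np.array([self.n_rows]),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "PSGRNModel":
        with np.load(path) as data:
            cfg_json = bytes(data["config_json"]).decode()
            stored_hash = bytes(data["config_hash"])
            if hashlib.sha256(cfg_json.encode()).digest() != stored_hash:
                raise ValidationError("checkpoint config hash mismatch")
            config = ModelConfig(**json.loads(cfg_json))
            model = cls(config)
            model.build(int(data["n_rows"][0]), config.tl)
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"param_{i}"]
            for i, bn in enumerate(model._bn_modules()):
                bn.running_mean[...] = data[f"bn_{i}_mean"]
                bn.running_var[...] = data[f"bn_{i}_var"]
        model.set_training(False)
        return model


def encode_branch(
    model: PSGRNModel, feature: FeatureMatrix | np.ndarray, branch: str
) -> np.ndarray:
    """Hidden-state sequence of one branch encoder for a single feature matrix.

    ``branch`` is ``"tf_branch"`` or ``"target_branch"``; the two branches
    hold independent parameters.  Returns an (n−tl−1) × hidden_dim array.
    """
    if branch not in ("tf_branch", "target_branch"):
        raise ValidationError("branch must be 'tf_branch' or 'target_branch'")
    values = feature.values if isinstance(feature, FeatureMatrix) else np.asarray(feature)
    if not model.built:
        model.build(values.shape[0], values.shape[1])
    if values.shape != (model.n_rows, model.config.tl):
        raise ValidationError(
            f"feature shape {values.shape} does not match model "
            f"({model.n_rows}, {model.config.tl})"
        )
    encoder = getattr(model, branch)
    if encoder is None:
        raise ValidationError("this configuration has no recurrent branches")
    return encoder.forward(values[None].astype(DTYPE))[0]


def merge_branches(h_tf: np.ndarray, h_target: np.ndarray, mode: str = "concat_rows") -> np.ndarray:
    """Combine the two hidden sequences into the spatial-module input.

    ``concat_rows`` stacks the sequences vertically (TF rows first) into a
    2·(n−tl−1) × hidden matrix; ``multiply`` forms the scaled correlation
    matrix h_tf · h_targetᵀ / hidden_dim used by the spatial-free variant.
    """
    h_tf = np.asarray(h_tf)
    h_target = np.asarray(h_target)
    if h_tf.shape != h_target.shape:
        raise ValidationError("branch outputs differ in shape")
    if mode == "concat_rows":
        return np.concatenate([h_tf, h_target], axis=0)
    if mode == "multiply":
        return (h_tf @ h_target.T) / h_tf.shape[1]
    raise ValidationError(f"unknown merge mode {mode!r}; valid: {MERGES}")


def spatial_module(model: PSGRNModel, merged: np.ndarray) -> np.ndarray:
    """Fixed-length spatial feature vector of a merged pair matrix."""
    if not model.built:
        raise RuntimeError("model not built; call build() or forward() first")
    if model.spatial is None:
        raise ValidationError("this configuration has no spatial module")
    merged = np.asarray(merged, dtype=DTYPE)
    return model.spatial.forward(merged[None, None])[0]


def predict_pair(
    model: PSGRNModel, fm_tf: FeatureMatrix, fm_target: FeatureMatrix
) -> PairScore:
    """Relatedness coefficient α ∈ (0,1) for one (TF, target) pair."""
    if not model.built:
        raise RuntimeError("model not built; call build() or train first")
    score = model.forward(fm_tf.values[None], fm_target.values[None])[0]
    return PairScore(
        tf_id=fm_tf.gene_id or "tf",
        gene_id=fm_target.gene_id or "target",
        score=float(score),
    )
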