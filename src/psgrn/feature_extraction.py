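"""Lagged difference-matrix encoding of expression time series.

Each gene's length-``n`` expression series is encoded as a matrix of
forward differences: row ``j`` (1-based, ``j = 1 … n-tl-1``) holds the
changes from time ``j`` to each of the next ``tl`` time points,

    row_j = [x[j+1]-x[j], x[j+2]-x[j], ..., x[j+tl]-x[j]],

so the matrix has shape ``(n - tl - 1) × tl``.  The encoding captures how
expression moves after every time point at up to ``tl`` steps of lag; a
regulated target tends to mirror its regulator's difference rows shifted
by the regulatory delay.  With the time-lag parameter at its default 32 a
107-point series becomes a 74 × 32 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets_io import ExpressionProfile, ValidationError

__all__ = ["FeatureMatrix", "difference_matrix", "normalize_series", "featurize_profile"]

DEFAULT_TIME_LAG = 32

NORMALIZE_MODES = ("none", "zscore", "log1p_zscore")


@dataclass
class FeatureMatrix:
    """Per-gene lagged difference matrix of shape (n - tl - 1) × tl."""

    values: np.ndarray
    tl: int
    gene_id: str | None = None

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def difference_matrix(series, tl: int, gene_id: str | None = None) -> FeatureMatrix:
    """Build the lagged difference matrix of a single expression series.

    Entry (j, d) is ``series[j+d] - series[j]`` with 1-based row index j and
    1-based lag offset d, i.e. the expression change d steps after time j.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if not (1 <= tl <= n - 2):
        raise ValidationError(
            f"time lag tl={tl} out of range for series length n={n}; need 1 <= tl <= n-2"
        )
    n_rows = n - tl - 1
    # vectorized: rows of a sliding window minus the window's anchor value
    idx = np.arange(n_rows)[:, None] + np.arange(1, tl + 1)[None, :]
    values = x[idx] - x[:n_rows, None]
    return FeatureMatrix(values=values, tl=tl, gene_id=gene_id)


def normalize_series(series, mode: str = "zscore") -> np.ndarray:
    """Standardize a series before differencing.

    ``none``: identity. ``zscore``: (x - mean) / sd, all-zero when the
    series is constant. ``log1p_zscore``: z-score of log(1 + x), for
    heavy-tailed non-negative expression levels.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise ValidationError("series must have length >= 2")
    if mode not in NORMALIZE_MODES:
        raise ValidationError(f"unknown mode {mode!r}; choose from {NORMALIZE_MODES}")
    if mode == "none":
        return x.copy()
    if mode == "log1p_zscore":
        if (x < 0).any():
            raise ValidationError("log1p_zscore requires non-negative values")
        x = np.log1p(x)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def featurize_profile(
    profile: ExpressionProfile,
    tl: int = DEFAULT_TIME_LAG,
    normalize: str = "zscore",
) -> dict[str, np.ndarray]:
    """Difference matrices for every gene in a profile, keyed by gene id."""
    return {
        gene: difference_matrix(normalize_series(profile.values[i], normalize), tl).values
        for i, gene in enumerate(profile.gene_ids)
    }
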