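"""Reading, filtering and pairing of expression profiles and candidate regulations.

The preprocessing pipeline implemented here turns two text inputs — a
gene × time-point expression matrix and a list of candidate TF→target
regulations with p-values — into a fully labeled set of ordered TF–gene
pairs suitable for supervised edge classification:

1. drop genes whose mean expression over the time course is below a
   threshold (non-expressed genes),
2. keep only credible regulations (p-value at or below a significance
   cutoff), sorted by ascending p-value,
3. restrict to the sub-network induced by the genes touched by the top-k
   most credible regulations,
4. enumerate every ordered (TF, gene) pair over that sub-network and
   label it 1 if it is a known regulation, 0 otherwise.

Positive labels are rare; ``network_density`` (regulations / (TFs × genes))
is exactly the positive-label prevalence of the resulting pair set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionProfile",
    "CandidateEdgeTable",
    "PairLabelSet",
    "read_expression",
    "read_edges",
    "filter_expressed",
    "filter_credible_edges",
    "build_subdataset",
    "label_all_pairs",
    "network_density",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def _detect_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class ExpressionProfile:
    """A gene-indexed matrix of expression levels over ordered time points."""

    gene_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_timepoints)
    time_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids but {self.values.shape[0]} rows"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.shape[1] < 2:
            raise ValidationError("need at least 2 time points")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains missing/non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def series(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, gene_ids: list[str]) -> "ExpressionProfile":
        """Restrict to ``gene_ids``, preserving this profile's row order."""
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        idx = [self.gene_ids.index(g) for g in keep]
        return ExpressionProfile(keep, self.values[idx], self.time_labels)

    def to_frame(self) -> pd.DataFrame:
        cols = self.time_labels or [f"t{i}" for i in range(self.n_timepoints)]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)

    def write(self, path: str | Path, delimiter: str | None = None) -> None:
        sep = _detect_delimiter(path, delimiter)
        self.to_frame().to_csv(path, sep=sep, index_label="gene_id", float_format="%.10g")


@dataclass
class CandidateEdgeTable:
    """Directed TF→target candidate regulations with p-values."""

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for tf, target, p in self.edges:
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"p-value {p} for ({tf},{target}) outside [0,1]")
            if (tf, target) in seen:
                raise ValidationError(f"duplicate edge ({tf},{target})")
            seen.add((tf, target))

    @property
    def tf_set(self) -> set[str]:
        return {tf for tf, _, _ in self.edges}

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return {(tf, target) for tf, target, _ in self.edges}

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["tf", "target", "p_value"])

    def write(self, path: str | Path, delimiter: str | None = None) -> None:
        sep = _detect_delimiter(path, delimiter)
        self.to_frame().to_csv(path, sep=sep, index=False, float_format="%.10g")


@dataclass
class PairLabelSet:
    """Every ordered (TF, gene) pair with a binary regulation label."""

    tfs: list[str]
    genes: list[str]
    pairs: list[tuple[str, str, int]]

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_positive(self) -> int:
        return sum(label for _, _, label in self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, _, label in self.pairs], dtype=int)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["tf", "gene", "label"])

    def write(self, path: str | Path, delimiter: str | None = None) -> None:
        sep = _detect_delimiter(path, delimiter)
        self.to_frame().to_csv(path, sep=sep, index=False)


def read_expression(path: str | Path, delimiter: str | None = None) -> ExpressionProfile:
    """Read a delimited expression matrix (first column gene IDs, header = time labels)."""
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ValidationError(
                f"non-numeric expression value in column {col!r}, row {bad[0]!r}"
            )
    if df.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    return ExpressionProfile(
        gene_ids=[str(g) for g in df.index],
        values=df.to_numpy(dtype=float),
        time_labels=[str(c) for c in df.columns],
    )


def read_edges(path: str | Path, delimiter: str | None = None) -> CandidateEdgeTable:
    """Read a 3-column (tf, target, p_value) delimited edge list, optional header."""
    sep = _detect_delimiter(path, delimiter)
    first = pd.read_csv(path, sep=sep, nrows=1, header=None)
    has_header = False
    try:
        float(first.iloc[0, 2])
    except (TypeError, ValueError):
        has_header = True
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    df.columns = ["tf", "target", "p_value"]
    edges = [
        (str(r.tf), str(r.target), float(r.p_value)) for r in df.itertuples(index=False)
    ]
    return CandidateEdgeTable(edges)


def filter_expressed(profile: ExpressionProfile, min_mean: float = 1.0) -> ExpressionProfile:
    """Keep genes whose mean expression over the time course is >= ``min_mean``."""
    if min_mean < 0:
        raise ValidationError("min_mean must be non-negative")
    means = profile.values.mean(axis=1)
    keep = means >= min_mean
    if not keep.any():
        warnings.warn("no genes pass the expression filter", stacklevel=2)
    gene_ids = [g for g, k in zip(profile.gene_ids, keep) if k]
    return ExpressionProfile(gene_ids, profile.values[keep], profile.time_labels)


def filter_credible_edges(
    edges: CandidateEdgeTable, alpha: float = 0.01
) -> CandidateEdgeTable:
    """Keep edges with p <= alpha, sorted ascending by p (ties: lexicographic)."""
    kept = [(tf, tgt, p) for tf, tgt, p in edges.edges if p <= alpha]
    kept.sort(key=lambda e: (e[2], e[0], e[1]))
    return CandidateEdgeTable(kept)


def build_subdataset(
    edges: CandidateEdgeTable, profile: ExpressionProfile, k: int
) -> tuple[ExpressionProfile, CandidateEdgeTable]:
    """Sub-network induced by the genes of the ``k`` most credible regulations.

    ``edges`` must already be credibility-filtered and sorted ascending by
    p-value.  The selected gene set is every TF or target appearing in the
    first ``k`` edges that is also present in ``profile``; the returned edge
    table contains *all* credible edges whose two endpoints lie in that gene
    set (the induced sub-network, not only the top-k edges).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(edges):
        warnings.warn(
            f"k={k} exceeds edge count {len(edges)}; using all edges", stacklevel=2
        )
        k = len(edges)
    expressed = set(profile.gene_ids)
    gene_set: set[str] = set()
    for tf, target, _ in edges.edges[:k]:
        if tf in expressed:
            gene_set.add(tf)
        if target in expressed:
            gene_set.add(target)
    induced = [
        (tf, tgt, p)
        for tf, tgt, p in edges.edges
        if tf in gene_set and tgt in gene_set
    ]
    return profile.subset(sorted(gene_set)), CandidateEdgeTable(induced)


def label_all_pairs(
    sub_profile: ExpressionProfile, sub_edges: CandidateEdgeTable
) -> PairLabelSet:
    """Enumerate every ordered (TF, gene) pair and label known regulations 1.

    TFs are the distinct edge sources; genes are every gene in the profile
    (TFs included, so self-pairs tf→tf are enumerated).  The result has
    exactly n_tfs × n_genes pairs.
    """
    genes = list(sub_profile.gene_ids)
    gene_set = set(genes)
    for tf, target, _ in sub_edges.edges:
        if tf not in gene_set or target not in gene_set:
            raise ValidationError(f"edge endpoint ({tf},{target}) missing from profile")
    tfs = sorted(sub_edges.tf_set)
    positive = sub_edges.pair_set
    pairs = [
        (tf, gene, 1 if (tf, gene) in positive else 0) for tf in tfs for gene in genes
    ]
    return PairLabelSet(tfs=tfs, genes=genes, pairs=pairs)


def network_density(n_regulations: int, n_tfs: int, n_genes: int) -> float:
    """Regulations / (TFs × genes): the positive prevalence of the pair set."""
    if n_tfs < 1 or n_genes < 1:
        raise ValidationError("need at least one TF and one gene")
    if not (0 <= n_regulations <= n_tfs * n_genes):
        raise ValidationError(
            f"regulation count {n_regulations} outside [0, {n_tfs * n_genes}]"
        )
    return n_regulations / (n_tfs * n_genes)
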