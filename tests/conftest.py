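import os

# pin BLAS to one thread before numpy loads: keeps training trajectories
# bit-identical regardless of host core count
for var in ("OPENBLAS_NUM_THREADS", "OMP_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(var, "1")

import numpy as np
import pytest

from psgrn import (
    CandidateEdgeTable,
    ExpressionProfile,
    PairDataset,
    SimulationConfig,
    featurize_profile,
    make_benchmark,
)


@pytest.fixture
def tiny_profile() -> ExpressionProfile:
    values = np.array(
        [
            [0.0, 1.0, 2.0, 3.0],
            [1.0, 1.0, 1.0, 1.0],
            [2.0, 4.0, 1.0, 5.0],
        ]
    )
    return ExpressionProfile(["g1", "g2", "g3"], values, ["t0", "t1", "t2", "t3"])


@pytest.fixture
def toy_edges() -> CandidateEdgeTable:
    return CandidateEdgeTable(
        [
            ("a", "b", 0.001),
            ("a", "c", 0.002),
            ("b", "d", 0.003),
            ("c", "a", 0.004),
        ]
    )


# A small, fast benchmark for training-path tests: 40 time points, tl=8
# gives 31-row feature matrices, and 20 genes keep epochs sub-second.
SMALL_SIM = SimulationConfig(
    n_genes=20, n_tfs=5, density=0.15, n_timepoints=40, signal_lag=2, seed=11
)
SMALL_TL = 8


@pytest.fixture(scope="session")
def small_benchmark():
    profile, grn, labels = make_benchmark(SMALL_SIM)
    return profile, grn, labels


@pytest.fixture(scope="session")
def small_dataset(small_benchmark) -> PairDataset:
    profile, _, labels = small_benchmark
    feats = featurize_profile(profile, tl=SMALL_TL)
    return PairDataset.from_label_set(labels, feats)
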