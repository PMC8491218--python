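"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from pesig import io, synthetic as syn
from pesig.io import ExpressionMatrix, ResponseTable


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, hand-sized."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 6.0, 6.0]],
            index=["GA", "GB", "GC"],
            columns=["S1", "S2", "S3", "S4"],
        )
    )


@pytest.fixture(scope="session")
def small_spec() -> syn.SyntheticSpec:
    """Down-scaled study conditions for fast unit tests."""
    return syn.SyntheticSpec(
        n_cell_lines=30,
        n_patients=24,
        n_genes=40,
        n_planted_angle_genes=8,
        n_curated=4,
        n_cn_correlated=1,
        network=syn.NetworkSpec(n_extra_nodes=10, edge_density=0.05, n_chains=2),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_spec):
    return syn.make_cell_line_panel(small_spec)


@pytest.fixture(scope="session")
def small_network(small_spec, small_panel):
    return syn.make_network(small_spec, small_panel.curated)


def separable_training(
    n_per_class: int = 20,
    n_informative: int = 1,
    n_noise: int = 9,
    gap_sd: float = 3.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """A planted perfectly-separable two-class training set.

    Informative genes have class means +-gap_sd/2 (unit noise SD), noise
    genes are pure noise. Returns (matrix, +-1 labels).
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    samples = [f"S{i:02d}" for i in range(n)]
    labels = np.array([io.RESISTANT] * n_per_class + [io.SENSITIVE] * n_per_class)
    rows, names = [], []
    for i in range(n_informative):
        shift = np.where(labels == io.RESISTANT, gap_sd / 2, -gap_sd / 2)
        rows.append(7.0 + shift + rng.normal(0, 1.0, n) * 0.3)
        names.append(f"INF{i}")
    for i in range(n_noise):
        rows.append(7.0 + rng.normal(0, 1.0, n))
        names.append(f"NOISE{i}")
    matrix = ExpressionMatrix(pd.DataFrame(rows, index=names, columns=samples))
    return matrix, pd.Series(labels, index=samples, dtype=int)
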