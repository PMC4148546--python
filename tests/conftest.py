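import numpy as np
import pandas as pd
import pytest

import binsig as bs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng):
    """12 genes x 8 samples of log2-like expression values."""
    vals = rng.normal(8.0, 1.5, size=(12, 8))
    return pd.DataFrame(
        vals,
        index=[f"g{i:02d}" for i in range(12)],
        columns=[f"s{i}" for i in range(8)],
    )


@pytest.fixture
def small_cohort():
    """Simulated 30-patient survival cohort with planted signal."""
    cfg = bs.SimulationConfig(
        n_genes=60, n_samples=30, n_informative=6, effect_size=1.0, seed=11
    )
    m, records, truth = bs.simulate_survival_cohort(cfg)
    labels = bs.binarize_survival(records)
    return m, records, labels, truth


def make_bins(codes, gene_ids=None, sample_ids=None):
    """Binned matrix from a list-of-lists of codes in {-1, 0, 1}."""
    codes = np.asarray(codes, dtype=np.int8)
    gene_ids = gene_ids or [f"g{i}" for i in range(codes.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(codes.shape[1])]
    return pd.DataFrame(codes, index=gene_ids, columns=sample_ids)
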