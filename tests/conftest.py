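import logging

import numpy as np
import pandas as pd
import pytest

from rewirenet.data import CountMatrix

logging.getLogger("rewirenet").setLevel(logging.ERROR)


def make_counts(values, gene_ids=None, levels=("CON", "VTM")) -> CountMatrix:
    """CountMatrix from a 2-D array, first half of columns = reference."""
    values = np.asarray(values)
    n_genes, n_samples = values.shape
    assert n_samples % 2 == 0
    half = n_samples // 2
    genes = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"{lev}_{i + 1}" for lev in levels for i in range(half)]
    conditions = pd.Series([lev for lev in levels for _ in range(half)], index=samples)
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples), conditions, levels)


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    return make_counts(rng.poisson(50, size=(20, 8)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
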