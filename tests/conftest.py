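import numpy as np
import pandas as pd
import pytest

from terminseq import GeneModel, make_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced synthetic dataset (fast) with ground truth."""
    return make_benchmark(n_genes=80, n_true_positive=10, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_genes(rng, n, min_len=2, max_len=5000):
    """Random gene spans on a shared chromosome namespace (may overlap)."""
    genes = []
    for i in range(n):
        start = int(rng.integers(0, 100_000))
        length = int(rng.integers(min_len, max_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i}", f"chr{int(rng.integers(1, 4))}", start,
                               start + length, strand))
    return genes


@pytest.fixture()
def sample_sheet():
    return pd.DataFrame({
        "sample_id": ["a1", "a2", "b1", "b2"],
        "genotype": ["WT", "WT", "hen2", "hen2"],
        "condition": ["control_22C"] * 4,
        "replicate": [1, 2, 1, 2],
    })
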