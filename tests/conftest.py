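import numpy as np
import pandas as pd
import pytest

from tumorhet import ExpressionDataset, GeneSetCollection


def make_dataset(values, gene_ids=None, sample_ids=None, cases=None, histotypes=None):
    """Build a small ExpressionDataset from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(1, n_genes + 1)]
    sample_ids = sample_ids or [f"S{j}" for j in range(1, n_samples + 1)]
    cases = cases or ["case1"] * n_samples
    histotypes = histotypes or ["HB"] * n_samples
    ann = pd.DataFrame(
        {"case_id": cases, "histotype": histotypes}, index=pd.Index(sample_ids)
    )
    return ExpressionDataset(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        ann,
    )


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, two cases in two histotypes."""
    return make_dataset(
        [[4.0, 6.0, 8.0, 10.0], [6.0, 6.0, 6.0, 6.0], [1.0, 2.0, 3.0, 4.0]],
        cases=["c1", "c1", "c2", "c2"],
        histotypes=["HB", "HB", "WT", "WT"],
    )


@pytest.fixture
def random_dataset():
    """40 genes x 12 samples of Gaussian log2 intensities, 3 cases x 2 histotypes."""
    rng = np.random.default_rng(42)
    return make_dataset(
        rng.normal(7.0, 1.5, size=(40, 12)),
        cases=[f"c{1 + j // 4}" for j in range(12)],
        histotypes=["HB"] * 8 + ["WT"] * 4,
    )


@pytest.fixture
def small_collection():
    return GeneSetCollection({"S1": ["G1", "G2"], "S2": ["G3"]}, {"S1": "a", "S2": "b"})
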