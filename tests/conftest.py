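import numpy as np
import pandas as pd
import pytest

from degnet import ExpressionDataset


def make_dataset(values: np.ndarray, *, dataset_id="ds1", group="LC",
                 n_case=None, gene_prefix="G") -> ExpressionDataset:
    """Wrap a matrix into an ExpressionDataset; last n_case columns are cases."""
    n_genes, n_samples = values.shape
    if n_case is None:
        n_case = n_samples // 2
    genes = [f"{gene_prefix}{i + 1}" for i in range(n_genes)]
    samples = [f"s{i + 1}" for i in range(n_samples)]
    classes = ["control"] * (n_samples - n_case) + ["case"] * n_case
    return ExpressionDataset(
        dataset_id=dataset_id,
        disease_group=group,
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_class=pd.Series(classes, index=samples),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    return make_dataset(8.0 + rng.standard_normal((20, 8)))
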