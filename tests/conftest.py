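import numpy as np
import pandas as pd
import pytest

from gravistab.matrixio import ExpressionMatrix, SampleSheet
from gravistab.simdata import default_config, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """400-gene three-platform dataset with the default planted truth."""
    return generate_dataset(default_config(seed=7, n_genes=400, band_size=40))


@pytest.fixture(scope="session")
def null_dataset():
    """All-null dataset: every gene has zero effect everywhere."""
    return generate_dataset(
        default_config(
            seed=13,
            n_genes=400,
            frac_global_stable=1.0,
            responsive_effects=(),
            panel_genes=(),
            band_size=0,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, gene_ids=None, sample_ids=None, scale="log2"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(data=df, scale=scale)


def make_sheet(rows):
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "platform", "condition", "replicate"])
    )
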