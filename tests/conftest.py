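import numpy as np
import pandas as pd
import pytest

from woundarray.core import CONDITIONS, DesignTable, ExpressionMatrix
from woundarray.differential import estimate_prior, fit_gene_models
from woundarray.synthetic import SyntheticConfig, generate_expression


def make_design(n_reps: int = 3) -> DesignTable:
    rows = [
        (f"{cond}_{r + 1}", cond, r + 1)
        for cond in CONDITIONS
        for r in range(n_reps)
    ]
    return DesignTable(
        pd.DataFrame(rows, columns=["sample", "condition", "replicate"])
    )


def make_log2_matrix(values: np.ndarray, n_reps: int = 3) -> ExpressionMatrix:
    """Wrap a genes × (4·n_reps) array as a log2 ExpressionMatrix."""
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"{cond}_{r + 1}" for cond in CONDITIONS for r in range(n_reps)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale="log2"
    )


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SyntheticConfig(n_genes=800, seed=42, de_fraction=0.15,
                          fc_range=(2.0, 4.0), template_fraction=0.0)
    matrix, design, truth = generate_expression(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def small_fits(small_dataset):
    _, matrix, design, _ = small_dataset
    fits = fit_gene_models(matrix.to_log2(pseudo=0.0), design)
    params = estimate_prior(fits)
    return fits, params
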