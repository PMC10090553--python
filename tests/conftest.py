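"""Shared fixtures: tiny matrices and annotation tables built in memory."""
import numpy as np
import pandas as pd
import pytest

from codepnet import MatrixTable, ScnAnnotation


@pytest.fixture
def tiny_matrix() -> MatrixTable:
    df = pd.DataFrame(
        [[-0.5, 0.1], [-0.3, 0.0]],
        index=pd.Index(["RET", "ZBTB7A"], name="gene"),
        columns=["L1", "L2"],
    )
    return MatrixTable(df)


@pytest.fixture
def small_annotation() -> ScnAnnotation:
    table = pd.DataFrame(
        {
            "scn_score": [2.0, -1.0, 1.1, 0.3],
            "lineage": ["SCLC", "OTHER", "SCLC", "OTHER"],
        },
        index=pd.Index(["A", "B", "C", "D"], name="cell_line"),
    )
    return ScnAnnotation(table)


def random_matrix(n_genes: int, n_samples: int, seed: int,
                  missing_rate: float = 0.0) -> MatrixTable:
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((n_genes, n_samples))
    if missing_rate:
        vals = np.where(rng.random(vals.shape) < missing_rate, np.nan, vals)
    df = pd.DataFrame(
        vals,
        index=pd.Index([f"G{i:04d}" for i in range(n_genes)], name="gene"),
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )
    return MatrixTable(df)
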