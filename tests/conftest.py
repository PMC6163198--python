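from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cilioprior.de import ExpressionDataset

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def limma_fixture() -> ExpressionDataset:
    """Tiny 30-probe, 4v5 expression matrix whose moderated-test output was
    cross-checked once against an independent reference implementation; the
    reference numbers live in limma_oracle.tsv."""
    mat = pd.read_csv(DATA / "limma_fixture.tsv", sep="\t", index_col=0)
    groups = pd.Series(["FTE"] * 4 + ["HGSOC"] * 5, index=mat.columns)
    return ExpressionDataset(matrix=mat, groups=groups, name="limma_fixture")


@pytest.fixture(scope="session")
def limma_oracle() -> pd.DataFrame:
    return pd.read_csv(DATA / "limma_oracle.tsv", sep="\t").set_index("probe")


def make_dataset(rng, n_probes=200, n1=5, n2=5, d0=4.0, s0_sq=0.05,
                 de_idx=(), effect=0.0, name="sim") -> ExpressionDataset:
    """Small expression dataset under the inverse-chi-square variance model."""
    sigma2 = s0_sq * d0 / rng.chisquare(d0, size=n_probes)
    mat = 7.0 + rng.normal(size=(n_probes, n1 + n2)) * np.sqrt(sigma2)[:, None]
    for i in de_idx:
        mat[i, n1:] += effect
    samples = [f"F{i}" for i in range(n1)] + [f"H{i}" for i in range(n2)]
    frame = pd.DataFrame(mat, index=[f"P{i:04d}" for i in range(n_probes)], columns=samples)
    groups = pd.Series(["FTE"] * n1 + ["HGSOC"] * n2, index=samples)
    return ExpressionDataset(matrix=frame, groups=groups, name=name)
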