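import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from prognosig import ClinicalTable, ExpressionMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """3 genes x 4 patients with one missing cell."""
    values = pd.DataFrame(
        [
            [0.5, -0.2, 0.1, np.nan],
            [0.3, 0.3, 0.3, 0.3],
            [-1.0, 2.0, 0.0, -0.5],
        ],
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
        columns=["P1", "P2", "P3", "P4"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def toy_clinical() -> ClinicalTable:
    data = pd.DataFrame(
        {
            "time_years": [5.0, 13.0, 4.0, 14.5],
            "death_event": [True, False, False, True],
        },
        index=pd.Index(["P1", "P2", "P3", "P4"], name="patient_id"),
    )
    return ClinicalTable(data)


def random_levels(rng: np.random.Generator, n_genes: int, n_patients: int) -> pd.DataFrame:
    """Random discretized matrix with levels in {-1, 0, +1}."""
    levels = rng.integers(-1, 2, size=(n_genes, n_patients)).astype(np.int8)
    return pd.DataFrame(
        levels,
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"p{j:03d}" for j in range(n_patients)],
    )
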