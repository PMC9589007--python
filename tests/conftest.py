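import numpy as np
import pandas as pd
import pytest

from tissueprot.containers import IntensityMatrix
from tissueprot.synthetic import (
    CohortSpec,
    SignalSpec,
    generate_cohort,
    generate_gene_sets,
    generate_proteome,
)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Two-tissue cohort with the study-like group structure, small counts."""
    return generate_cohort(
        CohortSpec(n_per_group=(8, 7, 6), tissues=("islets", "liver"), seed=7)
    )


@pytest.fixture(scope="session")
def small_sets():
    return generate_gene_sets(12, size_range=(8, 20), universe_size=300, seed=8)


@pytest.fixture(scope="session")
def small_proteome(small_cohort, small_sets):
    """Complete matrices + truth with one planted T2D-responsive set."""
    signal = SignalSpec(planted_sets=(("SET0003", 1.0, "T2D"),))
    return generate_proteome(small_cohort, 300, signal, small_sets, seed=9)


@pytest.fixture()
def toy_matrix() -> IntensityMatrix:
    """4 proteins x 5 samples log2 matrix with two missing cells."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(20, 2, size=(4, 5)),
        index=pd.Index([f"P{i}" for i in range(4)], name="protein_id"),
        columns=[f"s{j}" for j in range(5)],
    )
    values.iloc[0, 1] = np.nan
    values.iloc[2, 4] = np.nan
    return IntensityMatrix(values, tissue="liver", scale="log2")
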