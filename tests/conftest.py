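import numpy as np
import pandas as pd
import pytest

import psma_multiomics as pm


@pytest.fixture(scope="session")
def default_cohort() -> pm.SyntheticCohort:
    """One paper-schema cohort (n=65), biopsy grade informative."""
    return pm.generate_cohort(pm.CohortConfig(seed=42))


@pytest.fixture(scope="session")
def default_table(default_cohort) -> pm.OmicsFeatureTable:
    return pm.cohort_design_matrix(default_cohort)


@pytest.fixture(scope="session")
def null_cohort() -> pm.SyntheticCohort:
    """Label-independent cohort: no planted effects, biopsy grade decoupled."""
    return pm.generate_cohort(pm.CohortConfig(seed=7, bx_informative=False))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_table() -> pm.OmicsFeatureTable:
    """Small dense table with one strongly informative feature."""
    r = np.random.default_rng(5)
    n = 60
    y = pd.Series(r.integers(0, 2, n), index=[f"P{i:03d}" for i in range(n)])
    data = pd.DataFrame(
        {f"noise_{j}": r.normal(size=n) for j in range(6)}, index=y.index
    )
    data["signal"] = r.normal(size=n) + 2.5 * y
    cats = {c: "radiomics" for c in data.columns}
    return pm.OmicsFeatureTable(data=data, categories=cats, labels=y)
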