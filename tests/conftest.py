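import numpy as np
import pandas as pd
import pytest

from bcsurv import (
    SyntheticCohortSpec,
    SyntheticExpressionSpec,
    generate_cohort,
    generate_expression,
)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(SyntheticCohortSpec(n_subjects=120, seed=7))


@pytest.fixture(scope="session")
def planted_expression():
    """Two planted metagenes, modest size for fast factorization tests."""
    spec = SyntheticExpressionSpec(n_samples=60, seed=11, n_genes=120,
                                   rank=2, separation=4.0, noise_sd=0.5)
    return generate_expression(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
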