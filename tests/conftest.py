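import numpy as np
import pandas as pd
import pytest

from mycstratify.containers import ExpressionMatrix
from mycstratify.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Default study conditions with a reduced background for fast tests."""
    return CohortConfig(n_background_genes=200, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full default study conditions (55 patients, 1000 background genes)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture
def toy_matrix():
    """3 genes x 3 samples linear matrix with easily hand-checked values."""
    df = pd.DataFrame(
        {
            "s1": [2.0, 1.0, 4.0],
            "s2": [3.0, 1.0, 4.0],
            "s3": [5.0, 2.0, 8.0],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(df, scale="linear")


@pytest.fixture(scope="session")
def null_cohort_frame():
    """A no-signal expression matrix: every gene i.i.d. across samples."""
    rng = np.random.default_rng(2024)
    genes = [f"G{i:04d}" for i in range(300)]
    samples = [f"N{i:03d}" for i in range(30)]
    values = rng.normal(7.0, 1.0, size=(300, 30))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            scale="log2")
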