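import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hgsoctx.synthdata import SyntheticConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


#: desk-scale config used by most integration-style tests
SMALL_CONFIG = SyntheticConfig(
    n_samples=60,
    n_genes=600,
    markers_per_subtype=40,
    n_immune_genes=40,
    n_cis_genes=40,
    n_trans_hubs=2,
    trans_targets_per_hub=8,
    n_cga_genes=40,
    n_survival_genes=4,
    n_coexpression_modules=10,
    seed=123,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_expression():
    """4 genes x 4 samples with simple structure."""
    from hgsoctx.io_formats import ExpressionMatrix

    data = pd.DataFrame(
        {
            "S1": [1.0, 10.0, 5.0, 0.0],
            "S2": [2.0, 20.0, 5.0, 0.0],
            "S3": [3.0, 30.0, 5.0, 0.0],
            "S4": [4.0, 40.0, 5.0, 0.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return ExpressionMatrix(data)
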