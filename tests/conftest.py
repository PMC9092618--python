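import numpy as np
import pandas as pd
import pytest

from odorqspr import SyntheticSpec, make_study, PipelineConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """An 85-compound synthetic study shared by read-only tests."""
    compounds, X, truth = make_study(SyntheticSpec(seed=42))
    return compounds, X, truth


@pytest.fixture()
def fast_pipeline_config():
    """Pipeline configuration scaled for test runtime."""
    return PipelineConfig(gfa_iterations=600, n_permutations=20, seed=5)


@pytest.fixture()
def random_xy(rng):
    """A well-conditioned 40x6 regression problem."""
    X = pd.DataFrame(
        rng.standard_normal((40, 6)), columns=[f"v{j}" for j in range(6)]
    )
    y = 1.5 * X["v0"].to_numpy() - 0.8 * X["v3"].to_numpy() + rng.normal(0, 0.3, 40)
    return X, y
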