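import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20170731)


@pytest.fixture
def small_matrix(rng):
    """20 genes x 12 samples with positive means and nonzero variance."""
    values = rng.normal(8.0, 1.0, size=(20, 12))
    return pd.DataFrame(
        values,
        index=[f"g{i:02d}" for i in range(20)],
        columns=[f"s{j}" for j in range(12)],
    )
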