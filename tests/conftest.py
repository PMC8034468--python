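import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_matrix() -> pd.DataFrame:
    """3 genes x 2 samples with a zero in each sample."""
    return pd.DataFrame(
        [[1.0, 2.0], [0.0, 5.5], [3.3, 0.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
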