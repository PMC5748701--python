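import numpy as np
import pandas as pd
import pytest

from seromir.synthdata import SynthConfig, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_counts():
    """2-feature x 2-sample integer count matrix."""
    return pd.DataFrame(
        [[10, 20], [5, 0]],
        index=["mir-a", "mir-b"],
        columns=["s1", "s2"],
    )


@pytest.fixture
def toy_meta():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4", "s5", "s6"],
            "condition": ["control", "control", "control", "case", "case", "case"],
            "family1": [1, 0, 0, 1, 0, 0],
            "family2": [0, 1, 0, 0, 1, 0],
            "absorbance_414": [1.0, 2.0, 0.8, 3.0, 1.5, 0.6],
        }
    ).set_index("sample_id", drop=False)


@pytest.fixture(scope="session")
def default_synth():
    """One default-scale simulated dataset shared across tests."""
    return simulate_counts(SynthConfig(seed=11))
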