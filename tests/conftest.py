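import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PRINTED_FLOOD_MLE = np.array([28.3805432, 29.0062276, 5.2899143, 0.1774844])
CARBON_MLE = np.array([0.3731249, 2.4058010, 1.3198053])


@pytest.fixture(scope="session")
def flood():
    from adequacy.datasets import load_flood

    return load_flood()


@pytest.fixture(scope="session")
def flood_mle():
    return PRINTED_FLOOD_MLE.copy()


@pytest.fixture(scope="session")
def carbon_mle():
    return CARBON_MLE.copy()
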