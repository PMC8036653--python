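import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drugprox import EmbeddingMatrix

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture()
def random_embedding() -> EmbeddingMatrix:
    """30 proteins with fixed random Gaussian vectors (d=8)."""
    rng = np.random.default_rng(42)
    nodes = [f"P{i + 1:06d}" for i in range(30)]
    return EmbeddingMatrix(nodes, rng.normal(size=(30, 8)))
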