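import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ploidymc import CountMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def toy_counts() -> CountMatrix:
    """Two samples x two chromosomes, second sample skewed."""
    return CountMatrix(np.array([[10, 10], [10, 30]]), ("A", "B"), ("chr1", "chr2"))


@pytest.fixture
def rank_one_counts() -> CountMatrix:
    """Outer-product structure: no dosage signal."""
    return CountMatrix(np.array([[10, 20], [30, 60]]), ("A", "B"), ("chr1", "chr2"))
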