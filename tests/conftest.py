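import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160824)


def random_two_class_table(rng, max_rows=9, max_count=30):
    """Random I x 2 count table with both column totals positive."""
    while True:
        I = rng.integers(2, max_rows + 1)
        counts = rng.integers(0, max_count + 1, size=(I, 2))
        if counts.sum() > 0 and (counts.sum(axis=0) > 0).all():
            return counts
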