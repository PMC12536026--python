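import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def marker_table():
    from glympipe.cohort import CohortConfig, generate_marker_table

    return generate_marker_table(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def strong_pairs():
    """84 preprocessed subject pairs with strong derivative coupling."""
    from glympipe.cohort import SignalConfig, generate_signal_pair
    from glympipe.preprocess import preprocess

    pairs = []
    for child in np.random.SeedSequence(7).spawn(84):
        g, c = generate_signal_pair(
            SignalConfig(coupling_strength=0.9),
            rng=np.random.default_rng(child),
        )
        pairs.append((preprocess(g), preprocess(c)))
    return pairs
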