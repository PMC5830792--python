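import numpy as np
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

from mixsis import ConditionalRates, EffectiveRates


@pytest.fixture(scope="session")
def fig_exemplars():
    """The five showcase (lambda1, lambda2) pairs with their regimes."""
    return {
        "A": EffectiveRates(0.5, 0.9),
        "B": EffectiveRates(0.25, 2.0),
        "C": EffectiveRates(0.3, 4.0),
        "D": EffectiveRates(1.0, 4.0),
        "E": EffectiveRates(2.0, 5.0),
    }


@pytest.fixture(scope="session")
def conditional_groups():
    """Showcase state-conditional rate bundles (quoted in percent)."""
    return (ConditionalRates.from_percent(1, 15, 60, 70),
            ConditionalRates.from_percent(1, 80, 1, 20))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
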