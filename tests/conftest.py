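import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import specs

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_motifs():
    return specs.random_motifs(12, seed=101)


@pytest.fixture(scope="session")
def toy_library(toy_motifs):
    return specs.build_library(toy_motifs, seed=202)


@pytest.fixture(scope="session")
def five_bins():
    """A simple five-bin scheme with round mean fluorescences."""
    return specs.BinScheme(
        edges=np.array([-np.inf, 10.0, 100.0, 1000.0, 5000.0, np.inf]),
        means=np.array([5.0, 50.0, 500.0, 2000.0, 10000.0]),
    )


@pytest.fixture(scope="session")
def small_screen(toy_library):
    """A 24-construct simulated screen with moderate depth, shared read-only."""
    truth = specs.make_ground_truth(toy_library.construct_ids(), seed=303,
                                    n_specific={"A": 3})
    screen = specs.simulate_screen(truth, depth=50_000, seed=404)
    return screen


@pytest.fixture(scope="session")
def small_counts(small_screen):
    cm = specs.CountMatrix.from_screen(small_screen).normalize(pseudocount=0.5)
    filtered, _ = cm.replicate_filter()
    return filtered
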