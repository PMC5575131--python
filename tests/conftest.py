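import numpy as np
import pytest

from xanthotilt.pipeline import demo_pmf
from xanthotilt.synthetic import paper_window_centers, simulate_umbrella_run


@pytest.fixture(scope="session")
def reference_pmf():
    """The asymmetric tilt free-energy landscape used as simulation truth."""
    return demo_pmf()


@pytest.fixture(scope="session")
def umbrella_windows(reference_pmf):
    """One full 11-window umbrella run on the reference landscape.

    Session-scoped: the Langevin simulation is the expensive step and the
    downstream tests only read the windows.
    """
    return simulate_umbrella_run(
        reference_pmf, paper_window_centers(), spring_k=3.0,
        n_steps=150_000, seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
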