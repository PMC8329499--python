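import numpy as np
import pytest
from hypothesis import settings

from sedom.simulate import CouplingSpec, SimulationConfig, simulate_study

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A scaled-down study used across tests: same design, smaller universe."""
    kw = dict(
        seed=seed,
        n_formulas=600,
        n_asvs=150,
        n_differential=40,
        n_unique_upper=20,
        n_unique_deep=20,
        couplings=(
            CouplingSpec("bacteria_lowDBE", "Bacteria", 15, 10, "dbe_low", 0.9, -0.4),
            CouplingSpec("archaea_highDBE", "Archaea", 15, 10, "dbe_high", 0.9, 0.4),
        ),
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config(), with_peaklists=False)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
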