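import pytest

from bindover.pipeline import analyze_bundle
from bindover.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def bundle():
    """One default-scale simulated bundle shared across the suite."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def summary(bundle):
    """Full pipeline summary on the shared bundle."""
    return analyze_bundle(bundle)
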