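import numpy as np
import pytest

from richsplit import (
    ScenarioConfig,
    SADParams,
    catch_probabilities,
    draw_sample,
    run_sweep,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fig1_assemblage():
    """Uneven lognormal assemblage: S=60, mean abundance 1000, cv=0.95."""
    return catch_probabilities(SADParams.create("lognormal", 60, 1000.0, 0.95))


@pytest.fixture(scope="session")
def medium_sample(fig1_assemblage):
    """A 500-individual sample from the uneven assemblage."""
    return draw_sample(fig1_assemblage, 500, seed=20160922)


@pytest.fixture(scope="session")
def main_sweep():
    """Scaled-down main lognormal sweep shared by the acceptance-level tests.

    200 assemblages per cv over the full 0.15..1.15 grid, 200 draws per
    assemblage, 50 random 2-way splits per draw; the four estimators entering
    the two threshold pairs.
    """
    config = ScenarioConfig(
        n_assemblages=200,
        n_draws=200,
        n_splits=50,
        estimators=("chao1_bc", "jk1a", "chao2_bc", "jk1i"),
        seed=1,
    )
    return run_sweep(config)
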