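import numpy as np
import pytest

from clpnet import (EstimationConfig, SimulationConfig, TrueNetworkSpec,
                    build_network, generate_true_network, simulate_panel)


@pytest.fixture(scope="session")
def sparse_spec():
    """Ground truth with 10 strong positive cross-lagged edges."""
    return generate_true_network(10, effect_range=(0.6, 0.9), seed=7,
                                 positive_only=True, covariate_scale=0.1)


@pytest.fixture(scope="session")
def clean_panel(sparse_spec):
    """Complete-data panel from the sparse spec (no missingness)."""
    cfg = SimulationConfig(n_participants=1200, seed=11)
    return simulate_panel(sparse_spec, cfg)


@pytest.fixture(scope="session")
def fitted_network(clean_panel):
    return build_network(clean_panel, EstimationConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
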