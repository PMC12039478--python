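import numpy as np
import pytest

from bgbottleneck.basis import BasisPrototype, build_shifted_basis
from bgbottleneck.rnn import ConnectivityConfig, InputProtocol, build_connectivity
from bgbottleneck.synthetic import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def ring_basis():
    """The 5-output, 20-target overlapping ring basis of the cortical demo."""
    return build_shifted_basis(BasisPrototype.step(), b=5, n=20, topology="ring")


@pytest.fixture(scope="session")
def stable_network():
    """Inhibition-dominant (50:50 E/I) network used for dynamics tests."""
    return build_connectivity(ConnectivityConfig(seed=0), n_units=200,
                              excitatory_fraction=0.5)


@pytest.fixture(scope="session")
def protocol(ring_basis):
    return InputProtocol.sample(ring_basis, n_units=200, seed=0)


@pytest.fixture(scope="session")
def tuned_study():
    """Synthetic tracer study with ground-truth ratios 154 (upper) / 13 (weighted)."""
    config = GeneratorConfig(target_ratio=154.0, target_weighted_ratio=13.0, seed=7)
    catalog, experiments, truth = generate_study(config)
    return config, catalog, experiments, truth


@pytest.fixture(scope="session")
def small_study():
    """Small, fast synthetic study for invariant checks."""
    config = GeneratorConfig(n_regions=50, n_true_targets=12, seed=3)
    catalog, experiments, truth = generate_study(config)
    return config, catalog, experiments, truth
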