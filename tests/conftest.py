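import numpy as np
import pytest

import mdinvert as mi


@pytest.fixture(scope="session")
def phantom():
    return mi.default_phantom()


@pytest.fixture(scope="session")
def protocol():
    """Full-size synthetic protocol (139 measurements)."""
    return mi.make_protocol(seed=1)


@pytest.fixture(scope="session")
def small_protocol():
    """Cheap 40-measurement protocol for unit tests."""
    return mi.make_protocol(n_meas=40, seed=2)


@pytest.fixture(scope="session")
def gt_signal(phantom, protocol):
    return phantom.signal(protocol)


@pytest.fixture(scope="session")
def small_signal(phantom, small_protocol):
    return phantom.signal(small_protocol)


@pytest.fixture(scope="session")
def small_plan(small_protocol):
    return mi.draw_bootstrap_plan(small_protocol.M, 5, seed=7)


@pytest.fixture(scope="session")
def fast_mc_config():
    """Reduced-round MC settings for cheap structural tests."""
    return mi.McConfig(np_rounds=6, nm_rounds=4, nb=5, seed=7)


@pytest.fixture(scope="session")
def small_dictionary(phantom, small_protocol, small_plan, fast_mc_config):
    rng = np.random.default_rng(11)
    train, _ = mi.generate_training_set(
        phantom, 0.2, (130, 30), 10, small_protocol, rng)
    return mi.build_dictionary(train, small_protocol, small_plan,
                               fast_mc_config, n_reps=6, seed=11)
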