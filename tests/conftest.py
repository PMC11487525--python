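"""Shared fixtures: kernels warmed once, one trained reservoir per session.

Unit tests run on reduced problem sizes (shorter listening/training windows
than the long-run defaults) so the whole suite stays desk-scale; the windows
still satisfy the >= 2N-column conditioning requirement.
"""

import numpy as np
import pytest

from rcswitching import (RCParams, ReservoirRealization, TaskPair,
                         TrainConfig, train_seeing_double)
from rcswitching._kernels import warm_up


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    warm_up()


@pytest.fixture(scope="session")
def params():
    return RCParams()  # gamma=10, sigma=0.1, tau=0.01


@pytest.fixture(scope="session")
def scaled_train_config():
    """Short but well-conditioned windows: 10,000 columns >> 2N = 200."""
    return TrainConfig(t_listen=10.0, t_train=110.0)


@pytest.fixture(scope="session")
def realization():
    return ReservoirRealization.generate(n_nodes=100, connection_prob=0.04,
                                         spectral_radius=0.4, seed=1)


@pytest.fixture(scope="session")
def task8():
    return TaskPair.seeing_double(8.0)


@pytest.fixture(scope="session")
def trained_rc(realization, params, task8, scaled_train_config):
    """A multifunctional reservoir: x_cen = 8, rho = 0.4, seed 1."""
    return train_seeing_double(realization, params, task8.orbit_A,
                               task8.orbit_B, scaled_train_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
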