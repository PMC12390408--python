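import logging

import numpy as np
import pytest

from freezekin.pipeline import run_trial
from freezekin.synthetic import (
    GaitModelParams,
    analysis_config,
    generate_trajectory,
    simulate_imu,
)

logging.getLogger("freezekin").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_params():
    return GaitModelParams(n_strides=10, seed=0)


@pytest.fixture(scope="session")
def default_trial(default_params):
    """(truth, traj, rec) for the default 10-stride noise-free trial."""
    truth, traj = generate_trajectory(default_params)
    rec = simulate_imu(traj, default_params)
    return truth, traj, rec


@pytest.fixture(scope="session")
def default_result(default_trial):
    _, _, rec = default_trial
    return run_trial(rec, analysis_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
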