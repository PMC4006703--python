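"""Shared fixtures: the packaged model, calibration and synthetic data.

Everything heavy is session-scoped; the model geometry and apportionment
matrices are pure functions of the packaged configuration, so sharing
them across tests is safe.
"""

import numpy as np
import pytest

import lipogrid as lg

MEASURED_VLDL_TG_RATE = 60.0  # nmol/h, the packaged study condition


@pytest.fixture(scope="session")
def model():
    return lg.default_model()


@pytest.fixture(scope="session")
def params():
    return lg.default_parameters()


@pytest.fixture(scope="session")
def calibration():
    return lg.default_calibration()


@pytest.fixture(scope="session")
def boundaries():
    return lg.default_boundaries()


@pytest.fixture(scope="session")
def simulator(model, boundaries):
    return lg.Simulator(model, boundaries)


@pytest.fixture(scope="session")
def est_opts():
    return lg.default_estimation_options()


@pytest.fixture(scope="session")
def coupled(model, params):
    return lg.couple_submodels(model, params, MEASURED_VLDL_TG_RATE)


@pytest.fixture(scope="session")
def noiseless_data(simulator, params):
    spec = lg.SyntheticSpec(
        params=params,
        vldl_tg_production=MEASURED_VLDL_TG_RATE,
        seed=11,
        noise_cv=0.0,
    )
    return lg.generate_synthetic_profile(spec, simulator)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
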