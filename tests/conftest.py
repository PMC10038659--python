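import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eccquant as eq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_db():
    return eq.generate_protein_db(5, 120, seed=1)


@pytest.fixture()
def noise_free_cfg():
    return eq.SimConfig(
        seed=3,
        reporter_noise_cv=0.0,
        peptide_ionization_sigma=0.5,
        prm_cv=0.0,
        tic_drift_cv=0.0,
        missingness_rate=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
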