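import numpy as np
import pytest

from tumorhab import phantom, pipeline


def small_config(**kw) -> phantom.PhantomConfig:
    """Desk-scale phantom: ~120 tumor voxels, fast elasticity solves."""
    defaults = dict(grid_shape=(20, 20, 10),
                    tumor_semiaxes_mm=(4.0, 4.0, 3.5),
                    breast_semiaxes_mm=(8.5, 8.5, 6.0),
                    stress_interval_days=7.0, dt_days=0.5, seed=7)
    defaults.update(kw)
    return phantom.PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def small_patient() -> phantom.VirtualPatient:
    """One noiseless small-grid virtual patient, shared across tests."""
    return phantom.generate_virtual_patient(small_config())


@pytest.fixture(scope="session")
def small_patient_features(small_patient):
    return pipeline.compute_patient_features(small_patient)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three noiseless small-grid patients."""
    return phantom.generate_cohort(3, small_config(), seed=5)


def rng(seed=0):
    return np.random.default_rng(seed)
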