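import numpy as np
import pytest
from hypothesis import settings

from datquant.phantom import (
    AcquisitionConfig,
    build_phantom,
    fill_activities,
    simulate_spect,
)
from datquant.study import StudyConfig, make_fixture, run_study

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny():
    """Tiny (48^3, 4 mm) phantom with one noisy acquisition at 10:1."""
    return make_fixture("tiny", seed=0)


@pytest.fixture(scope="session")
def default_geometry():
    return build_phantom()


@pytest.fixture(scope="session")
def noiseless_acq(default_geometry):
    """Paper-scale noiseless acquisition at 10:1 with the default blur chain."""
    activity, record = fill_activities(default_geometry, 10, jitter_cv=0.0, seed=0)
    return simulate_spect(
        activity, AcquisitionConfig(seed=0), default_geometry, fill=record,
        noiseless=True,
    )


@pytest.fixture(scope="session")
def zero_blur_acq(default_geometry):
    """Paper-scale noiseless, blur-free acquisition at 10:1."""
    activity, record = fill_activities(default_geometry, 10, jitter_cv=0.0, seed=0)
    cfg = AcquisitionConfig(psf_fwhm=0.0, post_filter_fwhm=0.0, seed=0)
    return simulate_spect(activity, cfg, default_geometry, fill=record,
                          noiseless=True)


@pytest.fixture(scope="session")
def default_study():
    """The full default 23-acquisition study (fixed master seed)."""
    return run_study(StudyConfig(master_seed=0))


def rng(seed=0):
    return np.random.default_rng(seed)
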