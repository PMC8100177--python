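import numpy as np
import pytest

from rnflgray.synthdata import (
    GenerativeParams,
    render_bscan,
    sample_cohort,
)


@pytest.fixture(scope="session")
def default_params() -> GenerativeParams:
    return GenerativeParams(seed=11)


@pytest.fixture(scope="session")
def small_cohort(default_params):
    return sample_cohort(default_params, 8)


@pytest.fixture(scope="session")
def speckled_eye(default_params, small_cohort):
    """One rendered eye with default speckle, plus its ground truth."""
    truth = small_cohort[0]
    image, gt = render_bscan(truth, default_params)
    return truth, image, gt


@pytest.fixture(scope="session")
def noise_free_params() -> GenerativeParams:
    return GenerativeParams(seed=11, speckle_shape=None)


@pytest.fixture(scope="session")
def noise_free_eye(noise_free_params):
    truth = sample_cohort(noise_free_params, 3)[1]
    image, gt = render_bscan(truth, noise_free_params)
    return truth, image, gt


@pytest.fixture(scope="session")
def sector_widths() -> np.ndarray:
    """Angular widths (degrees) in canonical sector order T,IT,IN,N,SN,ST."""
    return np.array([90.0, 45.0, 45.0, 90.0, 45.0, 45.0])
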