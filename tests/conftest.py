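import numpy as np
import pytest

from compartdwi import DEFAULT_SCHEME, IVIMParams, RSIParams, ivim_signal
from compartdwi.synthetic import generate_cohort


@pytest.fixture
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def malignant_ivim():
    """Malignant-class mean IVIM parameters (group descriptives)."""
    return IVIMParams(dt=0.662e-3, dp=0.022, f=0.235)


@pytest.fixture
def benign_ivim():
    return IVIMParams(dt=0.940e-3, dp=0.019, f=0.256)


@pytest.fixture
def malignant_rsi():
    """Malignant-class mean RSI contributions."""
    return RSIParams(c1=0.540, c2=1.826, c3=0.161)


@pytest.fixture
def malignant_signal(malignant_ivim):
    """Noiseless malignant voxel signal over the full b scheme, S0=1."""
    return np.asarray(ivim_signal(malignant_ivim, 1.0, DEFAULT_SCHEME.array))


@pytest.fixture(scope="session")
def small_cohort():
    """A small three-class lesion cohort shared by the statistics tests."""
    return generate_cohort(n_malignant=24, n_benign=14, n_normal=14,
                           voxels_per_lesion=10, snr=50, seed=0)
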