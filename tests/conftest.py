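import numpy as np
import pytest

from veinphase import AcquisitionParams, BloodGasParams, PhantomSpec, make_pair


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams(te=5e-3, b0=7.0)


@pytest.fixture(scope="session")
def blood():
    return BloodGasParams()


@pytest.fixture(scope="session")
def parallel_bundle():
    """Noiseless straight cylinder parallel to B0, Yv = 0.62."""
    spec = PhantomSpec(
        shape=(64, 64, 48), radius=4.0, yv_true=0.62, snr=None, mecho_snr=None
    )
    return spec, make_pair(spec)


@pytest.fixture(scope="session")
def small_vein_bundle():
    """Noiseless small perpendicular vein for Method III round trips."""
    spec = PhantomSpec(
        shape=(64, 64, 48), radius=2.5, length=40, axis=(1.0, 0.0, 0.0),
        yv_true=0.66, dyh_true=0.066, snr=None, mecho_snr=None,
    )
    return spec, make_pair(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
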