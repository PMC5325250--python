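import numpy as np
import pytest

from phmri.perfusion import signal_to_concentration
from phmri.synthetic import AcquisitionConfig, make_tissue_truth, simulate_dsc_signal


@pytest.fixture(scope="session")
def acq():
    """Noiseless desk-scale acquisition: 40 frames at 1.5 s, TE 45 ms."""
    return AcquisitionConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def delay_free_truth():
    """Small phantom with no bolus delay (exact-recovery regime)."""
    rng = np.random.default_rng(42)
    return make_tissue_truth(0.40, 320.0, 0.32, shape=(20, 20, 8), rng=rng, lesion_delay_s=0.0)


@pytest.fixture(scope="session")
def delay_free_conc(delay_free_truth, acq):
    dsc = simulate_dsc_signal(delay_free_truth, acq)
    return signal_to_concentration(dsc)
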