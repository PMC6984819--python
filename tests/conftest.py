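import numpy as np
import pytest

import autapse as ap


@pytest.fixture(scope="session")
def reference_cell():
    """Median human basket-cell model with the simulation reversal preset."""
    return ap.reference_human_cell()


@pytest.fixture(scope="session")
def noiseless_pair():
    """Noise-free control/blocker sweep pair with its ground truth."""
    truth = ap.default_ground_truth(noise_sd_pA=0.0)
    control, blocker = ap.generate_voltage_clamp_pair(truth)
    return truth, control, blocker


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
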