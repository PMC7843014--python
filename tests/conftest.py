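import numpy as np
import pytest

from depotflow import synth
from depotflow.transport import TransportParams


@pytest.fixture(scope="session")
def basis64():
    return synth.gen_basis_spectra(64, seed=1)


@pytest.fixture(scope="session")
def default_params():
    # D_E, Phi_ET, h_E fixed by the assay; h_T a typical thick-section height
    return TransportParams(D_T=2e-6, K_EV=0.0, h_T=0.5)


@pytest.fixture(scope="session")
def disk_image():
    return synth.gen_injection_image(side_px=256, disk_radius_px=60, n_lobes=0, seed=7)


@pytest.fixture(scope="session")
def lobed_image():
    return synth.gen_injection_image(side_px=256, disk_radius_px=60, n_lobes=4,
                                     lobe_gain=1.0, seed=7)
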