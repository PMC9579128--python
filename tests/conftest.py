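import numpy as np
import pytest

from gdnano.physics_tables import MATERIALS, REACTIONS, default_let_rbe_table
from gdnano.beam_transport import build_sobp, in_tumor_proton_spectrum


@pytest.fixture(scope="session")
def let_table():
    return default_let_rbe_table()


@pytest.fixture(scope="session")
def materials():
    return MATERIALS


@pytest.fixture(scope="session")
def channels():
    return REACTIONS


@pytest.fixture(scope="session")
def sobp_beam():
    return build_sobp(depth_window=(2.0, 3.0), n_peaks=11)


@pytest.fixture(scope="session")
def tumor_proton_spectrum(sobp_beam):
    return in_tumor_proton_spectrum(sobp_beam, (2.0, 3.0), seed=11)
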