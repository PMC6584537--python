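import numpy as np
import pytest

from ediacaran_o2.forcings import ForcingSnapshot
from ediacaran_o2.model import present_day_forcing, present_day_state
from ediacaran_o2.params import central_parameters, default_parameters


@pytest.fixture(scope="session")
def baseline_params():
    """Closed baseline draw (published base-model values)."""
    return default_parameters()


@pytest.fixture(scope="session")
def central_params():
    """Closed central draw of the sampled uncertainty space."""
    return central_parameters()


@pytest.fixture()
def reference_state(baseline_params):
    return present_day_state(baseline_params)


@pytest.fixture()
def reference_forcing():
    return present_day_forcing()


@pytest.fixture()
def ediacaran_forcing_snapshot():
    """A typical early-Ediacaran instant: vegetation off, reduced uplift."""
    return ForcingSnapshot(D=1.1, U=0.5, V=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
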