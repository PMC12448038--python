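import numpy as np
import pytest

from eegtelemetry import (ProtocolSpec, SignalParams, default_montage,
                          generate)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def default_recording(montage):
    """One full default session (five 2-min cycles, 20 min at 250 Hz)."""
    return generate(ProtocolSpec(), montage, SignalParams(seed=1))


@pytest.fixture(scope="session")
def short_recording(montage):
    """A one-cycle session (2 min eyes-closed + 2 min eyes-open)."""
    return generate(ProtocolSpec(n_cycles=1), montage, SignalParams(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
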