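import numpy as np
import pytest

from tdmri.acquisition import breast_protocol
from tdmri.impulsed import impulsed_signal


@pytest.fixture(scope="session")
def protocol():
    return breast_protocol()


@pytest.fixture(scope="session")
def acq_index(protocol):
    return [(s.label, b) for s in protocol.sequences for b in s.b_values]


@pytest.fixture(scope="session")
def forward_signals(protocol):
    """Noiseless forward-model signal vector aligned with acq_index."""

    def _signals(params):
        out = []
        for seq in protocol.sequences:
            out.extend(np.atleast_1d(impulsed_signal(params, seq, np.array(seq.b_values))))
        return np.array(out)

    return _signals
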