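import numpy as np
import pytest

import oisi
from oisi import preprocessing as pp
from oisi import synthetic_data as sd


@pytest.fixture(scope="session")
def protocol():
    return oisi.make_default_protocol()


@pytest.fixture(scope="session")
def default_gt():
    return oisi.GroundTruth()


@pytest.fixture(scope="session")
def noiseless_gt(default_gt):
    return default_gt.model_copy(update={"noise": default_gt.noise.noiseless()})


@pytest.fixture(scope="session")
def noiseless_stacks(protocol, noiseless_gt):
    return sd.simulate_recording(protocol, noiseless_gt)


@pytest.fixture(scope="session")
def noiseless_cond_means(noiseless_stacks):
    return {k: pp.condition_mean(pp.frame_ratio(st)) for k, st in noiseless_stacks.items()}


def make_stack(values, **kw):
    """Convenience FrameStack constructor for hand-built arrays."""
    return sd.FrameStack(values=np.asarray(values, dtype=float), **kw)
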