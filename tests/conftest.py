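import numpy as np
import pytest

from fernet.gradients import make_scheme
from fernet.simulator import make_phantom
from fernet.tensor import prolate_tensor, tensor_eigensystem


@pytest.fixture(scope="session")
def scheme():
    """Single-shell b=800 scheme, 30 dispersed directions, 3 b0 volumes."""
    return make_scheme(800.0, 30, n_b0=3)


@pytest.fixture(scope="session")
def wm_tensor():
    """Healthy-WM prolate tensor: FA 0.5, MD 7.7e-4 mm^2/s."""
    return prolate_tensor(0.5, 7.7e-4)


@pytest.fixture(scope="session")
def ramp_phantom(scheme, wm_tensor):
    """Small noise-free phantom: linear VF ramp 0 -> 1 along x.

    The first x-slab is pure tissue (WM reference), the last pure free
    water (CSF reference).
    """
    shape = (8, 5, 3)
    x = np.linspace(0.0, 1.0, shape[0])
    vf = np.broadcast_to(x[:, None, None], shape).copy()
    evals = tensor_eigensystem(wm_tensor)[0]
    dwi, truth = make_phantom(vf, evals, scheme, snr=None)
    brain = np.ones(shape, bool)
    wm = np.zeros(shape, bool)
    wm[0] = True
    csf = np.zeros(shape, bool)
    csf[-1] = True
    return dict(dwi=dwi, truth=truth, brain=brain, wm=wm, csf=csf,
                shape=shape, vf=vf)
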