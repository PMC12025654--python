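import numpy as np
import pytest
from skimage.morphology import dilation, disk

import mnvquant as m


@pytest.fixture(scope="session")
def tree0():
    return m.generate_vessel_tree(0)


@pytest.fixture(scope="session")
def mask0(tree0):
    return m.rasterize_network(tree0)


@pytest.fixture(scope="session")
def roi0(mask0):
    return m.MnvRoi(dilation(mask0, disk(4)))


@pytest.fixture(scope="session")
def noiseless_img(mask0):
    zero = m.NoiseParams(speckle=0.0, granularity=0.0)
    return m.synthesize_angiogram(mask0, zero, seed=0)


@pytest.fixture(scope="session")
def noisy_img(mask0):
    return m.synthesize_angiogram(mask0, seed=100)


@pytest.fixture(scope="session")
def cohort68():
    return m.generate_cohort(seed=1)


def make_line_skeleton(n=101, shape=(20, 120), row=10, col0=5):
    sk = np.zeros(shape, dtype=bool)
    sk[row, col0 : col0 + n] = True
    return sk
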