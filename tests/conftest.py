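import dataclasses

import numpy as np
import pytest

from shgquant.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """A 4 x 4 mm phantom at coarse pitch, cheap enough for unit tests."""
    return PhantomSpec(frame_px=(512, 512), pixel_size_um=8.0, stage=1, seed=1)


@pytest.fixture(scope="session")
def phantom_stage1(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_spec(base, **kw):
    return dataclasses.replace(base, **kw)
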