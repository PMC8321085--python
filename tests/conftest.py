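import numpy as np
import pytest

import dbtvis as dv
from dbtvis.sweep import study_transfer_function


@pytest.fixture(scope="session")
def phantom_spec():
    """The study's default phantom (frozen conditions, seed 0)."""
    return dv.PhantomSpec()


@pytest.fixture(scope="session")
def phantom_volume(phantom_spec):
    return dv.generate_phantom(phantom_spec)


@pytest.fixture(scope="session")
def study_tf(phantom_spec):
    return study_transfer_function(phantom_spec)


@pytest.fixture(scope="session")
def small_spec():
    """A small, cheap phantom for render/sweep plumbing tests."""
    return dv.PhantomSpec(
        volume_shape=(64, 48, 16),
        spacing=(0.17, 0.17, 1.0),
        disk_diameters=(3.0,),
        disk_centers=((5.0, 4.0, 8.0),),
        z_spread_sigma=2.0,
        noise_sigma=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_volume(small_spec):
    return dv.generate_phantom(small_spec)
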