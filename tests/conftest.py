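import numpy as np
import pytest

from newtongn import FeatureLayout, SystemSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(params=["spring", "charge", "orbital"])
def smooth_spec(request):
    """Specs for the laws that are differentiable everywhere."""
    return SystemSpec(law=request.param, d=2)


@pytest.fixture
def spring_spec():
    return SystemSpec(law="spring", d=2)


@pytest.fixture
def lj_spec():
    return SystemSpec(law="lj", d=3)


@pytest.fixture
def layout_2d():
    return FeatureLayout(d=2)


@pytest.fixture
def layout_lj():
    return FeatureLayout(d=3, include_charge=False, include_displacement=True)
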