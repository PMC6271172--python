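import numpy as np
import pytest

from bleachmap.pixelfit import fit_stack
from bleachmap.synthgen import SynthSpec, render_stack


@pytest.fixture(scope="session")
def small_spec():
    """Down-scaled shading phantom used by most fitting tests."""
    return SynthSpec(shape=(48, 48), seed=7)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return render_stack(small_spec)


@pytest.fixture(scope="session")
def small_fit(small_stack):
    stack, _truth = small_stack
    return fit_stack(stack, "monoexp")


@pytest.fixture
def rng():
    return np.random.default_rng(20140729)
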