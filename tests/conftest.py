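import numpy as np
import pytest

import nailmorph as nm


@pytest.fixture(scope="session")
def study_cfg():
    return nm.study_config(seed=0)


@pytest.fixture(scope="session")
def gradient_phantom():
    """Default craniocaudal gradient (0.40 -> 0.10), one specimen."""
    spec = nm.PhantomSpec(seed=3)
    return nm.make_trabecular_phantom(spec)


@pytest.fixture(scope="session")
def const_phantom():
    """Constant designed fraction 0.20, one specimen."""
    spec = nm.PhantomSpec(bvtv_profile=0.20, seed=42)
    vol, lm, truth = nm.make_trabecular_phantom(spec)
    return spec, vol, lm, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
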