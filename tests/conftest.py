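import numpy as np
import pytest

from conceptboot.curricula import build_curriculum


@pytest.fixture(scope="session")
def construct_curriculum():
    return build_curriculum("construct")


@pytest.fixture(scope="session")
def all_curricula():
    return {
        name: build_curriculum(name)
        for name in ("construct", "deconstruct", "combine", "flip")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
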