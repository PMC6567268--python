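import numpy as np
import pytest

from angioprint.stacks_io import BinaryStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_binary(voxels, spacing=0.64) -> BinaryStack:
    return BinaryStack(voxels=np.asarray(voxels, dtype=bool), spacing_iso=spacing)


@pytest.fixture
def random_stack(rng):
    """A connected-ish random binary stack for property tests."""
    v = rng.random((12, 14, 16)) < 0.08
    v[6, 7, 8] = True  # never empty
    return make_binary(v)
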