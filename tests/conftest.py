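import numpy as np
import pytest

from pulmoct.phantom import GridSpec, NoduleSpec, generate_sphere_mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fine_grid():
    """Isotropic 0.05 mm grid large enough for a 9 mm nodule."""
    return GridSpec(shape=(220, 220, 220), spacing_mm=(0.05, 0.05, 0.05))


@pytest.fixture
def sphere_9mm(fine_grid):
    spec = NoduleSpec(kind="sphere", diameter_mm=9.0, center_mm=(5.5, 5.5, 5.5))
    return generate_sphere_mask(spec, fine_grid)
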