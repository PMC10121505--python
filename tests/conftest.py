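import numpy as np
import pytest

from spinemorph.phantom import Deformity, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def healthy_phantom():
    """Default 7-vertebra phantom, no noise, no deformities."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def deformed_phantom():
    """5-vertebra phantom with one of each severe deformity, mild tilts."""
    config = PhantomConfig(
        n_vertebrae=5,
        deformities=(
            Deformity(),
            Deformity("wedge", 0.75),
            Deformity("concave", 0.75),
            Deformity("crush", 0.75),
            Deformity(),
        ),
        tilts_deg=(0.0, 5.0, -5.0, 10.0, 0.0),
    )
    return config, generate_phantom(config)


def make_rect_mask(height_px: int, width_px: int,
                   shape=(40, 40), offset=(5, 5)) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    r0, c0 = offset
    mask[r0:r0 + height_px, c0:c0 + width_px] = True
    return mask


@pytest.fixture
def rect_mask():
    return make_rect_mask
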