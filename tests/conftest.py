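import numpy as np
import pytest

from cequal.frame import Frame, full_fov
from cequal.frame_scoring import GlcmParams
from cequal.pipeline import calibrate


def grey_frame(values: np.ndarray, n_levels: int | None = None) -> Frame:
    """Frame with identical channels (luminance == pixel value), full mask."""
    v = np.asarray(values, dtype=np.uint8)
    rgb = np.stack([v, v, v], axis=-1)
    return Frame(rgb=rgb, fov=full_fov(v.shape[1], v.shape[0]))


def level_value(level: int, n_levels: int) -> int:
    """Mid-bin grey value mapping exactly onto a quantisation level."""
    return min(255, int((level + 0.5) * 256 / n_levels))


@pytest.fixture(scope="session")
def glcm_params():
    return GlcmParams()


@pytest.fixture(scope="session")
def calibration():
    """Contrast threshold calibrated once on the standard synthetic set."""
    return calibrate(seed=1, n=500)
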