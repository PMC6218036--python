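import math

import numpy as np
import pytest

from photobf import anatomy, imaging, pipeline, synthetic



def green_canvas(rows: int, cols: int) -> np.ndarray:
    img = np.zeros((rows, cols, 3), dtype=np.uint8)
    img[...] = synthetic.GREEN
    return img


def rect_mask(w_cm: float, h_cm: float, scale: float) -> np.ndarray:
    """Axis-aligned rectangle rendered at pixel centers."""
    nr, nc = int(math.ceil(h_cm / scale)) + 4, int(math.ceil(w_cm / scale)) + 4
    y = (np.arange(nr) + 0.5) * scale - nr * scale / 2
    x = (np.arange(nc) + 0.5) * scale - nc * scale / 2
    yy, xx = np.meshgrid(y, x, indexing="ij")
    return (np.abs(yy) <= h_cm / 2) & (np.abs(xx) <= w_cm / 2)


def disk_mask(r_cm: float, scale: float) -> np.ndarray:
    n = int(math.ceil(2 * r_cm / scale)) + 4
    c = (np.arange(n) + 0.5) * scale - n * scale / 2
    yy, xx = np.meshgrid(c, c, indexing="ij")
    return yy**2 + xx**2 <= r_cm**2


@pytest.fixture(scope="session")
def phantom() -> synthetic.RenderedPhantom:
    """Default adult phantom at 0.5 cm/px."""
    return synthetic.render_phantom(synthetic.PhantomSpec())


@pytest.fixture(scope="session")
def phantom_masks(phantom):
    """Extracted, symmetrized, height-normalized masks of the default phantom."""
    h = phantom.spec.height_cm
    back = imaging.normalize_height(
        imaging.symmetrize(imaging.extract_mask(phantom.back)), h
    )
    side = imaging.normalize_height(
        imaging.symmetrize(imaging.extract_mask(phantom.side)), h
    )
    return back, side


@pytest.fixture(scope="session")
def phantom_keypoints(phantom_masks):
    back, _ = phantom_masks
    return anatomy.detect_key_points(back)


@pytest.fixture(scope="session")
def phantom_segments(phantom_masks, phantom_keypoints):
    back, _ = phantom_masks
    return anatomy.segment_body(back, phantom_keypoints)


@pytest.fixture(scope="session")
def phantom_features(phantom):
    return pipeline.process_subject(phantom.back, phantom.side, phantom.spec.height_cm)
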