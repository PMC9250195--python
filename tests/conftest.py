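import math

import numpy as np
import pytest

from rownav import detect_frame
from rownav.synthetic import CameraModel, SyntheticScene, render_frame


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def pristine(camera):
    """One default-scene frame plus its ground truth (shared, read-only)."""
    return render_frame(SyntheticScene(seed=1), camera)


def detection_errors(frame, truth):
    """(lateral px at bottom row, heading deg) of a detection, or None."""
    result = detect_frame(frame)
    if not result.ok:
        return None
    y = truth.image_size[1] - 1
    lat = result.line.x_at(y) - truth.line.x_at(y)
    head = abs(math.degrees(math.atan(result.line.a)
                            - math.atan(truth.line.a)))
    return lat, head


def random_mask(rng, shape=(64, 64), density=0.2):
    return (rng.random(shape) < density).astype(np.uint8) * 255
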