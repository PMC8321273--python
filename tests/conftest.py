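import numpy as np
import pytest

from toolmotion.geometry import BoundingBox, Category, Detection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_detection(x0, y0, x1, y1, category=Category.HAND, score=1.0, frame_index=0):
    return Detection(
        box=BoundingBox(x0, y0, x1, y1),
        category=category,
        score=score,
        frame_index=frame_index,
    )


def random_int_box(rng, lo=0, hi=40):
    """Random valid integer-coordinate box within [lo, hi)."""
    x0, x1 = sorted(rng.integers(lo, hi, size=2).tolist())
    y0, y1 = sorted(rng.integers(lo, hi, size=2).tolist())
    return BoundingBox(x0, y0, x1 + 1, y1 + 1)


def lattice_iou(a: BoundingBox, b: BoundingBox, extent=64):
    """Pixel-counting IoU oracle for integer boxes: rasterize and count."""
    ga = np.zeros((extent, extent), dtype=bool)
    gb = np.zeros((extent, extent), dtype=bool)
    ga[int(a.y_min) : int(a.y_max), int(a.x_min) : int(a.x_max)] = True
    gb[int(b.y_min) : int(b.y_max), int(b.x_min) : int(b.x_max)] = True
    inter = np.logical_and(ga, gb).sum()
    union = np.logical_or(ga, gb).sum()
    return inter / union if union else 0.0
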