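"""Box arithmetic, overlap ratio, and crop/resize primitives.

Coordinates are continuous, 0-based and half-open: a box covers
``[x_min, x_max) x [y_min, y_max)`` in pixel units, matching the COCO
``[x, y, width, height]`` convention after corner conversion.  The overlap
ratio (intersection over union) of a hand box and a tool box is the
selection statistic used to decide which detected hand operates a tool.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

#: Side length of the square crop fed to the visual feature extractor.
CROP_SIZE = 252


class Category(str, enum.Enum):
    """Detector category. Tool *class* (scissors vs needle holders) is not
    decided at detection time; only hand/tool is."""

    HAND = "hand"
    TOOL = "tool"


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with half-open extent.

    Raises ``ValueError`` for degenerate (zero width/height), negative or
    non-finite coordinates.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite box coordinates: {vals}")
        if min(vals) < 0:
            raise ValueError(f"negative box coordinates: {vals}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box (empty extent): {vals}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def to_coco(self) -> list[float]:
        """Corner convention -> COCO ``[x, y, width, height]``."""
        return [self.x_min, self.y_min, self.width, self.height]

    @classmethod
    def from_coco(cls, bbox: list[float] | tuple[float, ...]) -> "BoundingBox":
        x, y, w, h = bbox
        return cls(x, y, x + w, y + h)


@dataclass(frozen=True)
class Detection:
    """One detector output: a box, its hand/tool category, confidence and frame."""

    box: BoundingBox
    category: Category
    score: float
    frame_index: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        object.__setattr__(self, "category", Category(self.category))


@dataclass
class FrameDetections:
    """All detections of one frame."""

    frame_index: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        for d in self.detections:
            if d.frame_index != self.frame_index:
                raise ValueError(
                    f"detection frame {d.frame_index} != frame {self.frame_index}"
                )

    def hands(self) -> list[Detection]:
        return [d for d in self.detections if d.category is Category.HAND]

    def tools(self) -> list[Detection]:
        return [d for d in self.detections if d.category is Category.TOOL]


def area(b: BoundingBox) -> float:
    """Box area in pixels^2. Positive by construction."""
    return b.width * b.height


def intersection_area(a: BoundingBox, b: BoundingBox) -> float:
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if w <= 0 or h <= 0:
        return 0.0
    return w * h


def overlap_ratio(b_hand: BoundingBox, b_tool: BoundingBox) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1].

    Equals 1 iff the boxes are identical and 0 iff they are disjoint.
    """
    inter = intersection_area(b_hand, b_tool)
    if inter == 0.0:
        return 0.0
    union = area(b_hand) + area(b_tool) - inter
    return inter / union


def crop_region(frame: np.ndarray, b: BoundingBox, pad: float = 0.0) -> np.ndarray:
    """Extract the sub-image of ``b``, optionally expanded, clamped to the frame.

    ``pad`` expands the box by ``pad * max(width, height)`` on every side
    before clamping (the tool tip may lie outside the hand box).  Raises
    ``ValueError`` if the box lies entirely outside the frame, which signals
    an inconsistent detection.
    """
    if frame.ndim < 2 or frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError("empty frame")
    if pad < 0:
        raise ValueError("pad must be >= 0")
    h, w = frame.shape[:2]
    margin = pad * max(b.width, b.height)
    x0 = int(math.floor(b.x_min - margin))
    y0 = int(math.floor(b.y_min - margin))
    x1 = int(math.ceil(b.x_max + margin))
    y1 = int(math.ceil(b.y_max + margin))
    x0c, y0c = max(x0, 0), max(y0, 0)
    x1c, y1c = min(x1, w), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        raise ValueError(
            f"box ({b.x_min},{b.y_min},{b.x_max},{b.y_max}) lies outside "
            f"{w}x{h} frame: inconsistent detection"
        )
    return frame[y0c:y1c, x0c:x1c]


def resize_crop(img: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Bilinear resize to ``size`` x ``size`` x 3 (aspect ratio not preserved)."""
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("empty image")
    if img.shape[:2] == (size, size) and img.shape[2] == 3:
        return img
    pil = Image.fromarray(np.ascontiguousarray(img[:, :, :3]))
    out = pil.resize((size, size), Image.BILINEAR)
    return np.asarray(out)
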