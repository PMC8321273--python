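"""Synthetic egocentric scenes with ground truth: the test bed for the pipeline.

Each scene contains one target hand holding an elongated tool plus 0-3
distractor hands over a static textured background, rendered at 25 fps in a
480x270 frame (the 16:9 aspect of head-mounted surgical video, scaled for
desk-scale experiments).  The two tool classes are rendered with *identical*
sprites; they differ only in the motion program of the hand-tool pair:

- ``oscillate`` (scissors): small-amplitude linear oscillation of the
  hand-tool pair along a random axis, period ~12 frames — the quick
  back-and-forth of cutting.
- ``rotate`` (needle holders): the hand sweeps a circle of fixed radius
  about the tool anchor, period ~40 frames, the tool always pointing at the
  anchor — the slow wrist rotation of driving a suture needle.

Because per-frame appearance carries no class information, any classifier
above chance must be reading motion.  A detector-noise model (corner
jitter, misses, spurious boxes) turns ground truth into realistic imperfect
detections; with zero noise the oracle detector reproduces truth exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .geometry import BoundingBox, Category, Detection, FrameDetections

SCISSORS = "scissors"
NEEDLE_HOLDERS = "needle_holders"
PROGRAM_FOR_CLASS = {SCISSORS: "oscillate", NEEDLE_HOLDERS: "rotate"}

HAND_W, HAND_H = 64.0, 56.0
TOOL_LEN, TOOL_W = 70.0, 12.0
OSC_PERIOD = 12.0  # frames; ~0.5 s at 25 fps
OSC_AMPLITUDE = 22.0  # px
ROT_PERIOD = 40.0  # frames; ~1.6 s
ROT_RADIUS = 34.0  # px


@dataclass
class DetectorNoise:
    """Imperfections of the simulated detector."""

    box_jitter_sigma: float = 0.0  # px, per corner coordinate
    miss_rate: float = 0.0
    spurious_rate: float = 0.0  # expected false boxes per frame
    score_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if min(self.box_jitter_sigma, self.miss_rate, self.spurious_rate, self.score_noise_sigma) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.miss_rate > 1:
            raise ValueError("miss_rate must be <= 1")


#: Default noise level for "realistic detector" experiments.
DEFAULT_NOISE = DetectorNoise(
    box_jitter_sigma=2.0, miss_rate=0.05, spurious_rate=0.3, score_noise_sigma=0.1
)


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene; rendering is deterministic in seed."""

    n_frames: int = 60
    fps: int = 25
    frame_size: tuple[int, int] = (480, 270)  # (width, height)
    tool_class: str = SCISSORS
    motion_program: str | None = None  # default: class-appropriate program
    n_distractor_hands: int = 1
    noise: DetectorNoise = field(default_factory=DetectorNoise)
    seed: int = 0
    adversarial_distractors: bool = False  # allow distractors near the tool

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.tool_class not in PROGRAM_FOR_CLASS:
            raise ValueError(f"unknown tool class {self.tool_class!r}")
        if not 0 <= self.n_distractor_hands <= 3:
            raise ValueError("n_distractor_hands must be in 0..3")
        if self.motion_program is None:
            self.motion_program = PROGRAM_FOR_CLASS[self.tool_class]
        if self.motion_program not in ("oscillate", "rotate", "static"):
            raise ValueError(f"unknown motion program {self.motion_program!r}")


@dataclass
class FrameTruth:
    """Ground-truth geometry of one frame."""

    frame_index: int
    hand: BoundingBox
    tool: BoundingBox
    tool_segment: tuple[float, float, float, float]  # x0, y0, x1, y1
    distractors: list[BoundingBox]


@dataclass
class SceneTruth:
    """Full ground-truth trajectory set of a scene."""

    spec: SceneSpec
    frames: list[FrameTruth]
    anchor: tuple[float, float]  # rotation anchor / oscillation base


def _hand_box(cx: float, cy: float) -> BoundingBox:
    return BoundingBox(cx - HAND_W / 2, cy - HAND_H / 2, cx + HAND_W / 2, cy + HAND_H / 2)


def _tool_box(x0: float, y0: float, x1: float, y1: float, w: int, h: int) -> BoundingBox:
    half = TOOL_W / 2
    return BoundingBox(
        max(min(x0, x1) - half, 0.0),
        max(min(y0, y1) - half, 0.0),
        min(max(x0, x1) + half, float(w)),
        min(max(y0, y1) + half, float(h)),
    )


def make_scene(spec: SceneSpec) -> SceneTruth:
    """Generate per-frame ground-truth boxes for hand, tool and distractors."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.frame_size
    # keep every trajectory point comfortably inside the frame
    margin_x, margin_y = 130.0, 105.0
    cx0 = rng.uniform(margin_x, w - margin_x)
    cy0 = rng.uniform(margin_y, h - margin_y)
    phase = rng.uniform(0, 2 * math.pi)

    centers: list[tuple[float, float]] = []
    angles: list[float] = []
    if spec.motion_program == "oscillate":
        axis = rng.uniform(0, 2 * math.pi)
        theta = rng.uniform(0, 2 * math.pi)  # fixed tool angle, uniform marginal
        for t in range(spec.n_frames):
            s = OSC_AMPLITUDE * math.sin(2 * math.pi * t / OSC_PERIOD + phase)
            centers.append((cx0 + s * math.cos(axis), cy0 + s * math.sin(axis)))
            angles.append(theta)
        anchor = (cx0, cy0)
    elif spec.motion_program == "rotate":
        anchor = (cx0, cy0)
        for t in range(spec.n_frames):
            phi = phase + 2 * math.pi * t / ROT_PERIOD
            cx = cx0 + ROT_RADIUS * math.cos(phi)
            cy = cy0 + ROT_RADIUS * math.sin(phi)
            centers.append((cx, cy))
            angles.append(math.atan2(cy0 - cy, cx0 - cx))  # tool points at anchor
    else:  # static
        theta = rng.uniform(0, 2 * math.pi)
        centers = [(cx0, cy0)] * spec.n_frames
        angles = [theta] * spec.n_frames
        anchor = (cx0, cy0)

    # region the tool may visit, for distractor placement
    tool_extent = TOOL_LEN + TOOL_W
    reach = OSC_AMPLITUDE if spec.motion_program == "oscillate" else ROT_RADIUS
    exclusion = (
        cx0 - reach - tool_extent,
        cy0 - reach - tool_extent,
        cx0 + reach + tool_extent,
        cy0 + reach + tool_extent,
    )

    distractor_tracks: list[list[tuple[float, float]]] = []
    for _ in range(spec.n_distractor_hands):
        for _attempt in range(300):
            dx = rng.uniform(HAND_W / 2 + 2, w - HAND_W / 2 - 2)
            dy = rng.uniform(HAND_H / 2 + 2, h - HAND_H / 2 - 2)
            drift = 8.0
            ok = spec.adversarial_distractors or not (
                exclusion[0] - HAND_W / 2 - drift < dx < exclusion[2] + HAND_W / 2 + drift
                and exclusion[1] - HAND_H / 2 - drift < dy < exclusion[3] + HAND_H / 2 + drift
            )
            if ok:
                break
        dphase = rng.uniform(0, 2 * math.pi)
        dangle = rng.uniform(0, 2 * math.pi)
        amp = 0.0 if spec.motion_program == "static" else 8.0
        track = []
        for t in range(spec.n_frames):
            s = amp * math.sin(2 * math.pi * t / 30.0 + dphase)
            track.append(
                (
                    min(max(dx + s * math.cos(dangle), HAND_W / 2), w - HAND_W / 2),
                    min(max(dy + s * math.sin(dangle), HAND_H / 2), h - HAND_H / 2),
                )
            )
        distractor_tracks.append(track)

    frames = []
    for t in range(spec.n_frames):
        cx, cy = centers[t]
        th = angles[t]
        x1 = cx + TOOL_LEN * math.cos(th)
        y1 = cy + TOOL_LEN * math.sin(th)
        frames.append(
            FrameTruth(
                frame_index=t,
                hand=_hand_box(cx, cy),
                tool=_tool_box(cx, cy, x1, y1, w, h),
                tool_segment=(cx, cy, x1, y1),
                distractors=[_hand_box(*trk[t]) for trk in distractor_tracks],
            )
        )
    return SceneTruth(spec=spec, frames=frames, anchor=anchor)


# -- rendering -----------------------------------------------------------

_HAND_FILL = (172, 140, 118)
_HAND_EDGE = (120, 95, 80)
_TOOL_FILL = (198, 200, 206)


def _background(spec: SceneSpec) -> np.ndarray:
    """Static low-frequency noise texture, fixed per scene seed."""
    rng = np.random.default_rng(spec.seed + 7919)
    w, h = spec.frame_size
    low = rng.integers(55, 125, size=(h // 16, w // 16, 3), dtype=np.uint8)
    img = Image.fromarray(low).resize((w, h), Image.BILINEAR)
    return np.asarray(img)


def _draw_hand(draw: ImageDraw.ImageDraw, box: BoundingBox) -> None:
    draw.ellipse(
        [box.x_min, box.y_min, box.x_max - 1, box.y_max - 1],
        fill=_HAND_FILL,
        outline=_HAND_EDGE,
        width=2,
    )


def _draw_tool(draw: ImageDraw.ImageDraw, seg: tuple[float, float, float, float]) -> None:
    x0, y0, x1, y1 = seg
    th = math.atan2(y1 - y0, x1 - x0)
    nx, ny = -math.sin(th) * TOOL_W / 2, math.cos(th) * TOOL_W / 2
    poly = [(x0 + nx, y0 + ny), (x1 + nx, y1 + ny), (x1 - nx, y1 - ny), (x0 - nx, y0 - ny)]
    draw.polygon(poly, fill=_TOOL_FILL, outline=(90, 90, 96))


def render_frame(truth: SceneTruth, frame_index: int, background: np.ndarray | None = None) -> np.ndarray:
    """Rasterize one frame (RGB uint8)."""
    if background is None:
        background = _background(truth.spec)
    ft = truth.frames[frame_index]
    img = Image.fromarray(background.copy())
    draw = ImageDraw.Draw(img)
    for box in ft.distractors:
        _draw_hand(draw, box)
    _draw_hand(draw, ft.hand)
    _draw_tool(draw, ft.tool_segment)
    return np.asarray(img)


def frame_provider(truth: SceneTruth):
    """In-memory frame source for ``build_clip`` — no disk round trip."""
    bg = _background(truth.spec)
    return lambda i: render_frame(truth, i, bg)


def render_frames(truth: SceneTruth, out_dir: str | Path) -> list[Path]:
    """Write all frames as ``frame_%06d.png`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bg = _background(truth.spec)
    paths = []
    for ft in truth.frames:
        arr = render_frame(truth, ft.frame_index, bg)
        path = out_dir / f"frame_{ft.frame_index:06d}.png"
        Image.fromarray(arr).save(path)
        paths.append(path)
    return paths


# -- oracle detector -----------------------------------------------------


def _jitter_box(box: BoundingBox, sigma: float, w: int, h: int, rng: np.random.Generator) -> BoundingBox:
    if sigma == 0:
        return box
    x0, y0, x1, y1 = (
        box.x_min + rng.normal(0, sigma),
        box.y_min + rng.normal(0, sigma),
        box.x_max + rng.normal(0, sigma),
        box.y_max + rng.normal(0, sigma),
    )
    x0, x1 = sorted((x0, x1))
    y0, y1 = sorted((y0, y1))
    x0 = min(max(x0, 0.0), w - 2.0)
    y0 = min(max(y0, 0.0), h - 2.0)
    x1 = min(max(x1, x0 + 2.0), float(w))
    y1 = min(max(y1, y0 + 2.0), float(h))
    return BoundingBox(x0, y0, x1, y1)


def _score(rng: np.random.Generator, sigma: float) -> float:
    if sigma == 0:
        return 1.0
    return float(np.clip(1.0 - abs(rng.normal(0, sigma)), 0.05, 1.0))


def oracle_detect(
    truth: SceneTruth, noise: DetectorNoise | None = None, seed: int | None = None
) -> list[FrameDetections]:
    """Simulated detector output: jittered truth boxes, misses and spurious boxes.

    With zero noise the output equals ground truth exactly, all scores 1.0.
    """
    spec = truth.spec
    noise = noise if noise is not None else spec.noise
    rng = np.random.default_rng(spec.seed + 104729 if seed is None else seed)
    w, h = spec.frame_size
    out = []
    for ft in truth.frames:
        dets: list[Detection] = []
        candidates = [(ft.hand, Category.HAND)] + [
            (b, Category.HAND) for b in ft.distractors
        ] + [(ft.tool, Category.TOOL)]
        for box, cat in candidates:
            if noise.miss_rate > 0 and rng.random() < noise.miss_rate:
                continue
            dets.append(
                Detection(
                    box=_jitter_box(box, noise.box_jitter_sigma, w, h, rng),
                    category=cat,
                    score=_score(rng, noise.score_noise_sigma),
                    frame_index=ft.frame_index,
                )
            )
        if noise.spurious_rate > 0:
            for _ in range(rng.poisson(noise.spurious_rate)):
                bw = rng.uniform(20, 80)
                bh = rng.uniform(20, 80)
                x0 = rng.uniform(0, w - bw)
                y0 = rng.uniform(0, h - bh)
                dets.append(
                    Detection(
                        box=BoundingBox(x0, y0, x0 + bw, y0 + bh),
                        category=Category.HAND if rng.random() < 0.5 else Category.TOOL,
                        score=float(rng.uniform(0.05, 0.3)),
                        frame_index=ft.frame_index,
                    )
                )
        out.append(FrameDetections(frame_index=ft.frame_index, detections=dets))
    return out


# -- annotation I/O ------------------------------------------------------

CATEGORY_IDS = {"hand": 1, "tool": 2}


def write_coco_annotations(truth: SceneTruth, path: str | Path, file_pattern: str = "frame_{:06d}.png") -> None:
    """COCO detection JSON of the ground truth (categories: hand, tool)."""
    w, h = truth.spec.frame_size
    images, annotations = [], []
    ann_id = 1
    for ft in truth.frames:
        image_id = ft.frame_index + 1
        images.append(
            {"id": image_id, "file_name": file_pattern.format(ft.frame_index), "width": w, "height": h}
        )
        boxes = [(ft.hand, "hand")] + [(b, "hand") for b in ft.distractors] + [(ft.tool, "tool")]
        for box, cat in boxes:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": image_id,
                    "category_id": CATEGORY_IDS[cat],
                    "bbox": box.to_coco(),
                    "area": box.width * box.height,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": v, "name": k} for k, v in CATEGORY_IDS.items()],
    }
    Path(path).write_text(json.dumps(doc))


def read_coco_annotations(path: str | Path) -> dict[int, list[tuple[BoundingBox, str]]]:
    """Read COCO JSON back into per-frame (box, category-name) lists."""
    doc = json.loads(Path(path).read_text())
    required = {"images", "annotations", "categories"}
    if not required <= doc.keys():
        raise ValueError(f"COCO JSON missing keys {required - doc.keys()}")
    cat_names = {c["id"]: c["name"] for c in doc["categories"]}
    frame_of_image = {im["id"]: im["id"] - 1 for im in doc["images"]}
    out: dict[int, list[tuple[BoundingBox, str]]] = {f: [] for f in frame_of_image.values()}
    for ann in doc["annotations"]:
        box = BoundingBox.from_coco(ann["bbox"])
        out[frame_of_image[ann["image_id"]]].append((box, cat_names[ann["category_id"]]))
    return out


def write_detections_json(frames: list[FrameDetections], path: str | Path) -> None:
    """COCO-results-style detections: [{image_id, category_id, bbox, score}]."""
    records = [
        {
            "image_id": fd.frame_index + 1,
            "category_id": CATEGORY_IDS[d.category.value],
            "bbox": d.box.to_coco(),
            "score": d.score,
        }
        for fd in frames
        for d in fd.detections
    ]
    Path(path).write_text(json.dumps(records))


def read_detections_json(path: str | Path) -> list[FrameDetections]:
    records = json.loads(Path(path).read_text())
    by_frame: dict[int, list[Detection]] = {}
    names = {v: k for k, v in CATEGORY_IDS.items()}
    for r in records:
        fi = r["image_id"] - 1
        by_frame.setdefault(fi, []).append(
            Detection(
                box=BoundingBox.from_coco(r["bbox"]),
                category=Category(names[r["category_id"]]),
                score=r["score"],
                frame_index=fi,
            )
        )
    return [FrameDetections(frame_index=fi, detections=dets) for fi, dets in sorted(by_frame.items())]


def write_clip_labels(labels: list[dict], path: str | Path) -> None:
    """JSON-lines manifest of clip labels."""
    with Path(path).open("w") as fh:
        for rec in labels:
            fh.write(json.dumps(rec) + "\n")
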