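"""Assembly of fixed-length clip windows from per-frame target-hand selections.

A tool's classifier input is a window of T consecutive frames in which its
operating hand was selected; frames where selection failed break the track
into runs, and only runs of length >= T yield windows.  The default
T = 50 corresponds to 2 s of 25 fps video, long enough to contain at least
one full cycle of the characteristic hand motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .geometry import CROP_SIZE, BoundingBox, crop_region, resize_crop

#: Default classified-clip length in frames (2 s at 25 fps).
DEFAULT_T = 50
DEFAULT_FPS = 25


def frames_for_duration(seconds: float, fps: int = DEFAULT_FPS) -> int:
    """Number of frames spanning ``seconds`` of video at ``fps``."""
    if seconds <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    return round(seconds * fps)


@dataclass
class TargetTrack:
    """Per-frame selected hand boxes for one tool across a video.

    Entries must be strictly increasing in frame index; each entry is
    expected to come from a selection with positive overlap ratio.
    """

    tool_id: int
    entries: list[tuple[int, BoundingBox]] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        idx = [f for f, _ in self.entries]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("track frame indices must be strictly increasing")


@dataclass
class ClipWindow:
    """T consecutive 252x252 crops of the target hand, with one tool label."""

    images: np.ndarray  # (T, 252, 252, 3) uint8
    frame_indices: list[int]
    label: str | None = None  # "scissors" | "needle_holders" | None

    def __post_init__(self) -> None:
        t = len(self.frame_indices)
        if self.images.shape[0] != t:
            raise ValueError("images and frame_indices length mismatch")
        if self.images.shape[1:3] != (CROP_SIZE, CROP_SIZE):
            raise ValueError(f"crops must be {CROP_SIZE}x{CROP_SIZE}")
        diffs = np.diff(self.frame_indices)
        if t > 1 and not np.all(diffs == 1):
            raise ValueError("frame_indices must be gapless consecutive")

    @property
    def T(self) -> int:
        return len(self.frame_indices)


def find_runs(
    track: TargetTrack, max_gap: int = 0
) -> list[list[tuple[int, BoundingBox]]]:
    """Partition a track into maximal runs of consecutive frames.

    Successive entries belong to the same run iff their frame indices differ
    by at most ``1 + max_gap`` (default: exactly 1, i.e. strictly
    consecutive).
    """
    runs: list[list[tuple[int, BoundingBox]]] = []
    current: list[tuple[int, BoundingBox]] = []
    for entry in track.entries:
        if current and entry[0] - current[-1][0] > 1 + max_gap:
            runs.append(current)
            current = []
        current.append(entry)
    if current:
        runs.append(current)
    return runs


@dataclass(frozen=True)
class WindowSpan:
    """Half-open index span [start, start+T) into a run's entry list."""

    run_index: int
    offset: int
    T: int


def emit_windows(
    runs: Sequence[Sequence[tuple[int, BoundingBox]]], T: int, stride: int | None = None
) -> list[WindowSpan]:
    """Tile each run with windows of length T at the given stride.

    A run of length L yields ``floor((L - T)/stride) + 1`` spans when
    L >= T and none otherwise.  Inference default: ``stride = T``
    (non-overlapping windows).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if stride is None:
        stride = T
    if stride < 1:
        raise ValueError("stride must be >= 1")
    spans = []
    for ri, run in enumerate(runs):
        for off in range(0, len(run) - T + 1, stride):
            spans.append(WindowSpan(ri, off, T))
    return spans


def sample_fragment(
    runs: Sequence[Sequence[tuple[int, BoundingBox]]],
    T: int,
    rng: np.random.Generator,
) -> WindowSpan:
    """Draw one T-frame span uniformly over all valid offsets in all runs.

    This is the training-time random fragment sampler; every admissible
    (run, offset) pair has equal probability.
    """
    choices = [
        (ri, off) for ri, run in enumerate(runs) for off in range(len(run) - T + 1)
    ]
    if not choices:
        raise ValueError(f"no run of length >= {T}")
    ri, off = choices[rng.integers(len(choices))]
    return WindowSpan(ri, off, T)


FrameProvider = Callable[[int], np.ndarray]


def build_clip(
    frames: FrameProvider,
    track: TargetTrack,
    span: WindowSpan,
    runs: Sequence[Sequence[tuple[int, BoundingBox]]] | None = None,
    pad: float = 0.0,
    label: str | None = None,
) -> ClipWindow:
    """Crop and resize each frame of a window span into a ClipWindow.

    ``frames`` maps a frame index to an RGB ndarray (a directory reader or
    an in-memory renderer).  Each frame's selected hand box is cropped
    (``crop_region`` with ``pad``) and resized to 252x252.
    """
    if runs is None:
        runs = find_runs(track)
    run = runs[span.run_index]
    entries = run[span.offset : span.offset + span.T]
    if len(entries) != span.T:
        raise ValueError("span exceeds run length")
    images = np.empty((span.T, CROP_SIZE, CROP_SIZE, 3), dtype=np.uint8)
    indices = []
    for t, (frame_index, box) in enumerate(entries):
        frame = frames(frame_index)
        images[t] = resize_crop(crop_region(frame, box, pad=pad))
        indices.append(frame_index)
    return ClipWindow(images=images, frame_indices=indices, label=label)


def directory_frame_provider(directory: str | Path, pattern: str = "frame_{:06d}.png") -> FrameProvider:
    """Frame provider reading ``frame_%06d.png`` files from a directory."""
    directory = Path(directory)

    def provider(frame_index: int) -> np.ndarray:
        path = directory / pattern.format(frame_index)
        if not path.exists():
            raise FileNotFoundError(f"missing frame file {path}")
        import imageio.v3 as iio

        return iio.imread(path)

    return provider


def write_clip_manifest(
    clips: Iterable[dict], path: str | Path
) -> None:
    """JSON-lines manifest: {video, tool_id, start_frame, T, label, crop_paths}."""
    with Path(path).open("w") as fh:
        for record in clips:
            fh.write(json.dumps(record) + "\n")
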