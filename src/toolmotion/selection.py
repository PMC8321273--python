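"""Target-hand selection: pick, per tool, the hand with maximum overlap ratio.

Among all detected hand boxes in a frame, the hand operating a given tool is
taken to be the one whose box has the largest intersection-over-union with
the tool box.  A frame where no hand overlaps the tool yields no target hand
(the argmax over an all-zero overlap set would be meaningless: a hand that
does not touch the tool box cannot be operating it), and such frames break
the consecutive-frame runs used downstream.

Exact overlap ties are broken by higher detection score, then by lower list
index; real-valued boxes tie with probability zero, but test fixtures do.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .geometry import Category, Detection, FrameDetections, overlap_ratio


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of selecting the operating hand for one tool in one frame.

    ``selected_hand_index`` is ``None`` iff no hand overlaps the tool
    (``ratio`` is then 0).
    """

    frame_index: int
    tool_index: int
    selected_hand_index: int | None
    ratio: float

    def __post_init__(self) -> None:
        if (self.selected_hand_index is None) != (self.ratio == 0.0):
            raise ValueError("selected_hand_index must be None iff ratio == 0")


def select_target_hand(
    hands: list[Detection], tool: Detection, tool_index: int = 0
) -> SelectionResult:
    """Return the hand maximizing overlap ratio with ``tool``.

    All hands must carry category ``hand`` and the tool category ``tool``;
    a mismatch raises ``ValueError``.  An empty hand list or zero maximum
    overlap yields a result with no selected hand.
    """
    if tool.category is not Category.TOOL:
        raise ValueError(f"tool argument has category {tool.category}")
    best_idx: int | None = None
    best: tuple[float, float, float] | None = None  # (ratio, score, -index)
    for i, hand in enumerate(hands):
        if hand.category is not Category.HAND:
            raise ValueError(f"hand list entry {i} has category {hand.category}")
        r = overlap_ratio(hand.box, tool.box)
        if r == 0.0:
            continue
        key = (r, hand.score, -i)
        if best is None or key > best:
            best, best_idx = key, i
    if best_idx is None:
        return SelectionResult(tool.frame_index, tool_index, None, 0.0)
    return SelectionResult(tool.frame_index, tool_index, best_idx, best[0])


def select_all_targets(frame: FrameDetections) -> list[SelectionResult]:
    """One independent ``SelectionResult`` per tool detection in the frame.

    A single hand may be selected by more than one tool (e.g. momentarily
    overlapping two instruments); each tool's argmax is computed on its own.
    """
    hands = frame.hands()
    return [
        select_target_hand(hands, tool, tool_index=k)
        for k, tool in enumerate(frame.tools())
    ]


def write_selection_log(
    results: list[SelectionResult], path: str | Path, fmt: str = "csv"
) -> None:
    """Audit log of selections as CSV or JSON lines."""
    path = Path(path)
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["frame_index", "tool_index", "selected_hand_index", "ratio"]
            )
            writer.writeheader()
            for r in results:
                writer.writerow(asdict(r))
    elif fmt == "json":
        with path.open("w") as fh:
            for r in results:
                fh.write(json.dumps(asdict(r)) + "\n")
    else:
        raise ValueError(f"unknown log format {fmt!r}")
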