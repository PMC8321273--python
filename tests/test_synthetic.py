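"""Synthetic scene generator: trajectories, rendering, oracle detector, I/O."""

import json
import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from toolmotion.geometry import overlap_ratio
from toolmotion.synthetic import (
    DetectorNoise,
    NEEDLE_HOLDERS,
    OSC_PERIOD,
    ROT_RADIUS,
    SCISSORS,
    SceneSpec,
    make_scene,
    oracle_detect,
    read_coco_annotations,
    read_detections_json,
    render_frame,
    render_frames,
    write_coco_annotations,
    write_detections_json,
)


def center(box):
    return ((box.x_min + box.x_max) / 2, (box.y_min + box.y_max) / 2)


class TestMakeScene:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SceneSpec(n_frames=0)
        with pytest.raises(ValueError):
            SceneSpec(tool_class="forceps")
        with pytest.raises(ValueError):
            SceneSpec(n_distractor_hands=4)

    def test_program_defaults_follow_class(self):
        assert SceneSpec(tool_class=SCISSORS).motion_program == "oscillate"
        assert SceneSpec(tool_class=NEEDLE_HOLDERS).motion_program == "rotate"

    def test_oscillation_returns_to_start_each_period(self):
        truth = make_scene(SceneSpec(n_frames=30, tool_class=SCISSORS, seed=5))
        c0 = center(truth.frames[0].hand)
        cT = center(truth.frames[int(OSC_PERIOD)].hand)
        assert c0 == pytest.approx(cT, abs=1e-9)

    def test_rotation_keeps_fixed_radius_from_anchor(self):
        truth = make_scene(SceneSpec(n_frames=45, tool_class=NEEDLE_HOLDERS, seed=6))
        ax, ay = truth.anchor
        for ft in truth.frames:
            cx, cy = center(ft.hand)
            r = math.hypot(cx - ax, cy - ay)
            assert abs(r - ROT_RADIUS) < 1.0

    def test_same_seed_identical_trajectories(self):
        spec = SceneSpec(n_frames=20, seed=9, n_distractor_hands=2)
        t1, t2 = make_scene(spec), make_scene(spec)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert f1.hand == f2.hand and f1.tool == f2.tool
            assert f1.distractors == f2.distractors

    def test_tool_always_overlaps_target_hand(self):
        for seed in range(5):
            for cls in (SCISSORS, NEEDLE_HOLDERS):
                truth = make_scene(SceneSpec(n_frames=50, tool_class=cls, seed=seed))
                for ft in truth.frames:
                    assert overlap_ratio(ft.hand, ft.tool) > 0

    def test_distractors_never_overlap_tool(self):
        for seed in range(5):
            truth = make_scene(
                SceneSpec(n_frames=50, tool_class=NEEDLE_HOLDERS, seed=seed, n_distractor_hands=3)
            )
            for ft in truth.frames:
                for d in ft.distractors:
                    assert overlap_ratio(d, ft.tool) <= 0.05


class TestRendering:
    def test_writes_expected_png_files(self, tmp_path):
        truth = make_scene(SceneSpec(n_frames=3, seed=0))
        paths = render_frames(truth, tmp_path)
        assert len(paths) == 3
        assert all(p.exists() and p.name.startswith("frame_") for p in paths)

    def test_static_program_gives_identical_frames(self):
        truth = make_scene(SceneSpec(n_frames=3, motion_program="static", seed=1))
        f0 = render_frame(truth, 0)
        f1 = render_frame(truth, 1)
        np.testing.assert_array_equal(f0, f1)

    def test_frame_shape_matches_spec(self):
        spec = SceneSpec(n_frames=1, seed=2)
        arr = render_frame(make_scene(spec), 0)
        assert arr.shape == (spec.frame_size[1], spec.frame_size[0], 3)

    def test_per_frame_appearance_indistinguishable_between_classes(self):
        """Mean-intensity statistic of rendered frames: same distribution for
        both classes (the class signal is motion, not appearance)."""
        stats = {SCISSORS: [], NEEDLE_HOLDERS: []}
        for cls in stats:
            for seed in range(10):
                truth = make_scene(SceneSpec(n_frames=10, tool_class=cls, seed=seed))
                for t in range(10):
                    stats[cls].append(render_frame(truth, t).mean())
        _, p = ks_2samp(stats[SCISSORS], stats[NEEDLE_HOLDERS])
        assert p > 0.01


class TestOracleDetector:
    def test_zero_noise_reproduces_truth_exactly(self):
        truth = make_scene(SceneSpec(n_frames=10, seed=3, n_distractor_hands=2))
        frames = oracle_detect(truth, DetectorNoise())
        for ft, fd in zip(truth.frames, frames):
            hands = fd.hands()
            assert hands[0].box == ft.hand
            assert [h.box for h in hands[1:]] == ft.distractors
            assert fd.tools()[0].box == ft.tool
            assert all(d.score == 1.0 for d in fd.detections)

    def test_miss_rate_one_drops_everything(self):
        truth = make_scene(SceneSpec(n_frames=5, seed=3))
        frames = oracle_detect(truth, DetectorNoise(miss_rate=1.0))
        assert all(len(fd.detections) == 0 for fd in frames)

    def test_miss_fraction_within_binomial_band(self):
        truth = make_scene(SceneSpec(n_frames=500, seed=4, n_distractor_hands=1))
        frames = oracle_detect(truth, DetectorNoise(miss_rate=0.1), seed=11)
        n_expected = 3 * 500  # hand + distractor + tool per frame
        n_kept = sum(len(fd.detections) for fd in frames)
        dropped = 1 - n_kept / n_expected
        assert 0.07 <= dropped <= 0.13

    def test_spurious_boxes_have_low_scores(self):
        truth = make_scene(SceneSpec(n_frames=100, seed=5, n_distractor_hands=0))
        frames = oracle_detect(truth, DetectorNoise(spurious_rate=1.0), seed=12)
        n_dets = sum(len(fd.detections) for fd in frames)
        spurious = [d for fd in frames for d in fd.detections if d.score < 0.5]
        assert n_dets > 200  # 2 real per frame plus ~1 spurious
        assert len(spurious) > 50
        assert all(d.score <= 0.3 for d in spurious)

    def test_jitter_perturbs_but_keeps_valid_boxes(self):
        truth = make_scene(SceneSpec(n_frames=20, seed=6))
        frames = oracle_detect(truth, DetectorNoise(box_jitter_sigma=3.0), seed=13)
        moved = 0
        for ft, fd in zip(truth.frames, frames):
            for d in fd.detections:
                if d.box != ft.hand and d.box != ft.tool:
                    moved += 1
        assert moved > 0

    def test_noise_validation(self):
        with pytest.raises(ValueError):
            DetectorNoise(miss_rate=1.5)
        with pytest.raises(ValueError):
            DetectorNoise(box_jitter_sigma=-1)


class TestAnnotationIO:
    def test_coco_round_trip_and_schema(self, tmp_path):
        truth = make_scene(SceneSpec(n_frames=10, seed=7, n_distractor_hands=1))
        path = tmp_path / "ann.json"
        write_coco_annotations(truth, path)
        doc = json.loads(path.read_text())
        assert set(doc) == {"images", "annotations", "categories"}
        assert {c["name"] for c in doc["categories"]} == {"hand", "tool"}
        assert len(doc["images"]) == 10
        per_frame = read_coco_annotations(path)
        for ft in truth.frames:
            boxes = per_frame[ft.frame_index]
            hand_boxes = [b for b, cat in boxes if cat == "hand"]
            tool_boxes = [b for b, cat in boxes if cat == "tool"]
            assert len(tool_boxes) == 1
            for a, b in zip([ft.hand] + ft.distractors, hand_boxes):
                for u, v in zip((a.x_min, a.y_min, a.x_max, a.y_max),
                                (b.x_min, b.y_min, b.x_max, b.y_max)):
                    assert abs(u - v) < 1e-6

    def test_same_seed_byte_identical_annotations(self, tmp_path):
        spec = SceneSpec(n_frames=5, seed=8, n_distractor_hands=2)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_coco_annotations(make_scene(spec), p1)
        write_coco_annotations(make_scene(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_detections_round_trip(self, tmp_path):
        truth = make_scene(SceneSpec(n_frames=5, seed=9))
        frames = oracle_detect(truth, DetectorNoise(box_jitter_sigma=1.0), seed=1)
        path = tmp_path / "det.json"
        write_detections_json(frames, path)
        back = read_detections_json(path)
        assert len(back) == len(frames)
        for f1, f2 in zip(frames, back):
            assert len(f1.detections) == len(f2.detections)
            for d1, d2 in zip(f1.detections, f2.detections):
                assert d1.category == d2.category
                assert d1.score == pytest.approx(d2.score)
                assert d1.box.x_min == pytest.approx(d2.box.x_min)

    def test_malformed_coco_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"images": []}))
        with pytest.raises(ValueError):
            read_coco_annotations(path)
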