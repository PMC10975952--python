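"""Dual-circumference branch-point detection and non-maximum suppression."""

import numpy as np
import pytest

from visfeat.detect import (
    BranchPoint,
    DetectParams,
    circle_template,
    count_crossings,
    detect_branch_points,
    localize,
    nms,
)
from visfeat.fusion import RidgeImage
from visfeat.metrics import match_detections
from visfeat.synth import VesselTreeSpec, generate_tree, truth_ridge


def ridge_from(mask: np.ndarray) -> RidgeImage:
    sup = (np.asarray(mask) > 0).astype(np.uint8)
    return RidgeImage(support=sup, strength=sup.astype(float), direction=np.zeros(sup.shape + (2,)))


def draw_ray(mask, r0, c0, dr, dc, length):
    for k in range(length):
        mask[r0 + k * dr, c0 + k * dc] = 1


class TestCircleTemplate:
    def test_radius_one_is_eight_ring(self):
        tpl = circle_template(1)
        assert len(tpl.offsets) == 8
        assert set(tpl.offsets) == {(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)} - {(0, 0)}

    @pytest.mark.parametrize("radius", [2, 3, 5, 7])
    def test_contains_bresenham_circle_and_is_four_connected(self, radius):
        from skimage.draw import circle_perimeter

        tpl = circle_template(radius)
        rr, cc = circle_perimeter(0, 0, radius, method="bresenham")
        assert set(zip(rr.tolist(), cc.tolist())) <= set(tpl.offsets)
        # closed 4-connected walk
        offs = tpl.offsets
        for a, b in zip(offs, offs[1:] + offs[:1]):
            assert abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1
        assert len(set(offs)) == len(offs)

    @pytest.mark.parametrize("radius", [2, 5, 7])
    def test_offsets_stay_near_radius(self, radius):
        for dr, dc in circle_template(radius).offsets:
            assert abs(np.hypot(dr, dc) - radius) <= 0.8

    def test_starts_at_east(self):
        assert circle_template(5).offsets[0] == (0, 5)


class TestCountCrossings:
    def test_straight_line_two_runs(self):
        mask = np.zeros((21, 21), dtype=np.uint8)
        mask[10, :] = 1
        runs, peaks = count_crossings(ridge_from(mask), (10, 10), circle_template(5))
        assert runs == 2
        assert len(peaks) == 2

    def test_plus_four_runs(self):
        mask = np.zeros((21, 21), dtype=np.uint8)
        mask[10, :] = 1
        mask[:, 10] = 1
        runs, _ = count_crossings(ridge_from(mask), (10, 10), circle_template(5))
        assert runs == 4

    def test_y_junction_three_runs(self):
        mask = np.zeros((31, 31), dtype=np.uint8)
        draw_ray(mask, 15, 15, -1, 0, 12)  # up
        draw_ray(mask, 15, 15, 1, -1, 10)  # down-left
        draw_ray(mask, 15, 15, 1, 1, 10)  # down-right
        for radius in (5, 7):
            runs, peaks = count_crossings(ridge_from(mask), (15, 15), circle_template(radius))
            assert runs == 3
            assert len(peaks) == 3

    def test_border_circle_gives_skip_signal(self):
        mask = np.zeros((21, 21), dtype=np.uint8)
        mask[2, :] = 1
        assert count_crossings(ridge_from(mask), (2, 10), circle_template(5)) is None

    def test_disconnected_vessel_not_counted_by_default(self):
        mask = np.zeros((31, 31), dtype=np.uint8)
        mask[15, :] = 1  # line through the candidate
        mask[21, :] = 1  # unrelated parallel vessel at distance 6
        r = ridge_from(mask)
        runs_conn, _ = count_crossings(r, (15, 15), circle_template(7))
        runs_all, _ = count_crossings(r, (15, 15), circle_template(7), connected_only=False)
        assert runs_conn == 2
        assert runs_all == 4


class TestDetect:
    def test_blank_ridge_empty(self):
        assert detect_branch_points(ridge_from(np.zeros((32, 32)))) == []

    def test_constructed_y_detected_once(self):
        mask = np.zeros((41, 41), dtype=np.uint8)
        draw_ray(mask, 20, 20, -1, 0, 15)
        draw_ray(mask, 20, 20, 1, -1, 14)
        draw_ray(mask, 20, 20, 1, 1, 14)
        raw = detect_branch_points(ridge_from(mask))
        pts = localize(nms(raw, 7), raw)
        assert len(pts) == 1
        assert np.hypot(pts[0].row - 20, pts[0].col - 20) <= 2.0

    def test_second_circle_recovers_wide_merge(self):
        # arms that coincide out to radius ~5 but separate by radius 7
        mask = np.zeros((41, 41), dtype=np.uint8)
        draw_ray(mask, 20, 20, -1, 0, 15)
        draw_ray(mask, 20, 20, 1, 0, 6)
        # two arms splitting from (26,20)
        draw_ray(mask, 26, 20, 1, -1, 10)
        draw_ray(mask, 26, 20, 1, 1, 10)
        r = ridge_from(mask)
        res5 = count_crossings(r, (26, 20), circle_template(5))
        res7 = count_crossings(r, (26, 20), circle_template(7))
        assert res5[0] >= 3 or res7[0] >= 3
        raw = detect_branch_points(r)
        assert any(np.hypot(p.row - 26, p.col - 20) <= 3.5 for p in raw)

    def test_spurious_far_pixel_does_not_change_detections(self):
        truth = generate_tree(VesselTreeSpec(seed=6))
        ridge = truth_ridge(truth)
        base = detect_branch_points(ridge)
        sup = ridge.support.copy()
        # an isolated pixel far from all junctions (> 2 * max radius)
        far = None
        for r in range(20, 230):
            for c in range(20, 230):
                if sup[r - 16 : r + 17, c - 16 : c + 17].sum() == 0:
                    far = (r, c)
                    break
            if far:
                break
        sup[far] = 1
        ridge2 = RidgeImage(support=sup, strength=sup.astype(float), direction=ridge.direction)
        after = detect_branch_points(ridge2)
        assert [(p.row, p.col) for p in base] == [(p.row, p.col) for p in after]

    @pytest.mark.parametrize("rot", [0, 1, 2, 3])
    def test_quarter_turn_equivariance(self, rot):
        truth = generate_tree(VesselTreeSpec(seed=2))
        ridge = truth_ridge(truth)
        pts = {(p.row, p.col) for p in detect_branch_points(ridge)}
        sup = np.rot90(ridge.support, rot)
        h, w = ridge.support.shape
        rot_ridge = RidgeImage(
            support=sup.copy(),
            strength=sup.astype(float).copy(),
            direction=np.zeros(sup.shape + (2,)),
        )
        got = {(p.row, p.col) for p in detect_branch_points(rot_ridge)}
        def map_pt(r, c, k):
            for _ in range(k):
                r, c = w - 1 - c, r  # rot90 counterclockwise index map
            return r, c
        want = {map_pt(r, c, rot) for r, c in pts}
        assert got == want


class TestNms:
    def test_single_point_kept(self):
        p = BranchPoint(5, 5, 5, 3, 1.0)
        assert nms([p], 7) == [p]

    def test_two_close_points_strongest_survives(self):
        a = BranchPoint(10, 10, 5, 3, 10.0)
        b = BranchPoint(12, 12, 5, 3, 7.0)
        assert nms([a, b], 5) == [a]

    def test_matches_bruteforce_greedy(self, rng):
        pts = [
            BranchPoint(int(r), int(c), 5, 3, float(v))
            for r, c, v in zip(
                rng.integers(0, 100, 60), rng.integers(0, 100, 60), rng.random(60)
            )
        ]
        got = {(p.row, p.col) for p in nms(pts, 7)}
        # brute force: visit in (-score, row, col) order, suppress in window
        alive = [True] * len(pts)
        order = sorted(range(len(pts)), key=lambda i: (-pts[i].score_v, pts[i].row, pts[i].col))
        keep = set()
        for i in order:
            if not alive[i]:
                continue
            keep.add((pts[i].row, pts[i].col))
            for j in range(len(pts)):
                if max(abs(pts[j].row - pts[i].row), abs(pts[j].col - pts[i].col)) <= max(
                    7, pts[j].radius_hit + 2
                ):
                    alive[j] = False
        assert got == keep

    def test_no_survivors_within_radius(self, rng):
        pts = [
            BranchPoint(int(r), int(c), 5, 3, float(v))
            for r, c, v in zip(
                rng.integers(0, 60, 80), rng.integers(0, 60, 80), rng.random(80)
            )
        ]
        kept = nms(pts, 7)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert max(abs(a.row - b.row), abs(a.col - b.col)) > 7


class TestRecovery:
    def test_precision_and_recall_on_synthetic_trees(self):
        tp = fp = fn = 0
        for seed in range(10):
            truth = generate_tree(VesselTreeSpec(seed=seed))
            raw = detect_branch_points(truth_ridge(truth))
            pts = localize(nms(raw, 7), raw)
            a, b, c = match_detections(pts, truth.bifurcations)
            tp += a
            fp += b
            fn += c
        assert tp / (tp + fn) >= 0.9
        assert tp / (tp + fp) >= 0.9
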