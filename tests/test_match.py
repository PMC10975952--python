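"""ZSSD block matching and repeatability evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from visfeat.detect import BranchPoint
from visfeat.match import (
    Homography,
    MatchParams,
    evaluate,
    match_points,
    warp_patch,
    zssd,
)
from visfeat.synth import make_homography


def bp(r, c):
    return BranchPoint(r, c, 5, 3, 1.0)


class TestZssd:
    def test_identical_blocks_zero(self, rng):
        a = rng.random((21, 21))
        assert zssd(a, a) == 0.0

    def test_constant_offset_invariance(self, rng):
        a = rng.random((21, 21))
        assert zssd(a, np.clip(a + 0.2, -10, 10)) < 1e-24

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
    def test_offset_invariance_property(self, da, db):
        rng = np.random.default_rng(7)
        a = rng.random((9, 9))
        b = rng.random((9, 9))
        assert np.isclose(zssd(a + da, b + db), zssd(a, b), atol=1e-12)

    def test_matches_scalar_double_loop(self, rng):
        a, b = rng.random((21, 21)), rng.random((21, 21))
        da, db = a - a.mean(), b - b.mean()
        acc = 0.0
        for r in range(21):
            for c in range(21):
                acc += (da[r, c] - db[r, c]) ** 2
        assert np.isclose(zssd(a, b), acc / 441.0, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            zssd(np.zeros((3, 3)), np.zeros((4, 4)))


class TestHomography:
    def test_nonsingular_required(self):
        with pytest.raises(ValueError):
            Homography(np.zeros((3, 3)))

    def test_file_roundtrip(self, tmp_path):
        h = make_homography((64, 64), rotation_deg=10, translation=(2, 3), scale=1.1)
        path = tmp_path / "H.txt"
        h.to_file(path)
        h2 = Homography.from_file(path)
        assert np.allclose(h.matrix, h2.matrix)

    def test_translation_maps_points(self):
        h = make_homography((64, 64), translation=(5.0, -3.0))
        out = h.apply_rc((10.0, 20.0))
        assert np.allclose(out, (15.0, 17.0))

    def test_inverse_roundtrip(self, rng):
        h = make_homography((64, 64), rotation_deg=12, translation=(4, 1), scale=1.05)
        pts = rng.uniform(5, 59, (10, 2))
        back = h.inverse().apply_rc(h.apply_rc(pts))
        assert np.allclose(back, pts, atol=1e-9)


class TestWarpPatch:
    def test_identity_equals_plain_crop(self, rng):
        img = rng.random((64, 64))
        patch = warp_patch(img, (30, 30), Homography.identity(), 10)
        assert np.allclose(patch, img[20:41, 20:41])

    def test_translation_still_samples_source_location(self, rng):
        img = rng.random((64, 64))
        h = make_homography((64, 64), translation=(7.0, -4.0))
        patch = warp_patch(img, (30, 30), h, 10)
        assert np.allclose(patch, img[20:41, 20:41])

    def test_out_of_bounds_skip_signal(self, rng):
        img = rng.random((64, 64))
        assert warp_patch(img, (3, 3), Homography.identity(), 10) is None

    def test_rotation_correlates_with_true_target_crop(self):
        # render the same smooth scene in two views and check the warped
        # source patch predicts the target patch
        y, x = np.mgrid[0:128, 0:128] / 128.0
        img_i = 0.5 + 0.25 * np.sin(9 * x) * np.cos(7 * y)
        h = make_homography((128, 128), rotation_deg=10.0)
        hinv = h.inverse()
        rr, cc = np.mgrid[0:128, 0:128].astype(float)
        src = hinv.apply_rc(np.column_stack([rr.ravel(), cc.ravel()]))
        from scipy import ndimage

        img_j = ndimage.map_coordinates(
            img_i, [src[:, 0].reshape(128, 128), src[:, 1].reshape(128, 128)], order=1
        )
        p = (70, 60)
        q = h.apply_rc((float(p[0]), float(p[1])))
        qr, qc = int(round(q[0])), int(round(q[1]))
        warped = warp_patch(img_i, p, h, 10)
        target = img_j[qr - 10 : qr + 11, qc - 10 : qc + 11]
        corr = np.corrcoef(warped.ravel(), target.ravel())[0, 1]
        assert corr > 0.95


class TestMatchPoints:
    def test_identical_frames_self_match(self, rng):
        img = rng.random((128, 128))
        pts = [bp(40, 40), bp(80, 90), bp(60, 30)]
        res = match_points(pts, pts, img, img, Homography.identity())
        assert len(res) == 3
        for m in res:
            assert m.p_i == m.p_j
            assert m.zssd == 0.0
            assert m.correct

    def test_threshold_rejects_poor_candidates(self, rng):
        img_i = rng.random((128, 128))
        img_j = rng.random((128, 128))  # unrelated content
        pts = [bp(60, 60)]
        res = match_points(pts, pts, img_i, img_j, Homography.identity(),
                           MatchParams(zssd_threshold=0.02))
        assert res == []

    def test_translated_frame_matches(self, rng):
        img_i = np.clip(
            0.5 + 0.3 * np.sin(np.add.outer(np.arange(128) / 5.0, np.arange(128) / 7.0))
            + rng.normal(0, 0.01, (128, 128)),
            0,
            1,
        )
        dr, dc = 5, 9
        img_j = np.roll(np.roll(img_i, dr, axis=0), dc, axis=1)
        h = make_homography((128, 128), translation=(dr, dc))
        pts_i = [bp(40, 40), bp(60, 80), bp(90, 50)]
        pts_j = [bp(40 + dr, 40 + dc), bp(60 + dr, 80 + dc), bp(90 + dr, 50 + dc)]
        res = match_points(pts_i, pts_j, img_i, img_j, h)
        assert len(res) == 3
        assert all(m.correct for m in res)

    def test_symmetry_under_inverse(self, rng):
        img = np.clip(
            0.5 + 0.3 * np.sin(np.add.outer(np.arange(128) / 5.0, np.arange(128) / 7.0)),
            0,
            1,
        )
        pts = [bp(40, 40), bp(60, 80), bp(90, 50)]
        fwd = match_points(pts, pts, img, img, Homography.identity())
        bwd = match_points(pts, pts, img, img, Homography.identity().inverse())
        assert [(m.p_i, m.p_j) for m in fwd] == [(m.p_i, m.p_j) for m in bwd]


class TestEvaluate:
    def test_identical_frames_perfect_metrics(self, rng):
        img = rng.random((128, 128))
        pts = [bp(40, 40), bp(80, 90)]
        res = match_points(pts, pts, img, img, Homography.identity())
        ev = evaluate(res, pts, pts, Homography.identity(), image_shape=(128, 128))
        assert ev["repeatability"] == 1.0
        assert ev["average_error"] == 0.0
        assert ev["correctness"] == 1.0

    def test_disjoint_sets_zero_repeatability(self):
        pts_i = [bp(30, 30)]
        pts_j = [bp(90, 90)]
        ev = evaluate([], pts_i, pts_j, Homography.identity(), image_shape=(128, 128))
        assert ev["repeatability"] == 0.0
        assert ev["average_error"] is None

    def test_empty_detections_give_null_markers(self):
        ev = evaluate([], [], [], Homography.identity(), image_shape=(64, 64))
        assert ev["repeatability"] is None
        assert ev["correctness"] is None
        assert ev["variance"] is None

    def test_matches_bruteforce_recomputation(self, rng):
        img = np.clip(
            0.5 + 0.3 * np.sin(np.add.outer(np.arange(128) / 4.0, np.arange(128) / 6.0)),
            0,
            1,
        )
        h = make_homography((128, 128), translation=(3, 2))
        pts_i = [bp(40, 40), bp(60, 80), bp(90, 50)]
        pts_j = [bp(43, 42), bp(63, 82), bp(93, 52), bp(20, 110)]
        img_j = np.roll(np.roll(img, 3, axis=0), 2, axis=1)
        res = match_points(pts_i, pts_j, img, img_j, h)
        ev = evaluate(res, pts_i, pts_j, h, image_shape=(128, 128))
        # brute force repeatability
        n_rep = 0
        for p in pts_i:
            q = h.apply_rc((float(p.row), float(p.col)))
            d = min(np.hypot(pj.row - q[0], pj.col - q[1]) for pj in pts_j)
            if d < 3.5:
                n_rep += 1
        assert ev["repeatability"] == n_rep / len(pts_i)
        errs = [
            np.hypot(m.p_j[0] - h.apply_rc(m.p_i)[0], m.p_j[1] - h.apply_rc(m.p_i)[1])
            for m in res
        ]
        assert np.isclose(ev["average_error"], np.mean(errs))

    def test_average_error_of_correct_matches_below_radius(self, rng):
        img = rng.random((128, 128))
        pts = [bp(40, 40), bp(80, 90)]
        res = match_points(pts, pts, img, img, Homography.identity())
        correct = [m for m in res if m.correct]
        h = Homography.identity()
        for m in correct:
            q = h.apply_rc(m.p_i)
            assert np.hypot(m.p_j[0] - q[0], m.p_j[1] - q[1]) < MatchParams().correct_radius
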