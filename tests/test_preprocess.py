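"""Preprocessing: adaptive FOV masking, highlight detection, FMM inpainting."""

import numpy as np
import pytest

from visfeat.preprocess import (
    AdaptiveMaskParams,
    HighlightParams,
    InpaintParams,
    adaptive_mask,
    fmm_inpaint,
    green_channel,
    highlight_mask,
    preprocess_pipeline,
)

from conftest import scene


def naive_adaptive_mask(img, wh, ww, k):
    """Double-loop evaluation of the mean/median window threshold."""
    h, w = img.shape
    rh, rw = wh // 2, ww // 2
    pad = np.pad(img, ((rh, rh), (rw, rw)), mode="symmetric")
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            win = pad[r : r + wh, c : c + ww]
            thr = k * win.mean() - (1 - k) * np.median(win)
            out[r, c] = 1 if img[r, c] > thr else 0
    return out


def naive_highlight_mask(img, rad, k_var, C, floor):
    h, w = img.shape
    pad = np.pad(img, rad, mode="symmetric")
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            win = pad[r : r + 2 * rad + 1, c : c + 2 * rad + 1]
            thr = k_var * win.var() + C
            out[r, c] = 1 if (img[r, c] > thr and img[r, c] > floor) else 0
    return out


class TestAdaptiveMask:
    def test_uniform_image_is_all_foreground(self):
        img = np.full((32, 32), 0.5)
        assert adaptive_mask(img, AdaptiveMaskParams(15, 15, 0.5)).all()

    def test_zero_image_is_all_background(self):
        img = np.zeros((32, 32))
        assert not adaptive_mask(img, AdaptiveMaskParams(15, 15, 0.5)).any()

    def test_matches_naive_double_loop(self, rng):
        img = np.zeros((64, 64))
        img[:, :32] = 0.1
        img[:, 32:] = 0.9
        img += rng.normal(0, 0.02, img.shape)
        img = np.clip(img, 0, 1)
        got = adaptive_mask(img, AdaptiveMaskParams(15, 15, 0.5))
        want = naive_adaptive_mask(img, 15, 15, 0.5)
        assert np.array_equal(got, want)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            adaptive_mask(np.full((32, 32), 0.5), AdaptiveMaskParams(65, 65, 0.5))

    def test_monotone_remap_invariance_on_uniform_windows(self):
        # where mean == median (symmetric neighborhoods) the mask depends
        # only on intensity order, so an increasing affine remap keeps it
        img = np.tile(np.linspace(0.2, 0.8, 32), (32, 1))
        p = AdaptiveMaskParams(5, 5, 0.5)
        a = adaptive_mask(img, p)
        b = adaptive_mask(np.clip(0.5 * img + 0.1, 0, 1), p)
        interior = np.zeros_like(a, dtype=bool)
        interior[3:-3, 3:-3] = True
        assert np.array_equal(a[interior], b[interior])


class TestGreenChannel:
    def test_extracts_channel_one(self):
        g = np.tile(np.linspace(0, 1, 32), (32, 1))
        rgb = np.stack([np.zeros_like(g), g, np.zeros_like(g)], axis=-1)
        assert np.allclose(green_channel(rgb), g)

    def test_grayscale_passthrough(self):
        img = np.full((32, 32), 0.3)
        assert np.allclose(green_channel(img), img)

    def test_synthetic_rgb_scene_matches_green_plane(self):
        spec, truth, _ = scene(2)
        from visfeat.synth import render

        rgb = render(truth, spec, rgb=True)
        assert np.allclose(green_channel(rgb), rgb[:, :, 1])

    def test_two_channel_input_rejected(self):
        with pytest.raises(ValueError):
            green_channel(np.zeros((32, 32, 2)))


class TestHighlightMask:
    def test_uniform_image_never_flagged(self):
        img = np.full((32, 32), 0.5)
        assert not highlight_mask(img, HighlightParams(7, 1.0, 1.0)).any()

    def test_saturated_blob_flagged_exactly(self):
        img = np.full((64, 64), 0.5)
        img[30:35, 30:35] = 1.0
        got = highlight_mask(img, HighlightParams(7, 1.0, 0.05, 0.9))
        want = naive_highlight_mask(img, 7, 1.0, 0.05, 0.9)
        assert np.array_equal(got, want)
        assert got[30:35, 30:35].all()
        got[30:35, 30:35] = 0
        assert not got.any()

    def test_checkerboard_high_variance_suppresses(self):
        img = np.indices((32, 32)).sum(axis=0) % 2
        img = img.astype(float)
        got = highlight_mask(img, HighlightParams(7, 10.0, 0.05, 0.0))
        want = naive_highlight_mask(img, 7, 10.0, 0.05, 0.0)
        assert np.array_equal(got, want)
        assert not got.any()


class TestFmmInpaint:
    def test_constant_image_fills_exactly(self):
        img = np.full((32, 32), 0.4)
        holes = np.zeros((32, 32), dtype=np.uint8)
        holes[10:19, 10:19] = 1
        out = fmm_inpaint(img, holes)
        assert np.allclose(out, 0.4)

    def test_empty_mask_is_identity(self, rng):
        img = rng.random((32, 32))
        out = fmm_inpaint(img, np.zeros((32, 32), dtype=np.uint8))
        assert np.array_equal(out, img)

    def test_affine_ramp_recovered_within_tolerance(self):
        img = np.tile(np.linspace(0.1, 0.9, 48), (48, 1))
        holes = np.zeros((48, 48), dtype=np.uint8)
        holes[18:29, 18:29] = 1
        corrupted = img.copy()
        corrupted[holes > 0] = 1.0
        out = fmm_inpaint(corrupted, holes)
        assert np.abs(out - img)[holes > 0].max() < 0.02

    def test_agrees_with_biharmonic_reference_on_smooth_field(self):
        # independent reference inpainter on a smooth synthetic field
        from skimage.restoration import inpaint_biharmonic

        y, x = np.mgrid[0:48, 0:48] / 48.0
        img = 0.4 + 0.3 * np.sin(2 * x) * np.cos(1.5 * y)
        holes = np.zeros((48, 48), dtype=np.uint8)
        holes[20:28, 20:28] = 1
        corrupted = img.copy()
        corrupted[holes > 0] = 1.0
        ours = fmm_inpaint(corrupted, holes)
        ref = inpaint_biharmonic(corrupted, holes.astype(bool))
        assert np.abs(ours - ref)[holes > 0].max() < 0.05

    def test_pixels_outside_hole_untouched(self, rng):
        img = rng.random((32, 32))
        holes = np.zeros((32, 32), dtype=np.uint8)
        holes[12:17, 12:17] = 1
        out = fmm_inpaint(img, holes)
        assert np.array_equal(out[holes == 0], img[holes == 0])

    def test_fill_order_monotone_in_distance(self):
        img = np.full((32, 32), 0.5)
        holes = np.zeros((32, 32), dtype=np.uint8)
        holes[8:21, 8:21] = 1
        from scipy import ndimage

        edt = ndimage.distance_transform_edt(holes)
        order: list[tuple[int, int]] = []
        fmm_inpaint(img, holes, record_order=order)
        dists = [edt[r, c] for r, c in order]
        # fast-marching arrival order may differ from Euclidean by the
        # scheme's discretization, but never by more than one pixel step
        running_max = np.maximum.accumulate(dists)
        assert np.all(np.asarray(dists) >= running_max - 1.0)
        assert len(order) == int(holes.sum())

    def test_border_hole_rejected(self):
        img = np.full((32, 32), 0.5)
        holes = np.zeros((32, 32), dtype=np.uint8)
        holes[0:4, 10:14] = 1
        with pytest.raises(ValueError):
            fmm_inpaint(img, holes)

    def test_idempotent_on_consistent_fill(self):
        img = np.full((32, 32), 0.4)
        holes = np.zeros((32, 32), dtype=np.uint8)
        holes[10:15, 10:15] = 1
        once = fmm_inpaint(img, holes)
        twice = fmm_inpaint(once, holes)
        assert np.abs(once - twice).max() < 1e-6


class TestPreprocessPipeline:
    def test_clean_scene_passthrough(self):
        spec, truth, img = scene(3, noise=0.0, highlights=0, border=False)
        pre, fov = preprocess_pipeline(img)
        assert fov.all()
        assert np.allclose(pre, img)

    def test_fov_matches_generator_disk(self):
        spec, truth, img = scene(1)
        _, fov = preprocess_pipeline(img)
        assert (fov == truth.fov_mask).mean() >= 0.99

    def test_highlights_removed(self):
        spec, truth, img = scene(4)
        pre, _ = preprocess_pipeline(img)
        hl = truth.highlight_mask > 0
        if hl.any():
            assert pre[hl].max() < 0.98
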