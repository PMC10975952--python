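"""Shared fixtures: cached synthetic scenes and enhancement products.

Scenes are generated programmatically per seed; enhancement results are
cached per session because several test modules interrogate the same
stages.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from visfeat.frangi import frangi_multiscale
from visfeat.fusion import extract_ridge, fuse, gaussian_weights
from visfeat.mfat import mfat_multiscale
from visfeat.preprocess import preprocess_pipeline
from visfeat.synth import VesselTreeSpec, generate_tree, render


@lru_cache(maxsize=64)
def scene(seed: int, noise: float = 0.01, highlights: int = 3, border: bool = True):
    """(spec, truth, image) for a default 256x256 scene."""
    spec = VesselTreeSpec(seed=seed, noise_sigma=noise, n_highlights=highlights, border=border)
    truth = generate_tree(spec)
    img = render(truth, spec)
    return spec, truth, img


@lru_cache(maxsize=32)
def enhanced(seed: int, noise: float = 0.01, highlights: int = 3):
    """Full enhancement products for one scene at fusion mu = 3."""
    spec, truth, img = scene(seed, noise, highlights)
    pre, fov = preprocess_pipeline(img)
    fr = frangi_multiscale(pre, fov)
    mf = mfat_multiscale(pre, fov)
    use_m = mf.response > fr.response
    direction = np.where(use_m[..., None], mf.direction, fr.direction)
    w1, w2 = gaussian_weights(pre, fr.response, mf.response, 3.0)
    fused = fuse(fr.response, mf.response, w1, w2)
    ridge = extract_ridge(pre, fused, direction)
    return {
        "spec": spec,
        "truth": truth,
        "image": img,
        "pre": pre,
        "fov": fov,
        "frangi": fr,
        "mfat": mf,
        "direction": direction,
        "fused": fused,
        "ridge": ridge,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
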