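"""End-to-end orchestration: preprocess -> dual-branch enhancement ->
fusion/ridge -> detection/NMS -> (pair mode) matching and evaluation.

Every stage result is returned in one artifact dict; ``write_artifacts``
persists them with a manifest (parameters, seed, versions, content hashes)
so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from visfeat.config import PipelineConfig
from visfeat.detect import detect_branch_points, localize, nms
from visfeat.frangi import frangi_multiscale
from visfeat.fusion import select_mu
from visfeat.match import Homography, evaluate, match_points
from visfeat.mfat import mfat_multiscale
from visfeat.preprocess import preprocess_pipeline

log = logging.getLogger(__name__)


def _timed(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception:
        log.exception("stage %r failed", name)
        raise
    log.info("stage %-12s %.3f s", name, time.perf_counter() - t0)
    return out


def run_pipeline(image: np.ndarray, config: PipelineConfig | None = None) -> dict:
    """Single-frame pipeline; returns all intermediate artifacts.

    Keys: preprocessed, fov_mask, frangi, mfat, mu, ssim, fused, ridge,
    keypoints (after NMS), keypoints_raw.
    """
    config = config or PipelineConfig()
    pre, fov = _timed("preprocess", preprocess_pipeline, image, config.preprocess)
    fr = _timed("frangi", frangi_multiscale, pre, fov, config.frangi)
    mf = _timed("mfat", mfat_multiscale, pre, fov, config.mfat)

    if config.direction_source == "frangi":
        direction = fr.direction
    else:  # per-pixel stronger branch
        use_mfat = mf.response > fr.response
        direction = np.where(use_mfat[..., None], mf.direction, fr.direction)

    mu, fused, ridge, score = _timed(
        "fuse/ridge",
        select_mu,
        pre,
        fr.response,
        mf.response,
        direction,
        config.fusion,
        config.scales.sigmas,
        config.polarity,
    )
    raw_points = _timed("detect", detect_branch_points, ridge, config.detect, fov)
    points = localize(nms(raw_points, config.detect.nms_radius), raw_points)
    return {
        "preprocessed": pre,
        "fov_mask": fov,
        "frangi": fr,
        "mfat": mf,
        "mu": mu,
        "ssim": score,
        "fused": fused,
        "ridge": ridge,
        "keypoints_raw": raw_points,
        "keypoints": points,
    }


def run_pair(
    image_i: np.ndarray,
    image_j: np.ndarray,
    homography: Homography,
    config: PipelineConfig | None = None,
) -> dict:
    """Two-frame pipeline: per-frame detection, ZSSD matching, metrics."""
    config = config or PipelineConfig()
    art_i = run_pipeline(image_i, config)
    art_j = run_pipeline(image_j, config)
    matches = _timed(
        "match",
        match_points,
        art_i["keypoints"],
        art_j["keypoints"],
        art_i["preprocessed"],
        art_j["preprocessed"],
        homography,
        config.match,
    )
    metrics = evaluate(
        matches,
        art_i["keypoints"],
        art_j["keypoints"],
        homography,
        config.match,
        image_shape=art_j["preprocessed"].shape,
    )
    return {"frame_i": art_i, "frame_j": art_j, "matches": matches, "metrics": metrics}


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def write_artifacts(artifacts: dict, out_dir: str | Path, config: PipelineConfig, seed: int | None = None) -> Path:
    """Persist pipeline outputs with a JSON manifest of parameters and
    content hashes; returns the manifest path."""
    from visfeat import __version__
    from visfeat.imgio import write_image, write_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "visfeat_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": config.to_dict(),
        "artifacts": {},
    }
    write_image(out / "preprocessed.png", artifacts["preprocessed"])
    write_mask(out / "fov_mask.png", artifacts["fov_mask"])
    write_mask(out / "ridge.png", artifacts["ridge"].support)
    manifest["artifacts"]["preprocessed"] = _sha(artifacts["preprocessed"])
    manifest["artifacts"]["fov_mask"] = _sha(artifacts["fov_mask"])
    manifest["artifacts"]["ridge"] = _sha(artifacts["ridge"].support)
    manifest["mu"] = artifacts["mu"]
    manifest["ssim"] = artifacts["ssim"]
    with open(out / "keypoints.tsv", "w") as fh:
        fh.write("row\tcol\tradius\tcrossings\tscore\n")
        for p in artifacts["keypoints"]:
            fh.write(f"{p.row}\t{p.col}\t{p.radius_hit}\t{p.crossings}\t{p.score_v:.6g}\n")
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
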