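"""Preprocessing for endoscopic frames.

Stages: self-adaptive field-of-view masking (mean/median window threshold),
green-channel selection, local-variance specular-highlight detection, and
fast-marching (Telea-style) inpainting of the detected highlights.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from visfeat.validate import as_intensity, as_mask

log = logging.getLogger(__name__)

KNOWN, BAND, INSIDE = 0, 1, 2


@dataclass
class AdaptiveMaskParams:
    """Window and sensitivity for the self-adaptive foreground threshold.

    The per-pixel threshold is ``k * mean - (1 - k) * median`` over a
    ``window_w x window_h`` neighborhood; pixels strictly above it are
    foreground.  Window sides must be odd so the window is centered.
    """

    window_w: int = 31
    window_h: int = 31
    k: float = 0.5

    def __post_init__(self) -> None:
        if self.window_w < 1 or self.window_h < 1 or self.window_w % 2 == 0 or self.window_h % 2 == 0:
            raise ValueError("window dimensions must be odd positive integers")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("k must lie in [0, 1]")


@dataclass
class HighlightParams:
    """Local-variance highlight threshold: T = k_var * var + C.

    A pixel is flagged as highlight when it strictly exceeds both the local
    threshold T and the global saturation floor (specular highlights are
    saturated, so a locally bright but unsaturated pixel is not a highlight).
    """

    window_radius: int = 7
    k_var: float = 1.0
    C: float = 0.05
    saturation_floor: float = 0.9

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValueError("window_radius must be a positive integer")
        if not (np.isfinite(self.k_var) and self.k_var > 0):
            raise ValueError("k_var must be finite and > 0")
        if not (np.isfinite(self.C) and self.C >= 0):
            raise ValueError("C must be finite and >= 0")


@dataclass
class InpaintParams:
    """Fast-marching inpainting parameters.

    ``eps_radius`` is the radius of the known-neighbor ball B_eps(p); ``d0``
    and ``T0`` are the distance and level parameters of the geometric and
    level-set weight factors (both 1 by convention).
    """

    eps_radius: int = 5
    d0: float = 1.0
    T0: float = 1.0

    def __post_init__(self) -> None:
        if self.eps_radius < 1:
            raise ValueError("eps_radius must be a positive integer")


def adaptive_mask(image: np.ndarray, params: AdaptiveMaskParams | None = None) -> np.ndarray:
    """Self-adaptive foreground mask.

    Threshold per pixel: ``k * mean(window) - (1 - k) * median(window)``,
    computed with reflective padding; the mask is 1 where the intensity is
    strictly greater than the threshold.
    """
    params = params or AdaptiveMaskParams()
    img = as_intensity(image)
    if params.window_h > img.shape[0] or params.window_w > img.shape[1]:
        raise ValueError(
            f"window {params.window_h}x{params.window_w} larger than image {img.shape}"
        )
    size = (params.window_h, params.window_w)
    mean = ndimage.uniform_filter(img, size=size, mode="reflect")
    median = ndimage.median_filter(img, size=size, mode="reflect")
    thr = params.k * mean - (1.0 - params.k) * median
    return (img > thr).astype(np.uint8)


def green_channel(image: np.ndarray) -> np.ndarray:
    """Select the green channel (best vessel/tissue contrast) as float in [0, 1].

    3-channel input returns channel 1 (R=0, G=1, B=2); single-channel input
    passes through with a logged notice.  Integer inputs are rescaled by
    their dtype range.
    """
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        log.info("green_channel: single-channel input passed through unchanged")
        return as_intensity(arr)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return as_intensity(arr[:, :, 1], name="green channel")
    raise ValueError(f"expected a 3-channel or single-channel image, got shape {arr.shape}")


def highlight_mask(image: np.ndarray, params: HighlightParams | None = None) -> np.ndarray:
    """Flag specular-highlight pixels from the local intensity variance.

    T(x, y) = k_var * var(window) + C; flagged iff intensity > T and
    intensity > saturation_floor.
    """
    params = params or HighlightParams()
    img = as_intensity(image)
    size = 2 * params.window_radius + 1
    mean = ndimage.uniform_filter(img, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(img * img, size=size, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    thr = params.k_var * var + params.C
    return ((img > thr) & (img > params.saturation_floor)).astype(np.uint8)


def _march_distance(holes: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """First-order eikonal fast march from the hole boundary into the hole.

    Returns the arrival-time field T (0 on known pixels) and the hole pixels
    in increasing-arrival order.
    """
    h, w = holes.shape
    T = np.where(holes > 0, np.inf, 0.0)
    state = np.where(holes > 0, INSIDE, KNOWN).astype(np.uint8)

    heap: list[tuple[float, int, int]] = []

    def solve(r: int, c: int) -> float:
        # first-order upwind quadratic update with unit speed
        tx = min(
            T[r, c - 1] if c > 0 and state[r, c - 1] == KNOWN else np.inf,
            T[r, c + 1] if c < w - 1 and state[r, c + 1] == KNOWN else np.inf,
        )
        ty = min(
            T[r - 1, c] if r > 0 and state[r - 1, c] == KNOWN else np.inf,
            T[r + 1, c] if r < h - 1 and state[r + 1, c] == KNOWN else np.inf,
        )
        lo, hi = (tx, ty) if tx <= ty else (ty, tx)
        if np.isinf(lo):
            return np.inf
        if hi - lo >= 1.0 or np.isinf(hi):
            return lo + 1.0
        s = tx + ty
        disc = s * s - 2.0 * (tx * tx + ty * ty - 1.0)
        return 0.5 * (s + np.sqrt(max(disc, 0.0)))

    rows, cols = np.nonzero(holes)
    for r, c in zip(rows, cols):
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and state[rr, cc] == KNOWN:
                t = solve(r, c)
                if t < T[r, c]:
                    T[r, c] = t
                    state[r, c] = BAND
                    heapq.heappush(heap, (t, r, c))
                break

    order: list[tuple[int, int]] = []
    while heap:
        t, r, c = heapq.heappop(heap)
        if state[r, c] == KNOWN or t > T[r, c]:
            continue
        state[r, c] = KNOWN
        order.append((r, c))
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and state[rr, cc] != KNOWN:
                t2 = solve(rr, cc)
                if t2 < T[rr, cc]:
                    T[rr, cc] = t2
                    state[rr, cc] = BAND
                    heapq.heappush(heap, (t2, rr, cc))
    return T, order


def fmm_inpaint(
    image: np.ndarray,
    holes: np.ndarray,
    params: InpaintParams | None = None,
    record_order: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Fill hole pixels in fast-marching order from first-order estimates.

    Each hole pixel p is estimated from every known pixel q in B_eps(p) as
    I(q) + grad I(q) . (p - q), averaged with weights
    w = dir(p,q) * dst(p,q) * lev(p,q):

    - dir: alignment of (p - q) with the inpainting front normal at p (the
      normalized arrival-time gradient); uniform 1 where the normal vanishes;
    - dst: d0^2 / |p - q|^2;
    - lev: T0 / (1 + |T(p) - T(q)|), T being the arrival time.

    Pixels outside the hole mask are never modified; the fill is clipped to
    [0, 1].  ``record_order`` (if given) receives the (row, col) fill order.
    """
    params = params or InpaintParams()
    img = as_intensity(image).copy()
    hole = as_mask(holes, img.shape, name="holes")
    if hole.sum() == 0:
        return img
    if hole.sum() >= 0.3 * hole.size:
        raise ValueError("hole region must cover < 30% of the image")
    if hole[0, :].any() or hole[-1, :].any() or hole[:, 0].any() or hole[:, -1].any():
        raise ValueError("holes touching the image border are not inpaintable")

    T, order = _march_distance(hole)
    if record_order is not None:
        record_order.extend(order)

    known = hole == 0
    h, w = img.shape
    eps = params.eps_radius
    # ball offsets within radius eps, excluding the center
    dr, dc = np.mgrid[-eps : eps + 1, -eps : eps + 1]
    ball = (dr * dr + dc * dc <= eps * eps) & ~((dr == 0) & (dc == 0))
    off_r, off_c = dr[ball], dc[ball]

    # front normal at p: gradient of the arrival-time field
    gTr, gTc = np.gradient(T)

    for r, c in order:
        qr = r + off_r
        qc = c + off_c
        ok = (qr >= 0) & (qr < h) & (qc >= 0) & (qc < w)
        qr, qc = qr[ok], qc[ok]
        use = known[qr, qc]
        qr, qc = qr[use], qc[use]
        if qr.size == 0:
            continue
        vr = (r - qr).astype(np.float64)
        vc = (c - qc).astype(np.float64)
        dist2 = vr * vr + vc * vc
        dist = np.sqrt(dist2)

        nr, nc = gTr[r, c], gTc[r, c]
        nn = np.hypot(nr, nc)
        if nn > 1e-12:
            direc = np.abs((vr * nr + vc * nc) / (dist * nn))
        else:
            direc = np.ones_like(dist)
        dst = params.d0**2 / dist2
        lev = params.T0 / (1.0 + np.abs(T[r, c] - T[qr, qc]))
        wgt = direc * dst * lev
        wgt = np.where(wgt > 1e-12, wgt, 1e-12)

        # gradient at q from known pixels: central differences where both
        # neighbors are known, one-sided where only one is (still exact
        # for affine intensity fields), zero otherwise
        gr = np.zeros_like(dist)
        gc = np.zeros_like(dist)
        up, dn = np.clip(qr - 1, 0, h - 1), np.clip(qr + 1, 0, h - 1)
        le, ri = np.clip(qc - 1, 0, w - 1), np.clip(qc + 1, 0, w - 1)
        ku, kd = known[up, qc], known[dn, qc]
        kl, kr_ = known[qr, le], known[qr, ri]
        both_r = ku & kd
        gr[both_r] = 0.5 * (img[dn, qc] - img[up, qc])[both_r]
        only_d = kd & ~ku
        gr[only_d] = (img[dn, qc] - img[qr, qc])[only_d]
        only_u = ku & ~kd
        gr[only_u] = (img[qr, qc] - img[up, qc])[only_u]
        both_c = kl & kr_
        gc[both_c] = 0.5 * (img[qr, ri] - img[qr, le])[both_c]
        only_r = kr_ & ~kl
        gc[only_r] = (img[qr, ri] - img[qr, qc])[only_r]
        only_l = kl & ~kr_
        gc[only_l] = (img[qr, qc] - img[qr, le])[only_l]

        est = img[qr, qc] + gr * vr + gc * vc
        img[r, c] = float(np.clip(np.sum(wgt * est) / np.sum(wgt), 0.0, 1.0))
        known[r, c] = True

    return img


def _clean_fov(mask: np.ndarray) -> np.ndarray:
    """Keep the largest foreground component and fill interior holes."""
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(mask), lab, index=np.arange(1, n + 1))
        mask = (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    return ndimage.binary_fill_holes(mask).astype(np.uint8)


@dataclass
class PreprocessConfig:
    adaptive: AdaptiveMaskParams = field(default_factory=AdaptiveMaskParams)
    highlight: HighlightParams = field(default_factory=HighlightParams)
    inpaint: InpaintParams = field(default_factory=InpaintParams)
    clean_fov: bool = True


def preprocess_pipeline(
    image: np.ndarray, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Full preprocessing: green channel, FOV mask, highlight inpainting.

    Returns ``(intensity, fov_mask)``; highlight pixels strictly inside the
    field of view are inpainted, pixels outside the FOV mask are zeroed.
    """
    cfg = cfg or PreprocessConfig()
    gray = green_channel(image)
    fov = adaptive_mask(gray, cfg.adaptive)
    if cfg.clean_fov and fov.any():
        fov = _clean_fov(fov)
    spots = highlight_mask(gray, cfg.highlight)
    # keep only holes strictly inside the field of view (inpainting needs a
    # known ring around each hole)
    interior = ndimage.binary_erosion(fov, iterations=2, border_value=0)
    spots = (spots & interior).astype(np.uint8)
    spots[0, :] = spots[-1, :] = 0
    spots[:, 0] = spots[:, -1] = 0
    out = fmm_inpaint(gray, spots, cfg.inpaint) if spots.any() else gray
    out = out * fov
    return out, fov
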