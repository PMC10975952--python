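"""Gaussian-weighted fusion of the two enhancement branches and
single-pixel ridge (centerline) extraction.

The fused map is a pixelwise convex combination of the Frangi and MFAT
responses with Gaussian weights driven by each branch's residual against
the preprocessed image:

    w1 = exp(-(I - I_Frangi)^2 / (2 mu^2)),
    w2 = 1 - exp(-(I - I_MFAT)^2 / (2 mu^2)),
    I_vessel = (w1 * I_Frangi + w2 * I_MFAT) / (w1 + w2).

The shape parameter mu is selected per image by exhaustive search over a
grid in [2, 4]: for each candidate the scene is fused, binarized and
thinned to a centerline, and the mu whose centerline scores the highest
global SSIM against the image wins (ties to the smallest mu).

Ridge extraction follows the two-stage directional scheme: mark pixels
where the gradient projected on the cross-vessel direction V2 changes
sign within a half-pixel of the pixel center (evaluated analytically per
scale), then realize the local-maximum selection as response-ordered
removal of doubled pixels that never breaks the candidate band's
connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from visfeat.validate import as_intensity


@dataclass
class FusionParams:
    """mu candidates in [2, 4] (step 0.1 by default), the binarization
    threshold applied to the normalized fused map, and SSIM stabilizers."""

    mu_min: float = 2.0
    mu_max: float = 4.0
    mu_step: float = 0.1
    binarize_threshold: float = 0.15
    ssim_c1: float = 0.01**2
    ssim_c2: float = 0.03**2

    def __post_init__(self) -> None:
        if not (2.0 <= self.mu_min <= self.mu_max <= 4.0):
            raise ValueError("mu grid must lie within [2, 4]")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.ssim_c1 <= 0 or self.ssim_c2 <= 0:
            raise ValueError("SSIM stabilizers must be positive")

    @property
    def mu_grid(self) -> np.ndarray:
        n = int(round((self.mu_max - self.mu_min) / self.mu_step)) + 1
        return np.round(self.mu_min + self.mu_step * np.arange(n), 10)


@dataclass
class RidgeImage:
    """Single-pixel centerline: binary support, positive strength on the
    support, and the unit vessel tangent per pixel (shape (H, W, 2))."""

    support: np.ndarray
    strength: np.ndarray
    direction: np.ndarray


def gaussian_weights(
    image: np.ndarray, f: np.ndarray, m: np.ndarray, mu: float
) -> tuple[np.ndarray, np.ndarray]:
    """Residual-driven Gaussian weights (w1, w2); never normalized here."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    image = np.asarray(image, dtype=np.float64)
    w1 = np.exp(-((image - f) ** 2) / (2.0 * mu * mu))
    w2 = 1.0 - np.exp(-((image - m) ** 2) / (2.0 * mu * mu))
    return w1, w2


def fuse(f: np.ndarray, m: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Convex combination (w1*f + w2*m) / (w1 + w2); degenerate w1+w2=0
    pixels map to 0."""
    s = w1 + w2
    out = np.zeros_like(np.asarray(f, dtype=np.float64))
    np.divide(w1 * f + w2 * m, s, out=out, where=s > 0)
    return out


def ssim_global(a: np.ndarray, b: np.ndarray, c1: float = 0.01**2, c2: float = 0.03**2) -> float:
    """Global (whole-image) structural similarity index.

    Uses whole-image means, variances and covariance rather than the
    windowed mean-SSIM; constant image pairs are stabilized by c1/c2.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + c1)
        * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def binarize(vessel: np.ndarray, threshold: float) -> np.ndarray:
    """Binary vessel support: strictly above the threshold."""
    return (np.asarray(vessel) > threshold).astype(np.uint8)


def _sample(field: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear sampling with edge clamping."""
    return ndimage.map_coordinates(field, [rows, cols], order=1, mode="nearest")


def ridge_candidates(
    image: np.ndarray,
    scales: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0, 4.0, 6.0),
    polarity: str = "dark",
    eps: float = 1.0,
) -> np.ndarray:
    """Multiscale ridge candidate mask (centerline-bearing pixels).

    The cross-vessel directional derivative d(x) = grad I_sigma . V2
    changes sign across the centerline; equivalently its zero crossing
    t* = -d / (V2ᵀ H V2) lies within eps/2 of the pixel center.  The
    analytic form is evaluated per scale with that scale's own smoothed
    gradient and Hessian cross-direction V2, and a pixel fires if any
    scale places a vessel-polarity crossing inside it: near junctions a
    thin arm's valley is only a shoulder of a thick arm's basin at fine
    smoothing and its crossing reappears at coarser scales, so a
    single-scale test fragments the centerline there.
    """
    from visfeat.hessian import hessian_at_scale

    img = as_intensity(image)
    h, w = img.shape
    fire = np.zeros((h, w), dtype=bool)
    margin = 0.5 * eps
    for sigma in scales:
        smoothed = ndimage.gaussian_filter(img, sigma, mode="reflect")
        gr_s, gc_s = np.gradient(smoothed)
        fld = hessian_at_scale(img, sigma)
        nr, nc = fld.v2[..., 0], fld.v2[..., 1]
        d = gr_s * nr + gc_s * nc
        lam2 = fld.lam2 / sigma**2  # back to image units for the offset
        safe = np.abs(lam2) > 1e-12
        tstar = np.where(safe, -d / np.where(safe, lam2, 1.0), 1e9)
        inside = (np.abs(tstar * nr) <= margin) & (np.abs(tstar * nc) <= margin)
        pol = fld.lam2 > 0 if polarity == "dark" else fld.lam2 < 0
        fire |= inside & pol
    return fire


def extract_ridge(
    image: np.ndarray,
    vessel: np.ndarray,
    direction: np.ndarray,
    binarize_threshold: float = 0.15,
    eps: float = 1.0,
    scales: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0, 4.0, 6.0),
    polarity: str = "dark",
    min_component: int = 5,
    candidates: np.ndarray | None = None,
    loop_window: int = 8,
    spur_length: int = 3,
) -> RidgeImage:
    """Two-stage single-pixel centerline from a continuous vessel map.

    Stage 1 marks the pixels containing a zero crossing of the
    cross-vessel directional derivative within eps/2 of the pixel center
    (:func:`ridge_candidates`, evaluated over the scale grid), gated by
    the binarized vessel support; the pixelization of the continuous
    valley curve is connected wherever the response is, so the candidate
    band preserves the vessel topology.  Candidate strength is the fused
    vessel response.

    Stage 2 realizes the local-maximum selection as response-ordered
    removal: visiting candidates from weakest to strongest, a pixel is
    removed when a stronger candidate is 8-adjacent and its removal does
    not disconnect its neighbors — checked first locally (3x3), then
    within a small window to collapse the two-strand loops that
    different scales' slightly offset crossings can form.  Endpoints are
    never removed, so arms keep their full length; stubs of at most
    ``spur_length`` pixels dangling from a junction pixel are then
    pruned, and fragments smaller than ``min_component`` pixels are
    discarded as speckle.  The result is single-pixel wide (no solid 2x2
    block survives) with the connectivity of the candidate band.

    ``direction`` must be defined (nonzero) wherever vessel support
    exists; it is carried through to the output tangent field.
    ``candidates`` may hold a precomputed stage-1 mask (it depends only
    on the image and scale grid, so callers sweeping fusion parameters
    compute it once).
    """
    img = as_intensity(image)
    vessel = np.asarray(vessel, dtype=np.float64)
    support = vessel > binarize_threshold
    if support.any():
        norms = np.hypot(direction[..., 0], direction[..., 1])
        if np.any(norms[support] < 1e-9):
            raise ValueError("zero direction vector at a vessel pixel")

    h, w = img.shape
    fire = candidates if candidates is not None else ridge_candidates(img, scales, polarity, eps)
    keep = (fire & support).copy()
    resp = vessel

    ring = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))
    s8 = np.ones((3, 3))

    def ring_components(nbh: np.ndarray) -> int:
        idx = [k for k, (dr, dc) in enumerate(ring) if nbh[1 + dr, 1 + dc]]
        if not idx:
            return 0
        parent = {k: k for k in idx}

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in idx:
            for j in idx:
                if i < j:
                    (r1, c1), (r2, c2) = ring[i], ring[j]
                    if max(abs(r1 - r2), abs(c1 - c2)) <= 1:
                        ra, rb = find(i), find(j)
                        if ra != rb:
                            parent[rb] = ra
        return len({find(k) for k in idx})

    order = sorted(map(tuple, np.argwhere(keep)), key=lambda p: (resp[p], p[0], p[1]))

    def has_stronger_neighbor(r: int, c: int) -> bool:
        return any(
            keep[r + dr, c + dc]
            and (resp[r + dr, c + dc], r + dr, c + dc) > (resp[r, c], r, c)
            for dr, dc in ring
        )

    changed = True
    while changed:
        changed = False
        for r, c in order:  # weakest first
            if not keep[r, c] or r == 0 or c == 0 or r == h - 1 or c == w - 1:
                continue
            nbh = keep[r - 1 : r + 2, c - 1 : c + 2]
            if int(nbh.sum()) - 1 < 2:  # endpoints are sacred
                continue
            if has_stronger_neighbor(r, c) and ring_components(nbh) == 1:
                keep[r, c] = False
                changed = True
        # loop breaking: a two-strand loop pixel has two local neighbor
        # groups that rejoin within a small window
        for r, c in order:
            if not keep[r, c] or r < 1 or c < 1 or r >= h - 1 or c >= w - 1:
                continue
            nbh = keep[r - 1 : r + 2, c - 1 : c + 2]
            if int(nbh.sum()) - 1 < 2:
                continue
            if not has_stronger_neighbor(r, c) or ring_components(nbh) != 2:
                continue
            r1, r2 = max(r - loop_window, 0), min(r + loop_window + 1, h)
            c1, c2 = max(c - loop_window, 0), min(c + loop_window + 1, w)
            sub = keep[r1:r2, c1:c2].copy()
            sub[r - r1, c - c1] = False
            lab, _ = ndimage.label(sub, structure=s8)
            labels = {lab[r + dr - r1, c + dc - c1] for dr, dc in ring if keep[r + dr, c + dc]}
            if len(labels) == 1 and 0 not in labels:
                keep[r, c] = False
                changed = True

    # spur pruning: drop dangling chains of <= spur_length pixels that
    # terminate at a junction pixel (arms are far longer; such stubs are
    # scale-union residue).  The walk never crosses a junction pixel.
    def live_neighbors(r: int, c: int) -> list[tuple[int, int]]:
        return [
            (r + dr, c + dc)
            for dr, dc in ring
            if 0 <= r + dr < h and 0 <= c + dc < w and keep[r + dr, c + dc]
        ]

    changed = True
    while changed:
        changed = False
        for r, c in map(tuple, np.argwhere(keep)):
            if len(live_neighbors(r, c)) != 1:
                continue
            chain = [(r, c)]
            prev: tuple[int, int] | None = None
            cur = (r, c)
            hit_junction = False
            for _ in range(spur_length):
                nbs = [q for q in live_neighbors(*cur) if q != prev]
                if len(nbs) != 1:
                    break
                nxt = nbs[0]
                if len(live_neighbors(*nxt)) >= 3:
                    hit_junction = True
                    break
                prev, cur = cur, nxt
                chain.append(cur)
            if hit_junction:
                for q in chain:
                    keep[q] = False
                changed = True

    if min_component > 1:
        lab, n = ndimage.label(keep, structure=s8)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(lab, dtype=np.float64), lab, np.arange(1, n + 1))
            keep &= np.isin(lab, 1 + np.nonzero(sizes >= min_component)[0])

    out_strength = np.where(keep, vessel, 0.0)
    return RidgeImage(
        support=keep.astype(np.uint8), strength=out_strength, direction=direction
    )


def select_mu(
    image: np.ndarray,
    f: np.ndarray,
    m: np.ndarray,
    direction: np.ndarray,
    params: FusionParams | None = None,
    scales: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0, 4.0, 6.0),
    polarity: str = "dark",
) -> tuple[float, np.ndarray, RidgeImage, float]:
    """Exhaustive SSIM search over the mu grid.

    For each candidate mu the branches are fused, the fused map is thinned
    to a centerline, and the global SSIM between the image and the binary
    centerline is scored; returns (mu_best, fused, ridge, ssim_best) with
    ties resolved toward the smallest mu.
    """
    params = params or FusionParams()
    grid = params.mu_grid
    if grid.size == 0:
        raise ValueError("mu grid is empty")
    cand = ridge_candidates(image, scales, polarity)
    best: tuple[float, np.ndarray, RidgeImage, float] | None = None
    for mu in grid:
        w1, w2 = gaussian_weights(image, f, m, float(mu))
        fused = fuse(f, m, w1, w2)
        ridge = extract_ridge(
            image,
            fused,
            direction,
            params.binarize_threshold,
            scales=scales,
            polarity=polarity,
            candidates=cand,
        )
        # the centerline is scored in image intensity convention (dark
        # vessels on bright tissue), so structure correlates positively
        ridge_img = (
            1.0 - ridge.support if polarity == "dark" else ridge.support.astype(np.float64)
        )
        score = ssim_global(image, ridge_img, params.ssim_c1, params.ssim_c2)
        if best is None or score > best[3]:
            best = (float(mu), fused, ridge, score)
    assert best is not None
    return best
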