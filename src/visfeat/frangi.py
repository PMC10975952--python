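"""Frangi vesselness branch.

Per-pixel vesselness from the Hessian eigenvalues: the blob ratio
R_B = |lam1| / |lam2| separates tubes (R_B ~ 0) from blobs (R_B ~ 1), and
the structureness S = sqrt(lam1^2 + lam2^2) separates structure from flat
background.  The response is

    V = exp(-R_B^2 / (2 beta^2)) * (1 - exp(-S^2 / (2 c^2)))

zeroed where the eigenvalue sign contradicts the requested polarity (dark
vessels need lam2 > 0, bright vessels lam2 < 0).  The multiscale map is the
pixelwise maximum over the scale grid, with the winning scale and the
vessel tangent at that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from visfeat.hessian import HessianField, ScaleGrid, hessian_at_scale
from visfeat.validate import as_mask


@dataclass
class FrangiParams:
    """beta: blob/strip sensitivity; c: structureness smoothing (None for
    the standard automatic choice, half the maximum S per scale)."""

    beta: float = 0.5
    c: float | None = None
    scales: ScaleGrid = field(default_factory=ScaleGrid)
    polarity: str = "dark"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError("beta must be finite and positive")
        if self.c is not None and not (np.isfinite(self.c) and self.c > 0):
            raise ValueError("c must be finite and positive (or None for auto)")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")


@dataclass
class VesselnessMap:
    """response in [0, 1]; best_scale per pixel; direction = unit vessel
    tangent (row, col components, shape (H, W, 2))."""

    response: np.ndarray
    best_scale: np.ndarray
    direction: np.ndarray


def frangi_single_scale(field: HessianField, params: FrangiParams) -> np.ndarray:
    """Frangi response at one scale (already computed HessianField)."""
    lam1, lam2 = field.lam1, field.lam2
    abs2 = np.abs(lam2)
    nonzero = abs2 > 0
    rb = np.zeros_like(lam2)
    np.divide(np.abs(lam1), abs2, out=rb, where=nonzero)
    s2 = lam1 * lam1 + lam2 * lam2
    c = params.c
    if c is None:
        smax = np.sqrt(s2.max())
        if smax <= 0:
            return np.zeros_like(lam2)
        c = 0.5 * smax
    resp = np.exp(-(rb * rb) / (2.0 * params.beta**2)) * (1.0 - np.exp(-s2 / (2.0 * c * c)))
    ok = (lam2 > 0) if params.polarity == "dark" else (lam2 < 0)
    return np.where(ok & nonzero, resp, 0.0)


def frangi_multiscale(
    image: np.ndarray, mask: np.ndarray | None, params: FrangiParams | None = None
) -> VesselnessMap:
    """Pixelwise maximum Frangi response over the scale grid.

    Masked-out pixels are zeroed; the direction is the vessel tangent (the
    small-eigenvalue eigenvector) at each pixel's winning scale.  The map is
    rescaled to [0, 1] by its maximum so both enhancement branches are
    commensurate before fusion.
    """
    params = params or FrangiParams()
    img = np.asarray(image, dtype=np.float64)
    sigmas = params.scales.sigmas
    best = np.full(img.shape, -1.0)
    best_scale = np.full(img.shape, sigmas[0])
    direction = np.zeros(img.shape + (2,))
    for sigma in sigmas:
        fld = hessian_at_scale(img, sigma, params.scales.gamma)
        resp = frangi_single_scale(fld, params)
        win = resp > best
        best = np.where(win, resp, best)
        best_scale = np.where(win, sigma, best_scale)
        direction[win] = fld.v1[win]
    best = np.maximum(best, 0.0)
    if mask is not None:
        m = as_mask(mask, img.shape)
        best *= m
    peak = best.max()
    if peak > 0:
        best = best / peak
    return VesselnessMap(response=best, best_scale=best_scale, direction=direction)
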