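"""ZSSD neighborhood-block matching and repeatability evaluation.

For each branch point P in frame I, the ground-truth homography predicts
its location Q in frame J; frame-J detections within a circular search
region around Q (radius = width/20) are compared with P's patch by
zero-mean SSD over 21x21 blocks, with P's block affinely warped into
frame-J geometry via the local Jacobian of the homography.  The candidate
with minimal ZSSD below the acceptance threshold is the match; a match is
correct when it lies within the correctness radius of Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from visfeat.detect import BranchPoint


class Homography:
    """3x3 projective map acting on homogeneous (x, y, 1) = (col, row, 1).

    The matrix is normalized so the bottom-right entry is 1; it must be
    nonsingular.
    """

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("homography must be nonsingular")
        if abs(m[2, 2]) < 1e-12:
            raise ValueError("homography bottom-right entry must be nonzero")
        self.matrix = m / m[2, 2]

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    @classmethod
    def from_file(cls, path) -> "Homography":
        return cls(np.loadtxt(path).reshape(3, 3))

    def to_file(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.12g")

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def apply_rc(self, points_rc: np.ndarray) -> np.ndarray:
        """Map (row, col) points; returns float (row, col) coordinates."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=np.float64))
        xy1 = np.column_stack([pts[:, 1], pts[:, 0], np.ones(len(pts))])
        mapped = xy1 @ self.matrix.T
        out = np.column_stack([mapped[:, 1] / mapped[:, 2], mapped[:, 0] / mapped[:, 2]])
        return out if np.asarray(points_rc).ndim == 2 else out[0]

    def jacobian_rc(self, point_rc: tuple[float, float]) -> np.ndarray:
        """2x2 Jacobian d(row', col') / d(row, col) at a point."""
        r, c = point_rc
        h = self.matrix
        x, y = c, r
        w = h[2, 0] * x + h[2, 1] * y + h[2, 2]
        u = h[0, 0] * x + h[0, 1] * y + h[0, 2]
        v = h[1, 0] * x + h[1, 1] * y + h[1, 2]
        du_dx = (h[0, 0] * w - u * h[2, 0]) / (w * w)
        du_dy = (h[0, 1] * w - u * h[2, 1]) / (w * w)
        dv_dx = (h[1, 0] * w - v * h[2, 0]) / (w * w)
        dv_dy = (h[1, 1] * w - v * h[2, 1]) / (w * w)
        # (row', col') = (v, u); (row, col) = (y, x)
        return np.array([[dv_dy, dv_dx], [du_dy, du_dx]])


@dataclass
class MatchParams:
    """patch_half: half-size of the (2k+1)x(2k+1) comparison block;
    search_radius_frac: search-circle radius as a fraction of image width;
    zssd_threshold: acceptance bound on the normalized ZSSD;
    correct_radius: correctness distance to the homography prediction."""

    patch_half: int = 10
    search_radius_frac: float = 1.0 / 20.0
    zssd_threshold: float = 0.02
    correct_radius: float = 3.5

    def __post_init__(self) -> None:
        if self.patch_half < 1:
            raise ValueError("patch_half must be >= 1")
        if self.zssd_threshold <= 0:
            raise ValueError("zssd_threshold must be positive")


@dataclass
class MatchResult:
    p_i: tuple[int, int]
    p_j: tuple[int, int]
    zssd: float
    correct: bool


def zssd(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Zero-mean SSD normalized by pixel count.

    Each block's own mean is removed before the squared-difference sum, so
    the cost is invariant to additive intensity offsets; normalization by
    the pixel count makes the acceptance threshold block-size independent.
    """
    a = np.asarray(block_a, dtype=np.float64)
    b = np.asarray(block_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("blocks must share a shape")
    da = a - a.mean()
    db = b - b.mean()
    return float(np.mean((da - db) ** 2))


def _crop(image: np.ndarray, center: tuple[int, int], half: int) -> np.ndarray | None:
    r, c = center
    h, w = image.shape
    if r - half < 0 or c - half < 0 or r + half >= h or c + half >= w:
        return None
    return image[r - half : r + half + 1, c - half : c + half + 1]


def warp_patch(
    image_i: np.ndarray,
    center: tuple[int, int],
    h: Homography,
    patch_half: int = 10,
) -> np.ndarray | None:
    """Sample P's neighborhood from frame I in frame-J patch geometry.

    The homography is locally approximated by its Jacobian at P: a frame-J
    patch offset d maps back to P + J^{-1} d in frame I, sampled bilinearly.
    Returns None (skip signal) when any sample position leaves the image.
    """
    img = np.asarray(image_i, dtype=np.float64)
    jac = h.jacobian_rc(center)
    if abs(np.linalg.det(jac)) < 1e-12:
        return None
    jinv = np.linalg.inv(jac)
    side = 2 * patch_half + 1
    dr, dc = np.mgrid[-patch_half : patch_half + 1, -patch_half : patch_half + 1]
    back = jinv @ np.vstack([dr.ravel(), dc.ravel()])
    rows = center[0] + back[0].reshape(side, side)
    cols = center[1] + back[1].reshape(side, side)
    if rows.min() < 0 or cols.min() < 0 or rows.max() > img.shape[0] - 1 or cols.max() > img.shape[1] - 1:
        return None
    return ndimage.map_coordinates(img, [rows, cols], order=1)


def match_points(
    points_i: list[BranchPoint],
    points_j: list[BranchPoint],
    img_i: np.ndarray,
    img_j: np.ndarray,
    h: Homography,
    params: MatchParams | None = None,
) -> list[MatchResult]:
    """ZSSD matching of frame-I detections into frame J.

    Candidates are frame-J detections inside the search circle around the
    homography prediction Q; the minimal-ZSSD candidate below the threshold
    is accepted (ties: nearest to Q, then topmost-leftmost).
    """
    params = params or MatchParams()
    img_i = np.asarray(img_i, dtype=np.float64)
    img_j = np.asarray(img_j, dtype=np.float64)
    radius = params.search_radius_frac * img_j.shape[1]
    coords_j = np.array([(p.row, p.col) for p in points_j]).reshape(-1, 2)
    out: list[MatchResult] = []
    for p in points_i:
        q = h.apply_rc((p.row, p.col))
        patch_i = warp_patch(img_i, (p.row, p.col), h, params.patch_half)
        if patch_i is None or len(points_j) == 0:
            continue
        dist = np.hypot(coords_j[:, 0] - q[0], coords_j[:, 1] - q[1])
        cand_idx = np.nonzero(dist <= radius)[0]
        best: tuple[float, float, int, int, int] | None = None
        for j in cand_idx:
            pj = points_j[int(j)]
            patch_j = _crop(img_j, (pj.row, pj.col), params.patch_half)
            if patch_j is None:
                continue
            d = zssd(patch_i, patch_j)
            key = (d, float(dist[j]), pj.row, pj.col, int(j))
            if best is None or key < best:
                best = key
        if best is not None and best[0] < params.zssd_threshold:
            pj = points_j[best[4]]
            err = float(np.hypot(pj.row - q[0], pj.col - q[1]))
            out.append(
                MatchResult(
                    p_i=(p.row, p.col),
                    p_j=(pj.row, pj.col),
                    zssd=best[0],
                    correct=err < params.correct_radius,
                )
            )
    return out


def evaluate(
    matches: list[MatchResult],
    points_i: list[BranchPoint],
    points_j: list[BranchPoint],
    h: Homography,
    params: MatchParams | None = None,
    image_shape: tuple[int, int] | None = None,
) -> dict:
    """Repeatability / accuracy metrics under the ground-truth homography.

    - repeatability: fraction of frame-I points (whose prediction lands
      inside frame J, when the shape is known) with a frame-J detection
      within correct_radius of the prediction;
    - average_error: mean distance of matched points to their predictions;
    - variance: mean per-axis variance of matched point positions,
      normalized by the squared image diagonal (our reading of the
      "distribution spread" indicator);
    - correctness: fraction of matches flagged correct.

    Degenerate inputs yield explicit None entries, never NaN.
    """
    params = params or MatchParams()
    coords_j = np.array([(p.row, p.col) for p in points_j]).reshape(-1, 2)
    n_eval = 0
    n_repeat = 0
    for p in points_i:
        q = h.apply_rc((p.row, p.col))
        if image_shape is not None and not (
            0 <= q[0] <= image_shape[0] - 1 and 0 <= q[1] <= image_shape[1] - 1
        ):
            continue
        n_eval += 1
        if len(points_j) and np.hypot(coords_j[:, 0] - q[0], coords_j[:, 1] - q[1]).min() < params.correct_radius:
            n_repeat += 1

    errors = []
    for mres in matches:
        q = h.apply_rc(mres.p_i)
        errors.append(float(np.hypot(mres.p_j[0] - q[0], mres.p_j[1] - q[1])))

    variance = None
    if image_shape is not None and len(matches) >= 2:
        pos = np.array([mres.p_j for mres in matches], dtype=np.float64)
        diag2 = image_shape[0] ** 2 + image_shape[1] ** 2
        variance = float(np.mean(np.var(pos, axis=0)) / diag2)

    return {
        "n_points_i": len(points_i),
        "n_points_j": len(points_j),
        "n_matches": len(matches),
        "repeatability": (n_repeat / n_eval) if n_eval else None,
        "average_error": (float(np.mean(errors)) if errors else None),
        "variance": variance,
        "correctness": (
            float(np.mean([mres.correct for mres in matches])) if matches else None
        ),
    }
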