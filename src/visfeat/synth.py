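"""Seeded synthetic luminal scenes with exact ground truth.

Emulates the features of endoscopic vessel imagery that the pipeline must
cope with: dark tubular vessels of varying width on a brighter smoothly
varying tissue background, branching trees with known bifurcation
coordinates, saturated specular blobs, a dark circular field-of-view
border, and frame pairs related by a known homography.  Trees are grown as
self-avoiding random walks (distinct branches keep a safety margin from
each other, so the recorded bifurcations are the only junctions in the
scene), and every artifact is a pure function of the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from visfeat.fusion import RidgeImage
from visfeat.match import Homography

_BRANCH_MARGIN = 9  # min distance (px) kept between distinct branches
_MIN_ARM = 12  # every arm of a recorded bifurcation is at least this long
_BIF_SEP = 16  # min spacing between recorded bifurcations


@dataclass
class VesselTreeSpec:
    """Generation conditions for one scene.

    widths are in pixels (full width at half depth of the Gaussian
    cross-profile), contrast is the fractional darkening of the background
    at a vessel centerline, noise_sigma the additive Gaussian noise level
    applied inside the field of view.
    """

    seed: int = 0
    n_roots: int = 2
    branch_prob: float = 0.05
    width_range: tuple[float, float] = (1.5, 6.0)
    contrast: float = 0.5
    image_size: tuple[int, int] = (256, 256)
    border: bool = True
    n_highlights: int = 3
    noise_sigma: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.width_range
        if not (1.0 <= lo <= hi <= 8.0):
            raise ValueError("widths must lie in [1, 8]")
        if not 0.0 < self.contrast < 1.0:
            raise ValueError("contrast must lie in (0, 1)")
        if min(self.image_size) < 64:
            raise ValueError("image_size must be at least 64x64")
        if self.n_roots < 1 or self.n_roots > min(self.image_size) // 32:
            raise ValueError("infeasible number of roots for this image size")


@dataclass
class SceneTruth:
    """Exact ground truth for one rendered scene."""

    centerline_mask: np.ndarray
    bifurcations: list[tuple[int, int]]
    highlight_mask: np.ndarray
    fov_mask: np.ndarray
    branches: list[dict] = field(default_factory=list, repr=False)
    n_components: int = 0
    homography: Homography | None = None


def _fov_disk(shape: tuple[int, int]) -> tuple[np.ndarray, tuple[float, float], float]:
    h, w = shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    radius = 0.47 * min(h, w)
    rr, cc_grid = np.mgrid[0:h, 0:w]
    disk = ((rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius**2).astype(np.uint8)
    return disk, (cr, cc), radius


def generate_tree(spec: VesselTreeSpec) -> SceneTruth:
    """Grow a self-avoiding branching vessel tree inside the field of view.

    Deterministic given the seed.  Branch growth is a unit-step random walk
    with small heading jitter; bifurcations spawn with probability
    ``branch_prob`` per step, are kept at least 16 px apart, and are only
    recorded when all three arms reach 12 px, so every recorded bifurcation
    is a genuine >= 3-degree node of the rasterized centerline graph.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    fov, (cr, cc), fov_r = _fov_disk((h, w))
    if not spec.border:
        fov = np.ones((h, w), dtype=np.uint8)
    grow_r = fov_r - 10  # keep growth clear of the dark annulus

    occ = np.full((h, w), -1, dtype=np.int32)
    branches: list[dict] = []
    bif_events: list[dict] = []

    def inside(p: np.ndarray) -> bool:
        if spec.border:
            return (p[0] - cr) ** 2 + (p[1] - cc) ** 2 <= grow_r**2
        return 8 <= p[0] < h - 8 and 8 <= p[1] < w - 8

    def blocked(p: np.ndarray, bid: int, parent: int, spawn: np.ndarray | None) -> bool:
        r0, c0 = int(round(p[0])), int(round(p[1]))
        r1, r2 = max(r0 - _BRANCH_MARGIN, 0), min(r0 + _BRANCH_MARGIN + 1, h)
        c1, c2 = max(c0 - _BRANCH_MARGIN, 0), min(c0 + _BRANCH_MARGIN + 1, w)
        win = occ[r1:r2, c1:c2]
        ids = np.unique(win[win >= 0])
        for other in ids:
            if other == bid:
                continue
            if other == parent and spawn is not None and np.hypot(*(p - spawn)) < 14:
                continue
            return True
        return False

    def grow(start: np.ndarray, heading: float, width: float, length: float,
             bid: int, parent: int, depth: int) -> None:
        pts = [start.copy()]
        p = start.copy()
        spawn = start.copy() if parent >= 0 else None
        steps = int(length)
        since_branch = 0
        for _ in range(steps):
            heading += rng.normal(0.0, 0.035)
            p = p + np.array([np.sin(heading), np.cos(heading)])
            if not inside(p) or blocked(p, bid, parent, spawn):
                break
            pts.append(p.copy())
            occ[int(round(p[0])), int(round(p[1]))] = bid
            since_branch += 1
            if (
                depth < 3
                and since_branch > _MIN_ARM
                and len(branches) + len(bif_events) < 24
                and rng.random() < spec.branch_prob
            ):
                far = all(
                    np.hypot(p[0] - b["point"][0], p[1] - b["point"][1]) >= _BIF_SEP
                    for b in bif_events
                )
                if far:
                    side = 1.0 if rng.random() < 0.5 else -1.0
                    child_heading = heading + side * rng.uniform(0.6, 1.2)
                    child_width = max(width * 0.7, spec.width_range[0])
                    child_id = len(branches) + len(bif_events) + spec.n_roots + 100
                    bif_events.append(
                        {
                            "point": p.copy(),
                            "branch": bid,
                            "step": len(pts) - 1,
                            "child": {
                                "start": p.copy(),
                                "heading": child_heading,
                                "width": child_width,
                                "length": max(length * 0.5, 30.0),
                                "id": child_id,
                                "parent": bid,
                                "depth": depth + 1,
                            },
                        }
                    )
                    heading -= side * 0.2  # parent deflects away from the child
                    since_branch = 0
        branches.append(
            {"id": bid, "points": np.array(pts), "width": width, "root": parent < 0, "parent": parent}
        )

    # roots start in the interior; retry placement until the start pixel is
    # clear of previously grown roots
    for i in range(spec.n_roots):
        for _attempt in range(64):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.05, 0.35) * grow_r if spec.border else 0.25 * min(h, w)
            start = np.array([cr + rad * np.sin(ang), cc + rad * np.cos(ang)])
            if inside(start) and not blocked(start, i, -2, None):
                break
        width = rng.uniform(0.7 * spec.width_range[1], spec.width_range[1])
        grow(start, rng.uniform(0, 2 * np.pi), width, rng.uniform(0.5, 0.8) * min(h, w), i, -1, 0)

    # grow spawned children breadth-first (they may spawn further children)
    idx = 0
    while idx < len(bif_events):
        ev = bif_events[idx]
        ch = ev["child"]
        grow(ch["start"], ch["heading"], ch["width"], ch["length"], ch["id"], ch["parent"], ch["depth"])
        idx += 1

    # keep the raster and the bifurcation list consistent: a child branch
    # survives only when its bifurcation is recorded (all three arms long
    # enough and its parent survives), so recorded bifurcations are exactly
    # the junctions present in the scene
    by_id = {b["id"]: b for b in branches}
    kept_ids = {b["id"] for b in branches if b["root"] and len(b["points"]) >= 8}
    bifurcations: list[tuple[int, int]] = []
    for ev in bif_events:  # creation order: parents are decided first
        parent_b = by_id.get(ev["branch"])
        child_b = by_id.get(ev["child"]["id"])
        if parent_b is None or child_b is None or ev["branch"] not in kept_ids:
            continue
        before = ev["step"]
        after = len(parent_b["points"]) - 1 - ev["step"]
        if len(child_b["points"]) < _MIN_ARM or before < _MIN_ARM or after < _MIN_ARM:
            continue
        # the raster junction is where the child's pixels stop coinciding
        # with the parent's, which can trail the spawn point by a few steps
        parent_px = {tuple(q) for q in np.round(parent_b["points"]).astype(int)}
        jr, jc = int(round(ev["point"][0])), int(round(ev["point"][1]))
        for q in np.round(child_b["points"]).astype(int):
            if (int(q[0]), int(q[1])) in parent_px:
                jr, jc = int(q[0]), int(q[1])
            else:
                break
        bifurcations.append((jr, jc))
        kept_ids.add(ev["child"]["id"])
    branches = [b for b in branches if b["id"] in kept_ids]

    mask = np.zeros((h, w), dtype=np.uint8)
    for b in branches:
        pts = np.round(b["points"]).astype(int)
        mask[pts[:, 0], pts[:, 1]] = 1
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))

    return SceneTruth(
        centerline_mask=mask,
        bifurcations=bifurcations,
        highlight_mask=np.zeros((h, w), dtype=np.uint8),
        fov_mask=fov,
        branches=branches,
        n_components=int(n_comp),
    )


def _background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    coarse = rng.uniform(size=(6, 6))
    zoom = (shape[0] / 6, shape[1] / 6)
    bg = ndimage.zoom(coarse, zoom, order=3, mode="nearest")[: shape[0], : shape[1]]
    if bg.shape != shape:
        pad = np.zeros(shape)
        pad[: bg.shape[0], : bg.shape[1]] = bg
        bg = pad
    lo, hi = bg.min(), bg.max()
    if hi > lo:
        bg = (bg - lo) / (hi - lo)
    return 0.55 + 0.3 * bg


def _vessel_depth(truth: SceneTruth, shape: tuple[int, int]) -> np.ndarray:
    """Max over branches of Gaussian cross-profiles around centerlines."""
    depth = np.zeros(shape)
    widths = sorted({round(float(b["width"]) * 2) / 2 for b in truth.branches})
    for wclass in widths:
        canvas = np.zeros(shape, dtype=bool)
        for b in truth.branches:
            if round(float(b["width"]) * 2) / 2 != wclass:
                continue
            pts = np.round(b["points"]).astype(int)
            canvas[pts[:, 0], pts[:, 1]] = True
        if not canvas.any():
            continue
        d = ndimage.distance_transform_edt(~canvas)
        sigma = max(wclass / 2.355, 0.5)
        depth = np.maximum(depth, np.exp(-(d**2) / (2 * sigma**2)))
    return depth


def render(
    truth: SceneTruth,
    spec: VesselTreeSpec,
    rng: np.random.Generator | None = None,
    background: np.ndarray | None = None,
    rgb: bool = False,
) -> np.ndarray:
    """Render a scene from its truth.

    background (smooth field in [0.55, 0.85]) is darkened multiplicatively
    by the vessels' Gaussian cross-profiles, saturated highlight blobs are
    stamped (kept >= 10 px away from vessels and strictly inside the FOV),
    the region outside the field of view is exactly zero, and Gaussian
    noise is added inside the FOV only (the sensor surround is genuinely
    black).  Updates ``truth.highlight_mask`` in place.
    """
    rng = rng or np.random.default_rng(spec.seed + 7919)
    h, w = spec.image_size
    bg = background if background is not None else _background((h, w), rng)
    img = bg * (1.0 - spec.contrast * _vessel_depth(truth, (h, w)))

    hl = np.zeros((h, w), dtype=np.uint8)
    if spec.n_highlights > 0:
        vessel_dist = ndimage.distance_transform_edt(truth.centerline_mask == 0)
        interior = ndimage.binary_erosion(truth.fov_mask, iterations=15, border_value=0)
        ok = interior & (vessel_dist >= 10)
        rows, cols = np.nonzero(ok)
        if rows.size:
            for _ in range(spec.n_highlights):
                k = rng.integers(rows.size)
                rad = rng.uniform(2.0, 4.0)
                rr, cc = np.mgrid[0:h, 0:w]
                blob = (rr - rows[k]) ** 2 + (cc - cols[k]) ** 2 <= rad**2
                hl[blob] = 1
    truth.highlight_mask = hl

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape) * truth.fov_mask
    img[hl > 0] = 1.0
    img *= truth.fov_mask
    img = np.clip(img, 0.0, 1.0)
    if not rgb:
        return img
    r = 0.3 + 0.4 * img
    b = 0.2 + 0.2 * img
    out = np.stack([r * truth.fov_mask, img, b * truth.fov_mask], axis=-1)
    return np.clip(out, 0.0, 1.0)


def make_homography(
    shape: tuple[int, int],
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
) -> Homography:
    """Similarity homography about the image center.

    ``translation`` is (drow, dcol) in pixels; rotation is counterclockwise
    in the (x=col, y=row) plane.
    """
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    th = np.deg2rad(rotation_deg)
    rs = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = np.array([cx + translation[1], cy + translation[0]])
    m = np.eye(3)
    m[:2, :2] = rs
    m[:2, 2] = t - rs @ np.array([cx, cy])
    return Homography(m)


def generate_pair(
    spec: VesselTreeSpec,
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
) -> tuple[tuple[np.ndarray, SceneTruth], tuple[np.ndarray, SceneTruth], Homography]:
    """Render the same vessel tree from two viewpoints.

    Frame J is the frame-I scene mapped through the returned homography:
    centerlines and bifurcations are transformed exactly, the background
    field is resampled through the homography, widths scale with the map,
    and noise/highlights are drawn independently per frame.  Raises when
    fewer than 60% of the centerline points stay in view.
    """
    truth_i = generate_tree(spec)
    hmap = make_homography(spec.image_size, rotation_deg, translation, scale)

    h, w = spec.image_size
    branches_j = []
    n_in = n_tot = 0
    for b in truth_i.branches:
        pts_j = hmap.apply_rc(b["points"])
        keep = (
            (pts_j[:, 0] >= 1) & (pts_j[:, 0] <= h - 2) & (pts_j[:, 1] >= 1) & (pts_j[:, 1] <= w - 2)
        )
        n_tot += len(pts_j)
        n_in += int(keep.sum())
        if keep.sum() >= 2:
            # resample to unit arclength spacing where scaled steps exceed
            # one pixel, so the raster stays 8-connected
            pts_k = pts_j[keep]
            seg = np.hypot(*np.diff(pts_k, axis=0).T)
            if seg.max(initial=0.0) > 1.0 + 1e-9:
                arc = np.concatenate([[0.0], np.cumsum(seg)])
                n_new = max(int(np.ceil(arc[-1])) + 1, 2)
                ts = np.linspace(0.0, arc[-1], n_new)
                pts_k = np.column_stack(
                    [np.interp(ts, arc, pts_k[:, 0]), np.interp(ts, arc, pts_k[:, 1])]
                )
            branches_j.append({**b, "points": pts_k, "width": b["width"] * scale})
    if n_tot == 0 or n_in / n_tot < 0.6:
        raise ValueError("transform leaves less than 60% of the tree in view")

    fov, _, _ = _fov_disk((h, w))
    if not spec.border:
        fov = np.ones((h, w), dtype=np.uint8)
    mask_j = np.zeros((h, w), dtype=np.uint8)
    for b in branches_j:
        pts = np.round(b["points"]).astype(int)
        mask_j[pts[:, 0], pts[:, 1]] = 1
    # frame-J bifurcations are the divergence points of frame J's own
    # raster (where each child's pixels stop coinciding with its parent's)
    # — the raster junction can trail the geometric spawn point, and by a
    # different amount in each view
    by_id_j = {b["id"]: b for b in branches_j}
    bif_j = []
    for b in branches_j:
        parent = by_id_j.get(b.get("parent", -1))
        if parent is None:
            continue
        parent_px = {tuple(q) for q in np.round(parent["points"]).astype(int)}
        child_px = np.round(b["points"]).astype(int)
        jr, jc = int(child_px[0][0]), int(child_px[0][1])
        for q in child_px:
            if (int(q[0]), int(q[1])) in parent_px:
                jr, jc = int(q[0]), int(q[1])
            else:
                break
        if 0 <= jr < h and 0 <= jc < w and fov[jr, jc]:
            bif_j.append((jr, jc))
    _, n_comp_j = ndimage.label(mask_j, structure=np.ones((3, 3)))
    truth_j = SceneTruth(
        centerline_mask=mask_j,
        bifurcations=bif_j,
        highlight_mask=np.zeros((h, w), dtype=np.uint8),
        fov_mask=fov,
        branches=branches_j,
        n_components=int(n_comp_j),
        homography=hmap,
    )
    truth_i.homography = hmap

    rng_i = np.random.default_rng(spec.seed + 7919)
    bg_i = _background((h, w), rng_i)
    img_i_no_noise_bg = bg_i  # frame-J background is this field seen through H
    img_i = render(truth_i, spec, rng=rng_i, background=bg_i)

    # resample the background through the inverse map
    hinv = hmap.inverse()
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    src = hinv.apply_rc(np.column_stack([rr.ravel(), cc.ravel()]))
    bg_j = ndimage.map_coordinates(
        img_i_no_noise_bg, [src[:, 0].reshape(h, w), src[:, 1].reshape(h, w)], order=1, mode="nearest"
    )
    rng_j = np.random.default_rng(spec.seed + 104729)
    img_j = render(truth_j, spec, rng=rng_j, background=bg_j)
    return (img_i, truth_i), (img_j, truth_j), hmap


def truth_ridge(truth: SceneTruth) -> RidgeImage:
    """Ground-truth centerline packaged as a RidgeImage.

    Tangents come from finite differences along each branch polyline; the
    strength is 1 on the support.  Useful for exercising the detector and
    matcher in isolation from the enhancement stages.
    """
    shape = truth.centerline_mask.shape
    direction = np.zeros(shape + (2,))
    for b in truth.branches:
        pts = b["points"]
        if len(pts) < 2:
            continue
        tang = np.gradient(pts, axis=0)
        norms = np.hypot(tang[:, 0], tang[:, 1])
        norms[norms < 1e-9] = 1.0
        tang = tang / norms[:, None]
        ridx = np.round(pts).astype(int)
        direction[ridx[:, 0], ridx[:, 1]] = tang
    support = truth.centerline_mask.astype(np.uint8)
    return RidgeImage(
        support=support, strength=support.astype(np.float64), direction=direction
    )
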