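"""Dual-circumference branch-point detection (CDVB) with NMS.

A vascular bifurcation is a centerline pixel whose surrounding discrete
circle crosses three or more vessel segments.  Each candidate is tested
against circles of increasing radius (default 5 then 7 px — the second
circle recovers junctions whose arms merge at the smaller radius); runs of
on-pixels along the circumference are counted with wraparound, and the
peak (strongest) pixel of each run is recorded as the intersection
coordinate.  Accepted points are scored FAST-style over the circumference
and thinned by connectivity-based non-maximum suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from visfeat.fusion import RidgeImage


@dataclass(frozen=True)
class CircleTemplate:
    """Ordered (drow, dcol) offsets tracing a discrete circle
    counterclockwise from (0, +radius)."""

    radius: int
    offsets: tuple[tuple[int, int], ...]


@dataclass
class BranchPoint:
    row: int
    col: int
    radius_hit: int
    crossings: int
    score_v: float
    peak_positions: tuple[tuple[int, int], ...] = ()
    raw_exceed_count: int = 0  # per-pixel |I_x - I_p| > eps_d count, for audit


@dataclass
class DetectParams:
    """radii: circle radii tried in order; eps_d: intensity-difference
    threshold on the circumference; min_crossings: runs needed to accept;
    nms_radius: Chebyshev suppression neighborhood; candidates: 'junction'
    pre-filters to skeleton pixels with >= 3 on-neighbors, 'all' scans
    every ridge pixel."""

    radii: tuple[int, ...] = (5, 7)
    eps_d: float = 0.5
    min_crossings: int = 3
    nms_radius: int = 7
    candidates: str = "junction"

    def __post_init__(self) -> None:
        radii = tuple(int(r) for r in self.radii)
        if any(b <= a for a, b in zip(radii, radii[1:])) or any(r < 1 for r in radii):
            raise ValueError("radii must be ascending positive integers")
        self.radii = radii
        if self.candidates not in ("junction", "all"):
            raise ValueError("candidates must be 'junction' or 'all'")


def circle_template(radius: int) -> CircleTemplate:
    """Discrete-circle offsets in counterclockwise order starting at
    (0, +radius).  Radius 1 uses the full 8-neighbor ring by convention;
    larger radii use the midpoint circle thickened to 4-connectivity, so an
    8-connected centerline can never cross the circumference between two
    diagonal raster pixels without touching it."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius == 1:
        pts = {(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)} - {(0, 0)}
    else:
        pts = set()
        x, y, err = radius, 0, 1 - radius
        while x >= y:
            for dr, dc in (
                (y, x), (x, y), (x, -y), (y, -x),
                (-y, -x), (-x, -y), (-x, y), (-y, x),
            ):
                pts.add((dr, dc))
            y += 1
            if err < 0:
                err += 2 * y + 1
            else:
                x -= 1
                err += 2 * (y - x) + 1
    ordered = sorted(pts, key=lambda p: (np.arctan2(-p[0], p[1])) % (2 * np.pi))
    if radius > 1:
        # fill diagonal steps with the intermediate pixel nearest the radius
        filled: list[tuple[int, int]] = []
        n = len(ordered)
        for i, (r0, c0) in enumerate(ordered):
            filled.append((r0, c0))
            r1, c1 = ordered[(i + 1) % n]
            if abs(r1 - r0) == 1 and abs(c1 - c0) == 1:
                cand_a, cand_b = (r0, c1), (r1, c0)
                da = abs(np.hypot(*cand_a) - radius)
                db = abs(np.hypot(*cand_b) - radius)
                filled.append(cand_a if da <= db else cand_b)
        ordered = filled
    return CircleTemplate(radius=radius, offsets=tuple(ordered))


def count_crossings(
    ridge: RidgeImage,
    p: tuple[int, int],
    template: CircleTemplate,
    eps_d: float = 0.5,
    connected_only: bool = True,
) -> tuple[int, list[tuple[int, int]]] | None:
    """Count vessel crossings of the circumference around p.

    A circumference pixel is "on" when its value differs from the center by
    at most eps_d (for a binary ridge with p on a vessel this is simply a
    ridge pixel); a crossing is a maximal run of on-pixels, with wraparound
    across the start of the template.  Each run's peak (maximal-strength)
    coordinate is recorded.  With ``connected_only`` (the default) only
    runs reachable from p through ridge pixels inside the circle's disk are
    counted — a branch point is a pixel with three or more vessel segments
    *centered on it*, so unrelated vessels that merely graze the circle do
    not contribute.  Returns None (skip signal) when the circle does not
    fit inside the image.
    """
    h, w = ridge.support.shape
    r0, c0 = p
    if not (0 <= r0 < h and 0 <= c0 < w):
        return None
    rr = r0 + np.array([o[0] for o in template.offsets])
    cc = c0 + np.array([o[1] for o in template.offsets])
    if rr.min() < 0 or rr.max() >= h or cc.min() < 0 or cc.max() >= w:
        return None
    vals = ridge.support[rr, cc].astype(np.float64)
    center = float(ridge.support[r0, c0])
    on = np.abs(vals - center) <= eps_d
    if connected_only and center > 0:
        rad = max(max(abs(o[0]), abs(o[1])) for o in template.offsets)
        sub = ridge.support[r0 - rad : r0 + rad + 1, c0 - rad : c0 + rad + 1] > 0
        dr, dc = np.mgrid[-rad : rad + 1, -rad : rad + 1]
        disk = dr * dr + dc * dc <= (template.radius + 0.5) ** 2
        for orow, ocol in template.offsets:  # circle pixels always count
            disk[rad + orow, rad + ocol] = True
        lab, _ = ndimage.label(sub & disk, structure=np.ones((3, 3)))
        comp = lab[rad, rad]
        on = on & (lab[rr - (r0 - rad), cc - (c0 - rad)] == comp)

    n = on.size
    if not on.any():
        return 0, []
    if on.all():
        k = int(np.argmax(ridge.strength[rr, cc]))
        return 1, [(int(rr[k]), int(cc[k]))]

    # rotate so the walk starts just after an off-pixel: runs never wrap
    start = int(np.argmin(on))
    idx = (np.arange(n) + start) % n
    on_rot = on[idx]
    peaks: list[tuple[int, int]] = []
    runs = 0
    i = 0
    while i < n:
        if on_rot[i]:
            j = i
            while j < n and on_rot[j]:
                j += 1
            seg = idx[i:j]
            k = seg[int(np.argmax(ridge.strength[rr[seg], cc[seg]]))]
            peaks.append((int(rr[k]), int(cc[k])))
            runs += 1
            i = j
        else:
            i += 1
    return runs, peaks


def _score_v(ridge: RidgeImage, p: tuple[int, int], template: CircleTemplate, eps_d: float) -> tuple[float, int]:
    """FAST-style circumference score: sum of max(|I_x - I_p| - eps_d, 0),
    collapsing the bright/dark case split via the absolute difference.
    Also returns the raw count of pixels exceeding eps_d (audit value)."""
    rr = p[0] + np.array([o[0] for o in template.offsets])
    cc = p[1] + np.array([o[1] for o in template.offsets])
    diff = np.abs(ridge.support[rr, cc].astype(np.float64) - float(ridge.support[p]))
    return float(np.maximum(diff - eps_d, 0.0).sum()), int((diff > eps_d).sum())


def detect_branch_points(
    ridge: RidgeImage,
    params: DetectParams | None = None,
    mask: np.ndarray | None = None,
) -> list[BranchPoint]:
    """Unsuppressed branch-point detections on a single-pixel ridge.

    Candidates (junction-like skeleton pixels, or every ridge pixel with
    ``candidates='all'``) are tested against each radius in order; the
    first circle with >= min_crossings runs accepts the candidate.  Border
    and masked-out candidates are skipped.
    """
    params = params or DetectParams()
    templates = [circle_template(r) for r in params.radii]
    sup = ridge.support.astype(np.uint8)
    if params.candidates == "junction":
        nb = ndimage.convolve(sup, np.ones((3, 3), dtype=np.uint8), mode="constant") - sup
        cand = (sup > 0) & (nb >= 3)
    else:
        cand = sup > 0
    out: list[BranchPoint] = []
    for r0, c0 in zip(*np.nonzero(cand)):
        if mask is not None and mask[r0, c0] == 0:
            continue
        first: BranchPoint | None = None
        score = 0.0
        for tpl in templates:
            res = count_crossings(ridge, (int(r0), int(c0)), tpl, params.eps_d)
            if res is None:
                continue
            runs, peaks = res
            if runs >= params.min_crossings:
                v, raw = _score_v(ridge, (int(r0), int(c0)), tpl, params.eps_d)
                score += v  # every accepting circle adds support for the point
                if first is None:
                    first = BranchPoint(
                        row=int(r0),
                        col=int(c0),
                        radius_hit=tpl.radius,
                        crossings=runs,
                        score_v=0.0,
                        peak_positions=tuple(peaks),
                        raw_exceed_count=raw,
                    )
        if first is not None:
            first.score_v = score
            out.append(first)
    return out


def localize(
    kept: list[BranchPoint],
    raw: list[BranchPoint],
    window: int = 5,
) -> list[BranchPoint]:
    """Consensus localization of suppressed detections.

    Each surviving point is moved to the rounded score-weighted centroid
    of all raw detections within Chebyshev distance ``window`` — the
    candidate cloud surrounds the junction from every arm, so its centroid
    is far more stable across viewpoints than any single maximum-score
    member.  Scores and circle records are kept from the winning member.
    """
    if not raw or not kept:
        return list(kept)
    coords = np.array([(p.row, p.col) for p in raw], dtype=np.float64)
    scores = np.array([p.score_v for p in raw], dtype=np.float64)
    out: list[BranchPoint] = []
    for p in kept:
        sel = np.max(np.abs(coords - (p.row, p.col)), axis=1) <= window
        wgt = scores[sel]
        if wgt.sum() <= 0:
            wgt = np.ones(int(sel.sum()))
        cr, cc = (coords[sel] * wgt[:, None]).sum(axis=0) / wgt.sum()
        out.append(replace(p, row=int(round(cr)), col=int(round(cc))))
    return out


def nms(points: list[BranchPoint], nms_radius: int = 7) -> list[BranchPoint]:
    """Greedy non-maximum suppression.

    Points are visited in decreasing score order (ties: topmost, then
    leftmost); each accepted point suppresses every remaining point within
    Chebyshev distance nms_radius, so no two survivors are closer than
    that.  Greedy suppression (rather than keeping one point per
    transitively connected cluster) lets two genuine junctions two-to-three
    circle radii apart both survive even when weaker detections trail along
    the arms between them.
    """
    if not points:
        return []
    order = sorted(range(len(points)), key=lambda i: (-points[i].score_v, points[i].row, points[i].col))
    coords = np.array([(p.row, p.col) for p in points])
    # a detection first accepted at circle radius r localizes its junction
    # only to within r, so its own suppression window grows with r
    windows = np.array([max(nms_radius, p.radius_hit + 2) for p in points])
    alive = np.ones(len(points), dtype=bool)
    kept = []
    for i in order:
        if not alive[i]:
            continue
        kept.append(points[i])
        alive &= np.max(np.abs(coords - coords[i]), axis=1) > np.maximum(nms_radius, windows)
    kept.sort(key=lambda p: (p.row, p.col))
    return kept
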