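"""Evaluation harness against synthetic ground truth.

These helpers quantify ridge quality (centerline coverage, connectivity,
single-pixel cross-sections) and detector quality (precision/recall of
branch points at a correctness radius) on scenes with known truth.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from visfeat.detect import BranchPoint
from visfeat.synth import SceneTruth


def centerline_coverage(ridge_support: np.ndarray, truth: SceneTruth, tol: float = 1.5) -> float:
    """Fraction of truth centerline pixels within ``tol`` px of a ridge pixel."""
    if ridge_support.sum() == 0:
        return 0.0
    d = ndimage.distance_transform_edt(ridge_support == 0)
    cl = truth.centerline_mask > 0
    if not cl.any():
        return 1.0
    return float((d[cl] <= tol).mean())


def component_count(ridge_support: np.ndarray) -> int:
    """8-connected component count of the ridge support."""
    _, n = ndimage.label(ridge_support, structure=np.ones((3, 3)))
    return int(n)


def cross_section_widths(
    ridge_support: np.ndarray,
    truth: SceneTruth,
    sample_step: int = 3,
    junction_margin: float = 6.0,
    end_margin: int = 6,
    corridor: float = 3.0,
) -> list[int]:
    """Ridge widths (px) across sampled truth-centerline normals.

    At every ``sample_step``-th point of each truth branch interior (at
    least ``junction_margin`` px from any bifurcation and ``end_margin``
    steps from the branch ends — a cross-vessel direction only exists on
    vessel interiors), ridge pixels are collected in a
    corridor of +-``corridor`` px along the truth normal.  The
    cross-section is the 8-connected cluster of hits nearest the truth
    point; its width is 1 when it spans less than 2 px along the normal
    and contains no solid 2x2 block (L-shaped corners of a digital curve
    are width 1; genuine thickening is not), else 2 (or more, rounded
    from the span).
    """
    h, w = ridge_support.shape
    block = np.zeros((h, w), dtype=bool)
    s = ridge_support.astype(bool)
    block[:-1, :-1] = s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]
    widths: list[int] = []
    for b in truth.branches:
        pts = b["points"]
        if len(pts) < 5:
            continue
        tang = np.gradient(pts, axis=0)
        tang /= np.maximum(np.hypot(tang[:, 0:1], tang[:, 1:2]), 1e-9)
        for i in range(end_margin, len(pts) - end_margin, sample_step):
            p = pts[i]
            if truth.bifurcations and min(
                np.hypot(p[0] - r, p[1] - c) for r, c in truth.bifurcations
            ) < junction_margin:
                continue
            nrm = np.array([-tang[i, 1], tang[i, 0]])
            hits: set[tuple[int, int]] = set()
            for t in np.arange(-corridor, corridor + 1e-9, 0.25):
                q = p + t * nrm
                r0, c0 = int(round(q[0])), int(round(q[1]))
                if 0 <= r0 < h and 0 <= c0 < w and s[r0, c0]:
                    hits.add((r0, c0))
            if not hits:
                continue
            seed = min(hits, key=lambda x: np.hypot(x[0] - p[0], x[1] - p[1]))
            cluster = {seed}
            frontier = [seed]
            while frontier:
                x = frontier.pop()
                for q2 in hits:
                    if q2 not in cluster and max(abs(q2[0] - x[0]), abs(q2[1] - x[1])) <= 1:
                        cluster.add(q2)
                        frontier.append(q2)
            proj = [(px[0] - p[0]) * nrm[0] + (px[1] - p[1]) * nrm[1] for px in cluster]
            span = max(proj) - min(proj)
            has_block = any(
                block[min(a[0], b2[0]), min(a[1], b2[1])]
                for a in cluster
                for b2 in cluster
                if abs(a[0] - b2[0]) == 1 and abs(a[1] - b2[1]) == 1
            )
            widths.append(max(2, int(round(span))) if (span >= 2.0 or has_block) else 1)
    return widths


def match_detections(
    detections: list[BranchPoint] | np.ndarray,
    truth_points: list[tuple[int, int]],
    tol: float = 3.5,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to truth bifurcations.

    Returns (true positives, false positives, false negatives) at the
    given correctness radius.
    """
    if len(detections) and isinstance(detections[0], BranchPoint):
        det = np.array([(p.row, p.col) for p in detections], dtype=float)
    else:
        det = np.asarray(detections, dtype=float).reshape(-1, 2)
    gt = np.asarray(truth_points, dtype=float).reshape(-1, 2)
    used: set[int] = set()
    tp = 0
    for g in gt:
        best_j, best_d = -1, np.inf
        for j in range(len(det)):
            if j in used:
                continue
            d = float(np.hypot(det[j, 0] - g[0], det[j, 1] - g[1]))
            if d < best_d:
                best_j, best_d = j, d
        if best_j >= 0 and best_d <= tol:
            used.add(best_j)
            tp += 1
    return tp, len(det) - tp, len(gt) - tp


def junction_recall(ridge_support: np.ndarray, truth: SceneTruth, tol: float = 2.0) -> float:
    """Fraction of truth bifurcations with a ridge pixel within ``tol`` px."""
    if not truth.bifurcations:
        return 1.0
    if ridge_support.sum() == 0:
        return 0.0
    d = ndimage.distance_transform_edt(ridge_support == 0)
    hits = [d[r, c] <= tol for r, c in truth.bifurcations]
    return float(np.mean(hits))


def centerline_cv(response: np.ndarray, truth: SceneTruth) -> float:
    """Coefficient of variation of a response sampled on the truth
    centerline (junctions included) — the response-uniformity figure."""
    vals = response[truth.centerline_mask > 0]
    if vals.size == 0 or vals.mean() == 0:
        return float("nan")
    return float(vals.std() / vals.mean())
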