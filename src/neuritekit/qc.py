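"""Reconstruction quality alerts and inter-reconstruction comparison.

Sharp-turn outlier detection (turning angle above a threshold), classical
Sholl analysis (sphere crossings versus radius from the soma), total-length
consistency across annotators, pairwise spatial apartness between
reconstructions, and the give-up-rate statistic for annotation attempts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .morphology import NeuronTree, decompose_segments

__all__ = [
    "TurnAlert",
    "ShollCurve",
    "DistanceReport",
    "detect_sharp_turns",
    "sholl_analysis",
    "reconstruction_distance",
    "length_consistency",
    "give_up_rate",
]


@dataclass(frozen=True)
class TurnAlert:
    node_id: int
    turning_angle: float  # degrees; 0 = straight, 180 = reversal
    threshold_used: float
    segment_id: int


@dataclass
class ShollCurve:
    center: tuple[float, float, float]
    radii: np.ndarray
    crossings: np.ndarray


@dataclass
class DistanceReport:
    """Mean nearest-point distances between two reconstructions (voxel units)."""

    mean_ab: float
    mean_ba: float
    mean_bidirectional: float
    lateral_mean_ab: float
    lateral_mean_ba: float
    lateral_mean_bidirectional: float


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float | None:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return None
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def detect_sharp_turns(
    tree: NeuronTree, threshold: float = 90.0, window: int = 1
) -> list[TurnAlert]:
    """Flag nodes where the path bends more than ``threshold`` degrees.

    The turning angle at a node compares the incoming direction (from the
    ancestor ``window`` edges up, clamped at the root) with each outgoing
    direction (to the descendant ``window`` edges down each child chain,
    clamped at the next branch or tip); 0 deg is straight, 180 deg a
    reversal.  The alert fires on strict exceedance; zero-length direction
    vectors are skipped.  Each parent->child continuation at a branch node
    is evaluated independently.
    """
    if not 0 < threshold < 180:
        raise ValueError("threshold must be in (0, 180) degrees")
    if window < 1:
        raise ValueError("window must be >= 1")
    # edge -> id of the segment containing it
    edge_seg: dict[tuple[int, int], int] = {}
    for seg in decompose_segments(tree):
        ids = seg.node_ids
        for a, b in zip(ids, ids[1:]):
            edge_seg[(a, b)] = seg.id
    parent = {n.id: n.parent_id for n in tree.nodes}
    pos = {n.id: n.position for n in tree.nodes}
    alerts: list[TurnAlert] = []
    for n in tree.nodes:
        if n.parent_id == -1 or not tree.children(n.id):
            continue
        # ancestor `window` edges up, clamped at root
        anc = n.id
        for _ in range(window):
            if parent[anc] == -1:
                break
            anc = parent[anc]
        incoming = pos[n.id] - pos[anc]
        for child in tree.children(n.id):
            # descendant `window` edges down, clamped at branch/tip
            desc = child
            for _ in range(window - 1):
                kids = tree.children(desc)
                if len(kids) != 1:
                    break
                desc = kids[0]
            outgoing = pos[desc] - pos[n.id]
            theta = _angle_deg(incoming, outgoing)
            if theta is not None and theta > threshold:
                alerts.append(
                    TurnAlert(
                        node_id=n.id,
                        turning_angle=theta,
                        threshold_used=threshold,
                        segment_id=edge_seg[(n.id, child)],
                    )
                )
    return alerts


def sholl_analysis(
    tree: NeuronTree, radius_step: float, max_radius: float | None = None
) -> ShollCurve:
    """Count neurite crossings of concentric spheres centered at the soma.

    A parent-child edge crosses the sphere of radius r when one endpoint
    lies at distance < r and the other at distance >= r from the center
    (half-open convention: a node exactly on a sphere counts once).
    """
    if radius_step <= 0:
        raise ValueError("radius_step must be positive")
    center = tree.node(tree.root).position
    dist = {n.id: float(np.linalg.norm(n.position - center)) for n in tree.nodes}
    extent = max(dist.values()) if dist else 0.0
    if max_radius is None:
        max_radius = extent + radius_step
    radii = np.arange(radius_step, max_radius + 1e-12, radius_step)
    crossings = np.zeros(len(radii), dtype=int)
    for p, c in tree.edges():
        d1, d2 = dist[p], dist[c]
        lo, hi = min(d1, d2), max(d1, d2)
        # crossing iff lo < r <= hi
        crossings += (lo < radii) & (radii <= hi)
    return ShollCurve(center=tuple(center), radii=radii, crossings=crossings)


def _resample_polylines(tree: NeuronTree, step: float) -> np.ndarray:
    """Sample points along every segment polyline at spacing <= step,
    endpoints included."""
    pts: list[np.ndarray] = []
    for seg in decompose_segments(tree):
        path = np.array([[n.x, n.y, n.z] for n in seg.node_path], dtype=float)
        pts.append(path[0])
        for a, b in zip(path, path[1:]):
            ln = float(np.linalg.norm(b - a))
            if ln == 0:
                pts.append(b)
                continue
            n_sub = max(1, math.ceil(ln / step))
            for i in range(1, n_sub + 1):
                pts.append(a + (b - a) * (i / n_sub))
    return np.array(pts)


def _pieces(tree: NeuronTree) -> tuple[np.ndarray, np.ndarray]:
    starts, ends = [], []
    for p, c in tree.edges():
        starts.append(tree.node(p).position)
        ends.append(tree.node(c).position)
    if not starts:  # single-node tree: degenerate zero-length piece at the node
        pos = tree.node(tree.roots[0]).position
        starts, ends = [pos], [pos]
    return np.array(starts), np.array(ends)


def _min_dist_to_pieces(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Exact point-to-segment distances, minimized over all pieces."""
    ab = ends - starts  # (m, d)
    ab2 = np.einsum("ij,ij->i", ab, ab)  # (m,)
    best = np.full(len(points), np.inf)
    # chunk over points to bound memory
    chunk = max(1, 2_000_000 // max(1, len(starts)))
    for i0 in range(0, len(points), chunk):
        p = points[i0:i0 + chunk]  # (k, d)
        ap = p[:, None, :] - starts[None, :, :]  # (k, m, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.einsum("kmd,md->km", ap, ab) / ab2[None, :]
        t = np.nan_to_num(t, nan=0.0)
        t = np.clip(t, 0.0, 1.0)
        nearest = starts[None, :, :] + t[..., None] * ab[None, :, :]
        d = np.linalg.norm(p[:, None, :] - nearest, axis=-1)
        best[i0:i0 + chunk] = d.min(axis=1)
    return best


def reconstruction_distance(
    a: NeuronTree, b: NeuronTree, sampling_step: float = 1.0
) -> DistanceReport:
    """Mean spatial apartness between two reconstructions.

    Each tree's polylines are resampled at ``sampling_step``; every sample of
    one tree is matched to its exact nearest point on the other tree's
    polylines.  The bidirectional mean symmetrizes the two directions; the
    lateral variant ignores the z coordinate (apartness in the imaging
    plane).
    """
    if sampling_step <= 0:
        raise ValueError("sampling_step must be positive")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty tree")
    pa = _resample_polylines(a, sampling_step)
    pb = _resample_polylines(b, sampling_step)
    sa, ea = _pieces(a)
    sb, eb = _pieces(b)
    mean_ab = float(_min_dist_to_pieces(pa, sb, eb).mean())
    mean_ba = float(_min_dist_to_pieces(pb, sa, ea).mean())
    lat_ab = float(_min_dist_to_pieces(pa[:, :2], sb[:, :2], eb[:, :2]).mean())
    lat_ba = float(_min_dist_to_pieces(pb[:, :2], sa[:, :2], ea[:, :2]).mean())
    return DistanceReport(
        mean_ab=mean_ab,
        mean_ba=mean_ba,
        mean_bidirectional=(mean_ab + mean_ba) / 2,
        lateral_mean_ab=lat_ab,
        lateral_mean_ba=lat_ba,
        lateral_mean_bidirectional=(lat_ab + lat_ba) / 2,
    )


def length_consistency(trees: list[NeuronTree]) -> dict:
    """Spread of total reconstruction length across annotators.

    percent_of_mean = 100 * (max - min) / mean over the tree lengths.
    """
    from .morphology import total_length

    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    lengths = [total_length(t) for t in trees]
    mean = float(np.mean(lengths))
    max_abs_diff = float(max(lengths) - min(lengths))
    return {
        "lengths": lengths,
        "mean_length": mean,
        "max_abs_diff": max_abs_diff,
        "percent_of_mean": 100.0 * max_abs_diff / mean if mean > 0 else float("nan"),
    }


def give_up_rate(attempts: list[dict]) -> float:
    """Fraction of failed annotation attempts: (#failed)/(#all).

    Each attempt is a record with a boolean ``succeeded`` field (annotator id
    is informational).
    """
    if not attempts:
        raise ValueError("no attempts")
    failed = sum(1 for a in attempts if not a["succeeded"])
    return failed / len(attempts)
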