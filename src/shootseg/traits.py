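"""Organ-level phenotypic trait extraction from segmented point clouds.

Three traits are measured, all in millimetres:

* **stem diameter** — the stem points are split into 4 equal slices along z;
  a 3D line is fitted to the lowest slice by orthogonal least squares (the
  principal axis through the slice centroid) and the diameter is twice the
  median perpendicular point-to-line distance.  For points exactly on a
  cylinder surface this recovers the true diameter regardless of angular
  sampling.
* **leaf length** — the geodesic (shortest path on a k-nearest-neighbour
  graph) between the two extreme points of the leaf along its first
  principal axis.
* **leaf width** — the leaf is split into 5 equal bins along the first
  principal axis; in each bin the geodesics between the second- and
  third-axis extreme pairs are computed, and the longest such path is the
  width.

Geodesics run on the raw points; a straight leaf measured this way equals
its chord, a curved leaf its arc length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .cloud import LEAF, STEM, LabeledPointCloud, ValidationError


@dataclass
class TraitRecord:
    """Measured traits of one plant; ``None`` marks a failed measurement."""

    stem_diameter: float | None
    #: (instance_id, leaf_length | None, leaf_width | None) per leaf instance
    leaves: list[tuple[int, float | None, float | None]] = field(default_factory=list)

    def as_rows(self, plant_id: str = "") -> list[dict]:
        rows = []
        if self.stem_diameter is not None:
            rows.append({"plant_id": plant_id, "instance_id": 0,
                         "trait": "stem_diameter", "value_mm": self.stem_diameter})
        for iid, length, width in self.leaves:
            if length is not None:
                rows.append({"plant_id": plant_id, "instance_id": iid,
                             "trait": "leaf_length", "value_mm": length})
            if width is not None:
                rows.append({"plant_id": plant_id, "instance_id": iid,
                             "trait": "leaf_width", "value_mm": width})
        return rows


# ---------------------------------------------------------------------------
# stem


def stem_diameter(stem_points: np.ndarray) -> float:
    """Twice the median perpendicular distance from the lowest z-quartile of
    the stem to its orthogonal-least-squares line."""
    pts = np.asarray(stem_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 8:
        raise ValidationError("stem diameter needs >= 8 points of shape (N, 3)")
    z = pts[:, 2]
    z_lo, z_hi = z.min(), z.max()
    if z_hi == z_lo:
        raise ValidationError("stem points span zero z range")
    lowest = pts[z <= z_lo + (z_hi - z_lo) / 4.0]
    if lowest.shape[0] < 3:
        raise ValidationError("lowest stem slice has fewer than 3 points")
    centered = lowest - lowest.mean(axis=0)
    cov = centered.T @ centered
    if not np.any(cov):
        raise ValidationError("degenerate stem slice: all points identical")
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    along = centered @ axis
    perp = centered - along[:, None] * axis
    return 2.0 * float(np.median(np.linalg.norm(perp, axis=1)))


# ---------------------------------------------------------------------------
# geodesics


def _knn_graph(pts: np.ndarray, k: int):
    n = pts.shape[0]
    k_eff = min(k + 1, n)
    dist, idx = cKDTree(pts).query(pts, k=k_eff)
    if n == 1:
        return coo_matrix((1, 1))
    rows = np.repeat(np.arange(n), k_eff - 1)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    return coo_matrix((vals, (rows, cols)), shape=(n, n))


def geodesic_path_length(points: np.ndarray, idx_a: int, idx_b: int, k: int = 10) -> float:
    """Shortest-path length between two points on the k-NN graph with
    Euclidean edge weights; falls back to the straight-line distance (with a
    warning) when the graph is disconnected between them."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 2:
        raise ValidationError("geodesic needs at least 2 points")
    if not (0 <= idx_a < n and 0 <= idx_b < n):
        raise ValidationError(f"indices out of range for {n} points")
    if idx_a == idx_b:
        return 0.0
    graph = _knn_graph(pts, k)
    d = dijkstra(graph, directed=False, indices=idx_a)[idx_b]
    if not np.isfinite(d):
        warnings.warn(
            "k-NN graph disconnected between the end points; "
            "falling back to straight-line distance",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.linalg.norm(pts[idx_a] - pts[idx_b]))
    return float(d)


# ---------------------------------------------------------------------------
# leaves


def _pca_axes(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    w, v = np.linalg.eigh(centered.T @ centered)
    order = np.argsort(w)[::-1]
    return v[:, order]  # columns = PC1, PC2, PC3


def _extreme_on_axis(proj: np.ndarray, ortho: np.ndarray, side: str) -> int:
    """Index of the extreme point along a projection; among candidates within
    1% of the projection range of the extreme, the one closest to the
    centroid in the orthogonal components is taken (direction-independent,
    and stable when a whole edge ties)."""
    span = proj.max() - proj.min()
    lim = proj.max() - 0.01 * span if side == "max" else proj.min() + 0.01 * span
    cand = np.flatnonzero(proj >= lim) if side == "max" else np.flatnonzero(proj <= lim)
    off = ortho[cand] - ortho.mean(axis=0)
    return int(cand[np.argmin(np.linalg.norm(off, axis=1))])


def leaf_length(leaf_points: np.ndarray, k: int = 10) -> float:
    """Geodesic between the two extreme points along the first principal axis."""
    pts = np.asarray(leaf_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 10:
        raise ValidationError("leaf length needs >= 10 points of shape (N, 3)")
    axes = _pca_axes(pts)
    proj = (pts - pts.mean(axis=0)) @ axes[:, 0]
    if proj.max() == proj.min():
        raise ValidationError("degenerate leaf: no spread along any axis")
    ortho = (pts - pts.mean(axis=0)) @ axes[:, 1:]
    a = _extreme_on_axis(proj, ortho, "min")
    b = _extreme_on_axis(proj, ortho, "max")
    return geodesic_path_length(pts, a, b, k=k)


def leaf_width(leaf_points: np.ndarray, k: int = 10, n_bins: int = 5) -> float:
    """Longest geodesic between second/third-axis extreme pairs over equal
    bins of the first-axis projection; empty or single-point bins are
    skipped (gappy leaves are expected)."""
    pts = np.asarray(leaf_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 10:
        raise ValidationError("leaf width needs >= 10 points of shape (N, 3)")
    axes = _pca_axes(pts)
    centered = pts - pts.mean(axis=0)
    p1 = centered @ axes[:, 0]
    if p1.max() == p1.min():
        raise ValidationError("degenerate leaf: no spread along any axis")
    edges = np.linspace(p1.min(), p1.max(), n_bins + 1)
    graph = _knn_graph(pts, k)
    best = None
    for b in range(n_bins):
        hi = edges[b + 1] + (1e-9 if b == n_bins - 1 else 0.0)
        members = np.flatnonzero((p1 >= edges[b]) & (p1 < hi))
        if members.size < 2:
            continue
        for ax in (1, 2):
            proj = centered[members] @ axes[:, ax]
            a = members[int(np.argmin(proj))]
            c = members[int(np.argmax(proj))]
            if a == c:  # degenerate bin (no spread on this axis): width 0
                if best is None:
                    best = 0.0
                continue
            d = dijkstra(graph, directed=False, indices=a)[c]
            if not np.isfinite(d):
                d = float(np.linalg.norm(pts[a] - pts[c]))
            if best is None or d > best:
                best = float(d)
    if best is None:
        raise ValidationError("all first-axis bins have fewer than 2 points")
    return best


# ---------------------------------------------------------------------------
# full record


def extract_traits(cloud: LabeledPointCloud, k: int = 10) -> TraitRecord:
    """Stem diameter plus per-leaf-instance length and width.

    Organs failing their preconditions (too few points, degenerate
    geometry) yield ``None`` entries with a warning instead of aborting the
    whole plant.
    """
    stem_pts = cloud.coords[cloud.semantic == STEM]
    diameter = None
    try:
        diameter = stem_diameter(stem_pts)
    except ValidationError as exc:
        warnings.warn(f"stem diameter unavailable: {exc}", RuntimeWarning, stacklevel=2)
    leaves = []
    ids = np.unique(cloud.instance[(cloud.semantic == LEAF) & (cloud.instance >= 1)])
    for iid in ids:
        pts = cloud.coords[cloud.instance == iid]
        length = width = None
        try:
            length = leaf_length(pts, k=k)
            width = leaf_width(pts, k=k)
        except ValidationError as exc:
            warnings.warn(
                f"leaf {int(iid)} traits unavailable: {exc}", RuntimeWarning, stacklevel=2
            )
        leaves.append((int(iid), length, width))
    return TraitRecord(stem_diameter=diameter, leaves=leaves)


def pair_trait_values(records, ground_truths) -> dict[str, tuple[list[float], list[float]]]:
    """Collect (ground truth, prediction) value pairs per trait across plants.

    ``records`` and ``ground_truths`` are parallel lists of
    :class:`TraitRecord` and generator ground truths; leaves pair by
    instance ID, failed measurements are dropped.
    """
    out: dict[str, tuple[list[float], list[float]]] = {
        "stem_diameter": ([], []), "leaf_length": ([], []), "leaf_width": ([], [])
    }
    for rec, gt in zip(records, ground_truths):
        if rec.stem_diameter is not None:
            out["stem_diameter"][0].append(gt.stem_diameter)
            out["stem_diameter"][1].append(rec.stem_diameter)
        gt_by_id = {iid: (length, width) for iid, length, width in gt.leaves}
        for iid, length, width in rec.leaves:
            if iid not in gt_by_id:
                continue
            gl, gw = gt_by_id[iid]
            if length is not None:
                out["leaf_length"][0].append(gl)
                out["leaf_length"][1].append(length)
            if width is not None:
                out["leaf_width"][0].append(gw)
                out["leaf_width"][1].append(width)
    return out


__all__ = [
    "TraitRecord",
    "stem_diameter",
    "geodesic_path_length",
    "leaf_length",
    "leaf_width",
    "extract_traits",
    "pair_trait_values",
]
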