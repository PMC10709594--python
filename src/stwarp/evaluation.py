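"""Alignment quality evaluation: landmarks, expression correspondence, regions.

After two sections are aligned, quality is quantified without any ground
truth map by (i) the root-mean-square error between manually placed
corresponding landmarks, (ii) gene-expression correspondence at matched
spatial locations — cells aggregated onto a shared 200 µm grid or into
pseudospots matching a spot-based technology's geometry, normalized, and
compared per gene by cosine similarity — and (iii) the consistency of
cell-type composition within anatomical regions (Euclidean distances
between composition vectors, Shannon entropy before and after boundary
expansion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors

from .deform import AffineTransform, DiffeoMap
from .points import PointSet

__all__ = [
    "LandmarkSet", "RegionComposition", "landmark_rmse", "grid_aggregate",
    "cosine_similarity", "pseudospot_aggregate", "cpm_log_normalize",
    "matched_mask", "region_entropy", "random_region", "expand_region_knn",
    "composition_distance",
]


@dataclass
class LandmarkSet:
    """Ordered (x, y) µm landmarks; correspondence across sets is by index."""

    points: np.ndarray
    names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.names is not None and len(self.names) != len(self.points):
            raise ValueError("names length must match point count")

    def __len__(self):
        return len(self.points)


@dataclass
class RegionComposition:
    """Cell-type proportion vector of one region."""

    region_id: object
    n_cells: int
    proportions: np.ndarray

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.n_cells < 1:
            raise ValueError("region must contain at least one cell")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    @classmethod
    def from_labels(cls, region_id, labels, n_types: Optional[int] = None):
        labels = np.asarray(labels)
        if n_types is None:
            n_types = int(labels.max()) + 1
        counts = np.bincount(labels, minlength=n_types).astype(float)
        return cls(region_id, len(labels), counts / counts.sum())


def _apply_transform(transform, pts):
    if transform is None:
        return pts
    if isinstance(transform, AffineTransform):
        return transform.apply(pts)
    if isinstance(transform, DiffeoMap):
        return transform.transform_points(pts)
    return np.atleast_2d(transform(pts))


def landmark_rmse(transform, pointsI, pointsJ) -> float:
    """RMSE (µm) between transformed source landmarks and target landmarks.

    ``transform`` may be an AffineTransform, a DiffeoMap, any callable on
    (n, d) coordinates, or None for the identity.
    """
    pI = np.atleast_2d(np.asarray(pointsI, dtype=float))
    pJ = np.atleast_2d(np.asarray(pointsJ, dtype=float))
    if pI.shape != pJ.shape:
        raise ValueError("landmark sets must have equal length")
    moved = _apply_transform(transform, pI)
    return float(np.sqrt(np.mean(np.sum((moved - pJ) ** 2, axis=1))))


def grid_aggregate(points: PointSet, grid_size: float = 200.0, origin=None):
    """Sum per-cell features over half-open square pixels of side ``grid_size`` µm.

    Bins are [k*g, (k+1)*g) from a shared ``origin`` (default: this point
    set's bounding-box minimum) so that two datasets aggregated with the
    same origin land on identical pixels.  Returns (bin index array
    (n_pix, 2) of (i, j) = floor((x, y - origin)/g), counts (n_pix,
    n_features), pixel center coordinates (n_pix, 2)).
    """
    if points.feature_matrix is None:
        raise ValueError("point set has no feature matrix")
    if origin is None:
        origin = np.array([points.x.min(), points.y.min()])
    origin = np.asarray(origin, dtype=float)
    ij = np.floor((points.coords - origin) / grid_size).astype(np.int64)
    keys, inverse = np.unique(ij, axis=0, return_inverse=True)
    counts = np.zeros((len(keys), points.feature_matrix.shape[1]))
    np.add.at(counts, inverse, np.asarray(points.feature_matrix, dtype=float))
    centers = origin + (keys + 0.5) * grid_size
    return keys, counts, centers


def cosine_similarity(u, v) -> float:
    """u . v / (|u| |v|); NaN sentinel when both vectors are zero."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 and nv == 0.0:
        return float("nan")
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v / (nu * nv))


def pseudospot_aggregate(cells: PointSet, spot_centers, radius: float):
    """Sum cell features into disk pseudospots around ``spot_centers``.

    A cell belongs to a spot when its distance to the spot centroid is
    strictly less than ``radius`` (µm); a cell within radius of several
    centers contributes to each of them.  Returns (n_spots, n_features)
    counts.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if cells.feature_matrix is None:
        raise ValueError("point set has no feature matrix")
    centers = np.atleast_2d(np.asarray(spot_centers, dtype=float))
    feats = np.asarray(cells.feature_matrix, dtype=float)
    tree = cKDTree(cells.coords)
    out = np.zeros((len(centers), feats.shape[1]))
    for s, idx in enumerate(tree.query_ball_point(centers, r=radius)):
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            continue
        dist = np.linalg.norm(cells.coords[idx] - centers[s], axis=1)
        sel = idx[dist < radius]  # strict inequality
        if sel.size:
            out[s] = feats[sel].sum(axis=0)
    return out


def cpm_log_normalize(count_matrix):
    """Counts-per-million scaling then log10(x + 1), per observation (row).

    All-zero rows pass through as zeros; returns (normalized matrix,
    boolean flag vector marking those rows).
    """
    X = np.asarray(count_matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = X.sum(axis=1, keepdims=True)
    zero = totals.ravel() == 0
    safe = np.where(totals == 0, 1.0, totals)
    return np.log10(X / safe * 1e6 + 1.0), zero


def matched_mask(weights, threshold: float = 0.85, grid=None, points: Optional[PointSet] = None):
    """Pixels (and optionally cells) assessed as matched tissue.

    ``mask = matching posterior > threshold``.  When a target grid
    (row_coords, col_coords) and a point set are supplied, each cell is
    kept or dropped by the mask value of its containing pixel (cells
    outside the grid are dropped).  Returns mask, or (mask, keep).
    """
    from .lddmm import MixtureWeights

    wm = weights.matching if isinstance(weights, MixtureWeights) else np.asarray(weights)
    mask = wm > threshold
    if grid is None or points is None:
        return mask
    rows, cols = (np.asarray(a, dtype=float) for a in grid)
    drow = rows[1] - rows[0] if len(rows) > 1 else 1.0
    dcol = cols[1] - cols[0] if len(cols) > 1 else 1.0
    ri = np.round((points.y - rows[0]) / drow).astype(int)
    ci = np.round((points.x - cols[0]) / dcol).astype(int)
    inside = (ri >= 0) & (ri < len(rows)) & (ci >= 0) & (ci < len(cols))
    keep = np.zeros(len(points), dtype=bool)
    keep[inside] = mask[ri[inside], ci[inside]]
    return mask, keep


def region_entropy(labels_or_proportions) -> float:
    """Shannon entropy (nats) of a region's cell-type composition: -sum p ln p."""
    arr = np.asarray(labels_or_proportions)
    if arr.ndim == 1 and (arr.dtype.kind in "iu" or not np.isclose(arr.sum(), 1.0)):
        counts = np.bincount(arr.astype(int))
        p = counts[counts > 0] / counts.sum()
    else:
        p = arr[arr > 0]
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("proportions must sum to 1")
    return float(-(p * np.log(p)).sum())


def random_region(cells: PointSet, n_cells: int, seed: int = 0) -> np.ndarray:
    """Randomly demarcated region: the ``n_cells`` nearest cells to a random center.

    The center is drawn uniformly over the bounding box; deterministic
    given ``seed``.  Returns member indices.
    """
    if n_cells > len(cells):
        raise ValueError("n_cells exceeds the number of cells")
    rng = np.random.default_rng(seed)
    (xmin, xmax), (ymin, ymax) = cells.bounding_box()
    center = np.array([rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)])
    dist = np.linalg.norm(cells.coords - center, axis=1)
    return np.argsort(dist, kind="stable")[:n_cells]


def expand_region_knn(member_idx, cells: PointSet, k: int = 100) -> np.ndarray:
    """Expand a region by the k nearest neighbors of its members (ball tree).

    Returns the sorted union of the original member indices with every
    member's k nearest cells; k = 0 returns the region unchanged.
    """
    member_idx = np.asarray(member_idx, dtype=int)
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0 or len(member_idx) == 0:
        return np.unique(member_idx)
    n_query = min(k + 1, len(cells))  # +1: a member is its own nearest neighbor
    nn = NearestNeighbors(n_neighbors=n_query, algorithm="ball_tree").fit(cells.coords)
    _, neigh = nn.kneighbors(cells.coords[member_idx])
    return np.union1d(member_idx, neigh.ravel())


def composition_distance(a: RegionComposition, b: RegionComposition) -> float:
    """Euclidean distance between two cell-type proportion vectors."""
    pa, pb = a.proportions, b.proportions
    if pa.shape != pb.shape:
        raise ValueError("composition vectors must have equal length")
    return float(np.linalg.norm(pa - pb))
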