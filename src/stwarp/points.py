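"""Cell-position point sets (the space measure of a tissue section)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["PointSet"]


@dataclass
class PointSet:
    """Positions of cells in a tissue section, in µm.

    A point set is the discrete space measure of the section: each cell
    contributes a point mass at its (x, y) centroid, optionally carrying a
    per-cell weight and a per-cell feature (gene count) vector.

    Parameters
    ----------
    x, y : array of µm coordinates, equal length.
    weights : optional nonnegative per-point mass; default 1 per cell.
    feature_matrix : optional (n_points, n_features) count matrix.
    feature_names : optional labels for the feature columns.
    """

    x: np.ndarray
    y: np.ndarray
    weights: Optional[np.ndarray] = None
    feature_matrix: Optional[np.ndarray] = None
    feature_names: Optional[Sequence[str]] = None
    labels: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("coordinates contain NaN")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float).ravel()
            if self.weights.shape != self.x.shape:
                raise ValueError("weights length must match coordinates")
            if (self.weights < 0).any():
                raise ValueError("weights must be nonnegative")
        if self.feature_matrix is not None:
            self.feature_matrix = np.asarray(self.feature_matrix)
            if self.feature_matrix.shape[0] != len(self.x):
                raise ValueError("feature_matrix rows must match number of points")
            if self.feature_names is not None and len(self.feature_names) != self.feature_matrix.shape[1]:
                raise ValueError("feature_names length must match feature_matrix columns")

    def __len__(self):
        return len(self.x)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) coordinates."""
        return np.stack([self.x, self.y], axis=1)

    @property
    def effective_weights(self) -> np.ndarray:
        return self.weights if self.weights is not None else np.ones(len(self.x))

    def with_coords(self, coords: np.ndarray) -> "PointSet":
        """Copy of this point set with replaced coordinates (same metadata)."""
        coords = np.asarray(coords, dtype=float)
        return PointSet(
            coords[:, 0], coords[:, 1],
            weights=None if self.weights is None else self.weights.copy(),
            feature_matrix=self.feature_matrix,
            feature_names=self.feature_names,
            labels=self.labels,
        )

    def subset(self, idx) -> "PointSet":
        return PointSet(
            self.x[idx], self.y[idx],
            weights=None if self.weights is None else self.weights[idx],
            feature_matrix=None if self.feature_matrix is None else self.feature_matrix[idx],
            feature_names=self.feature_names,
            labels=None if self.labels is None else np.asarray(self.labels)[idx],
        )

    def bounding_box(self):
        """((xmin, xmax), (ymin, ymax)) in µm."""
        return (self.x.min(), self.x.max()), (self.y.min(), self.y.max())
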