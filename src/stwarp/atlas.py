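"""3D atlas volumes: 3D-to-2D alignment, annotation lift-over, plane fits.

A 2D tissue section is rarely a perfect plane of the 3D reference it came
from: cutting tilts the section away from the nominal (coronal) plane and
local distortions push cells out of any plane entirely.  Aligning the 3D
atlas volume to the 2D slice with the same affine + velocity-field model —
now in three dimensions — captures both effects, and the solved map carries
every cell's 2D coordinates into atlas space, where voxel-level anatomical
annotations can be read off (lift-over).

Coordinate convention: 3D point coordinates are (x, y, z) µm with x the
out-of-plane (anterior-posterior) axis; volume arrays are indexed [x, y, z]
and the 2D slice embeds at x = 0 with its own (x, y) coordinates mapped to
the volume's (y, z) in-plane axes.  The nominal section is therefore a
constant-x plane, and section obliqueness is the angle between the best-fit
plane and the y-z plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .deform import GridAxes
from .lddmm import AlignmentResult, LDDMMConfig, _lddmm_core
from .raster import RasterImage

__all__ = [
    "AtlasVolume", "SlicePlaneFit", "lddmm_3d_to_2d", "liftover_labels",
    "best_fit_plane", "embed_slice_points", "UNLABELED",
]

UNLABELED = -1  # sentinel for points outside the annotation volume


@dataclass
class AtlasVolume:
    """3D grayscale volume with µm axes and optional integer annotations.

    values : (nx, ny, nz) intensity, axis 0 = out-of-plane (AP) axis.
    axes : µm center coordinates of each voxel plane, per axis.
    annotation : optional integer label volume of identical shape.
    label_names : optional mapping label id -> (acronym/name).
    """

    values: np.ndarray
    axes: Sequence[np.ndarray]
    annotation: Optional[np.ndarray] = None
    label_names: Optional[dict] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3D")
        self.axes = [np.asarray(a, dtype=float) for a in self.axes]
        if tuple(len(a) for a in self.axes) != self.values.shape:
            raise ValueError("axis lengths must match volume shape")
        if self.annotation is not None:
            self.annotation = np.asarray(self.annotation)
            if self.annotation.shape != self.values.shape:
                raise ValueError("annotation shape must match intensity shape")
        for ax in self.axes:
            if len(ax) > 1 and (np.diff(ax) <= 0).any():
                raise ValueError("axis coordinates must be strictly increasing")

    @property
    def voxel_size(self) -> float:
        ax = self.axes[0]
        return float(ax[1] - ax[0]) if len(ax) > 1 else 1.0

    @property
    def grid(self) -> GridAxes:
        return GridAxes(self.axes, perm=(0, 1, 2))

    def normalized(self) -> "AtlasVolume":
        peak = np.abs(self.values).max()
        return AtlasVolume(self.values / peak if peak > 0 else self.values.copy(),
                           [a.copy() for a in self.axes], self.annotation, self.label_names)


@dataclass
class SlicePlaneFit:
    """Total-least-squares plane through transformed slice points."""

    normal: np.ndarray        # unit vector
    offset: float             # plane is {p : normal . p = offset}
    rmse: float               # µm, orthogonal residual
    angle_deg: float          # angle between plane and the y-z plane

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be nonnegative")
        if not 0.0 <= self.angle_deg <= 90.0 + 1e-9:
            raise ValueError("angle must be within [0, 90] degrees")


def best_fit_plane(points3d: np.ndarray) -> SlicePlaneFit:
    """Fit the most representative plane of a 3D point cloud.

    The plane normal is the smallest-singular-value direction of the
    centered coordinates (total least squares); ``rmse`` is the root mean
    square orthogonal distance, and the angle is measured between the
    fitted plane and the y-z plane (i.e. between the normal and the x
    axis), in degrees — 0 for a perfectly coronal section.
    """
    pts = np.atleast_2d(np.asarray(points3d, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need at least 3 points in 3D")
    center = pts.mean(axis=0)
    centered = pts - center
    _, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] <= max(svals[0], 1.0) * 1e-12:
        raise np.linalg.LinAlgError("degenerate fit: points are collinear")
    normal = Vt[2]
    rmse = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    cosang = np.clip(abs(normal[0]), 0.0, 1.0)
    return SlicePlaneFit(normal=normal, offset=float(normal @ center),
                         rmse=rmse, angle_deg=float(np.degrees(np.arccos(cosang))))


def liftover_labels(annotation: AtlasVolume, points3d: np.ndarray) -> np.ndarray:
    """Nearest-voxel annotation labels for points in atlas µm coordinates.

    Points outside the volume's bounding box receive the ``UNLABELED``
    sentinel (-1).
    """
    if annotation.annotation is None:
        raise ValueError("volume carries no annotation array")
    pts = np.atleast_2d(np.asarray(points3d, dtype=float))
    labels = np.full(pts.shape[0], UNLABELED, dtype=annotation.annotation.dtype)
    idx = np.empty(pts.shape, dtype=np.intp)
    inside = np.ones(pts.shape[0], dtype=bool)
    for k, ax in enumerate(annotation.axes):
        step = ax[1] - ax[0] if len(ax) > 1 else 1.0
        i = np.round((pts[:, k] - ax[0]) / step).astype(np.intp)
        half = step / 2.0
        inside &= (pts[:, k] >= ax[0] - half) & (pts[:, k] <= ax[-1] + half)
        idx[:, k] = np.clip(i, 0, len(ax) - 1)
    labels[inside] = annotation.annotation[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    return labels


def embed_slice_points(points2d: np.ndarray, x_offset: float = 0.0) -> np.ndarray:
    """Embed 2D slice coordinates (x, y) at the x=offset plane of the 3D frame.

    The slice's first coordinate maps to the volume's in-plane y axis and
    its second to z.
    """
    p = np.atleast_2d(np.asarray(points2d, dtype=float))
    return np.column_stack([np.full(len(p), float(x_offset)), p[:, 0], p[:, 1]])


def lddmm_3d_to_2d(volume: AtlasVolume, slice_image: RasterImage,
                   config: Optional[LDDMMConfig] = None,
                   x_offset: float = 0.0) -> AlignmentResult:
    """Align a 3D volume (source) to a 2D slice raster (target).

    Solves a 3D affine + 3D velocity field such that the volume resampled
    on the deformed slice plane matches the 2D image — the same mixture +
    contrast objective as the 2D case, with the matching sum running over
    the slice's pixels embedded at x = ``x_offset``.  ``x_offset`` (µm)
    initializes the out-of-plane translation (e.g. a bregma estimate); it
    is ignored when the config supplies an explicit initial transform.

    The returned result's ``transform_points_inverse`` carries embedded 2D
    cell coordinates into 3D atlas coordinates (see
    :func:`transform_cells_to_atlas`).
    """
    config = config or LDDMMConfig()
    vol = volume.normalized() if config.normalize else volume
    target = slice_image.normalized() if config.normalize else slice_image

    if config.initial_affine(3) is None and x_offset != 0.0:
        # affine maps atlas -> slice frame; the slice's x=0 plane sits at
        # atlas x = x_offset, so initialize T_x = -x_offset.
        config = _with_translation(config, np.array([-float(x_offset), 0.0, 0.0]))

    gx, gy = np.meshgrid(target.col_coords, target.row_coords)
    slice_pts2 = np.stack([gx.ravel(), gy.ravel()], axis=1)
    target_pts = embed_slice_points(slice_pts2, 0.0)
    target_vals = target.values.reshape(target.n_channels, -1)

    result = _lddmm_core(vol.values, vol.grid, target_pts, target_vals,
                         pixel_measure=target.dx**2, config=config,
                         target_shape=target.values.shape[1:])
    result.target_grid = GridAxes.from_image(target)
    return result


def _with_translation(config: LDDMMConfig, T: np.ndarray) -> LDDMMConfig:
    from dataclasses import replace
    return replace(config, T=T)


def transform_cells_to_atlas(result: AlignmentResult, points2d: np.ndarray,
                             x_offset: float = 0.0) -> np.ndarray:
    """Carry 2D slice cell coordinates (µm) into 3D atlas coordinates."""
    return result.transform_points_inverse(embed_slice_points(points2d, x_offset))
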