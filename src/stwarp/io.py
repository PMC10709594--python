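"""Readers and writers for cell tables, images, atlas volumes, and landmarks.

Every loader converts to the package's internal units immediately: cell and
landmark coordinates in µm, images channel-first with intensities scaled to
[0, 1], NRRD voxel spacing honored and converted to µm.  Readers are strict
about required columns (a missing coordinate column raises a named error
rather than silently loading a partial table) and log what they loaded.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .atlas import AtlasVolume
from .deform import DiffeoMap
from .evaluation import LandmarkSet
from .points import PointSet
from .raster import RasterImage

logger = logging.getLogger("stwarp.io")

__all__ = [
    "CellTableDialect", "DIALECTS", "read_cell_table", "write_cell_table",
    "read_image", "read_nrrd", "write_nrrd", "read_landmarks",
    "write_landmarks", "write_alignment", "load_map",
]


@dataclass
class CellTableDialect:
    """Column naming and unit convention of a cell-table CSV.

    ``scale`` multiplies coordinates on load (e.g. 1/5 for tables stored at
    5x the physical µm scale); ``count_columns='auto'`` attaches every
    numeric column that is not a coordinate or id as a feature.
    """

    x: str = "x"
    y: str = "y"
    cell_id: Optional[str] = None
    count_columns: Optional[object] = "auto"
    label_column: Optional[str] = None
    scale: float = 1.0
    header: bool = True


# common single-cell ST export conventions
DIALECTS = {
    "generic": CellTableDialect(),
    "merfish": CellTableDialect(x="center_x", y="center_y", cell_id="EntityID"),
    "xenium": CellTableDialect(x="x_centroid", y="y_centroid", cell_id="cell_id"),
    # STARmap well exports store centroid positions at 5x the µm scale
    "starmap": CellTableDialect(x="X", y="Y", scale=0.2),
}


def _resolve_dialect(dialect) -> CellTableDialect:
    if dialect is None:
        return DIALECTS["generic"]
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    return dialect


def read_cell_table(path, dialect=None) -> PointSet:
    """Load a cell-position CSV as a PointSet (coordinates in µm, row order kept)."""
    d = _resolve_dialect(dialect)
    df = pd.read_csv(path, header=0 if d.header else None,
                     float_precision="round_trip")
    for col in (d.x, d.y):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path} (columns: {list(df.columns)})")
    x = df[d.x].to_numpy(dtype=float) * d.scale
    y = df[d.y].to_numpy(dtype=float) * d.scale

    feats = names = None
    if d.count_columns is not None:
        if d.count_columns == "auto":
            skip = {d.x, d.y, d.cell_id, d.label_column}
            names = [c for c in df.columns
                     if c not in skip and pd.api.types.is_numeric_dtype(df[c])]
        else:
            names = list(d.count_columns)
            missing = [c for c in names if c not in df.columns]
            if missing:
                raise KeyError(f"count columns {missing} not found in {path}")
        if names:
            feats = df[names].to_numpy(dtype=float)
        else:
            names = None
    labels = df[d.label_column].to_numpy() if d.label_column in (df.columns if d.label_column else []) else None
    ps = PointSet(x, y, feature_matrix=feats, feature_names=names, labels=labels)
    logger.info("loaded %d cells from %s (x range %.1f..%.1f µm, y %.1f..%.1f µm)",
                len(ps), path, x.min(), x.max(), y.min(), y.max())
    return ps


def write_cell_table(points: PointSet, path):
    data = {"x": points.x, "y": points.y}
    if points.labels is not None:
        data["label"] = points.labels
    df = pd.DataFrame(data)
    if points.feature_matrix is not None:
        names = points.feature_names or [f"f{i}" for i in range(points.feature_matrix.shape[1])]
        df = pd.concat([df, pd.DataFrame(points.feature_matrix, columns=list(names))], axis=1)
    df.to_csv(path, index=False, float_format="%.17g")


def read_image(path, pixel_size: float = 1.0, origin=(0.0, 0.0)) -> RasterImage:
    """Load PNG/TIFF as a channel-first RasterImage with values in [0, 1].

    ``pixel_size`` (µm) and ``origin`` fix the physical grid; integer dtypes
    are scaled by their type maximum.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)  # H,W,C -> C,H,W
    else:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    rows = origin[1] + pixel_size * (0.5 + np.arange(arr.shape[1]))
    cols = origin[0] + pixel_size * (0.5 + np.arange(arr.shape[2]))
    logger.info("loaded image %s: %s channels, %sx%s px at %.2f µm, range %.3f..%.3f",
                path, arr.shape[0], arr.shape[1], arr.shape[2], pixel_size, arr.min(), arr.max())
    return RasterImage(arr, rows, cols)


def read_nrrd(path, annotation_path=None) -> AtlasVolume:
    """Load an NRRD atlas volume (+ optional annotation volume of equal shape).

    Voxel spacing is read from the header and converted to µm axis
    coordinates; axis 0 is taken as the out-of-plane (AP) axis.
    """
    img = sitk.ReadImage(str(path))
    vals = sitk.GetArrayFromImage(img)  # (z, y, x) in sitk order = reversed spacing order
    spacing = list(img.GetSpacing())[::-1]
    if vals.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {vals.ndim}D")
    axes = [sp * (0.5 + np.arange(n)) for sp, n in zip(spacing, vals.shape)]
    ann = None
    if annotation_path is not None:
        aimg = sitk.ReadImage(str(annotation_path))
        ann = sitk.GetArrayFromImage(aimg)
        if ann.shape != vals.shape:
            raise ValueError("annotation shape must match intensity shape")
    logger.info("loaded volume %s: shape %s spacing %s µm, range %.3f..%.3f",
                path, vals.shape, spacing, vals.min(), vals.max())
    return AtlasVolume(vals.astype(float), axes, annotation=ann)


def write_nrrd(volume: AtlasVolume, path):
    img = sitk.GetImageFromArray(volume.values)
    spacing = [float(a[1] - a[0]) if len(a) > 1 else 1.0 for a in volume.axes][::-1]
    img.SetSpacing(spacing)
    sitk.WriteImage(img, str(path))


def read_landmarks(path, row_col_order: bool = False) -> LandmarkSet:
    """Load a 2-column (x_µm, y_µm [, name]) landmark CSV.

    ``row_col_order=True`` handles legacy files stored as (row, col) =
    (y, x) pairs by swapping the two coordinate columns on load.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    num = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    if len(num) < 2:
        raise ValueError(f"{path}: need two numeric coordinate columns")
    pts = df[num[:2]].to_numpy(dtype=float)
    if row_col_order:
        pts = pts[:, ::-1]
    names = df["name"].tolist() if "name" in df.columns else None
    return LandmarkSet(pts, names)


def write_landmarks(landmarks: LandmarkSet, path):
    df = pd.DataFrame(landmarks.points, columns=["x_um", "y_um"])
    if landmarks.names is not None:
        df["name"] = list(landmarks.names)
    df.to_csv(path, index=False, float_format="%.17g")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_alignment(result, outdir, source_points: Optional[PointSet] = None):
    """Persist an AlignmentResult: map, objective log, aligned coordinates.

    Writes ``map.json``/``map.npz`` (reloadable via :func:`load_map`),
    ``objective.csv`` with the per-iteration energy components, and — when
    ``source_points`` is given — ``aligned_cells.csv`` with transformed
    coordinates.
    """
    os.makedirs(outdir, exist_ok=True)
    result.diffeo.save(os.path.join(outdir, "map"))
    pd.DataFrame(result.trace).to_csv(os.path.join(outdir, "objective.csv"), index=False)
    if source_points is not None:
        moved, inside = result.diffeo.transform_points(source_points.coords, return_flags=True)
        df = pd.DataFrame({"x": moved[:, 0], "y": moved[:, 1], "inside_grid": inside})
        df.to_csv(os.path.join(outdir, "aligned_cells.csv"), index=False)


def load_map(outdir) -> DiffeoMap:
    return DiffeoMap.load(os.path.join(outdir, "map"))
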