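"""Affine + velocity-field diffeomorphic transformations.

A map is the composition of a time-varying velocity-field flow and an
affine transform: ``phi(x) = A @ flow_1(x)``, with the flow obtained by
integrating the velocity field from time 0 to 1.  Restricting the velocity
field to be spatially smooth guarantees the flow is a diffeomorphism —
smooth, invertible, neighbor-preserving — which is what lets the solved map
be applied back and forth between raster images and raw cell coordinates.

Conventions
-----------
Public point coordinates are (x, y) µm in 2D and (x, y, z) µm in 3D, where
in 3D the x axis is the out-of-plane (anterior-posterior, for a coronal
brain atlas) axis.  Internal rasters are row-major with row <-> y and
col <-> x; 3D arrays are indexed [x, y, z].  ``GridAxes.perm`` records the
mapping from array axes to point components.

Integration is explicit stepwise (semi-Lagrangian) composition over ``nt``
timesteps with multilinear interpolation of the velocity at the moving
positions.  The forward flow steps points along +v in time order; the
backward (inverse) flow steps along -v in reversed time order.  Both maps
are maintained explicitly: the forward map carries points, the inverse map
pulls back images.  Beyond the grid the displacement is extended as a
constant (nearest-edge value) so cells at tissue margins are still mapped,
and such points are flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._interp import grid_points, interp
from .points import PointSet
from .raster import RasterImage

__all__ = [
    "GridAxes", "AffineTransform", "VelocityField", "DiffeoMap",
    "integrate_velocity", "apply_to_points", "apply_to_image",
]


@dataclass
class GridAxes:
    """Rectilinear grid axes (array order) plus the array-axis -> point-component map."""

    axes: Sequence[np.ndarray]
    perm: tuple  # perm[i] = point component carried by array axis i

    def __post_init__(self):
        self.axes = [np.asarray(a, dtype=float) for a in self.axes]
        self.perm = tuple(self.perm)
        if sorted(self.perm) != list(range(len(self.axes))):
            raise ValueError("perm must be a permutation of axis indices")

    @classmethod
    def from_image(cls, image: RasterImage) -> "GridAxes":
        return cls([image.row_coords, image.col_coords], perm=(1, 0))

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple:
        return tuple(len(a) for a in self.axes)

    @property
    def spacing(self) -> list:
        return [float(a[1] - a[0]) if len(a) > 1 else 1.0 for a in self.axes]

    def to_grid_order(self, pts: np.ndarray) -> np.ndarray:
        """Reorder (m, d) point-order coordinates into array-axis order."""
        return np.asarray(pts, dtype=float)[:, list(self.perm)]

    def points(self) -> np.ndarray:
        """All grid nodes as (N, d) coordinates in point order."""
        iperm = np.argsort(self.perm)
        return grid_points(self.axes)[:, iperm]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        g = self.to_grid_order(pts)
        ok = np.ones(g.shape[0], dtype=bool)
        for k, ax in enumerate(self.axes):
            ok &= (g[:, k] >= ax[0]) & (g[:, k] <= ax[-1])
        return ok


@dataclass
class AffineTransform:
    """Affine map x -> L @ x + T acting on point-order coordinates (µm)."""

    L: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        self.T = np.asarray(self.T, dtype=float).ravel()
        d = self.L.shape[0]
        if self.L.shape != (d, d) or self.T.shape != (d,):
            raise ValueError("L must be (d, d) and T length d")

    @classmethod
    def identity(cls, d: int = 2) -> "AffineTransform":
        return cls(np.eye(d), np.zeros(d))

    @property
    def ndim(self) -> int:
        return self.L.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous (d+1, d+1) matrix."""
        d = self.ndim
        M = np.eye(d + 1)
        M[:d, :d] = self.L
        M[:d, d] = self.T
        return M

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.L.T + self.T

    def inverse(self) -> "AffineTransform":
        Linv = np.linalg.inv(self.L)
        return AffineTransform(Linv, -Linv @ self.T)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: x -> self(other(x))."""
        return AffineTransform(self.L @ other.L, self.L @ other.T + self.T)


@dataclass
class VelocityField:
    """Time-sampled velocity field v_t on a fixed spatial grid.

    values : (nt, d, *spatial) in µm per unit time; component order matches
    point order (x, y[, z]), spatial axes match ``grid.axes``.
    a, p : smoothness scale (µm) and Laplacian power of the regularizing
    operator (id - a^2 Δ)^p under which the field's norm is penalized.
    """

    values: np.ndarray
    grid: GridAxes
    a: float = 500.0
    p: float = 2.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        d = self.grid.ndim
        if self.values.ndim != d + 2 or self.values.shape[1] != d:
            raise ValueError("values must be (nt, d, *spatial)")
        if self.values.shape[2:] != self.grid.shape:
            raise ValueError("spatial shape must match grid")
        if not np.isfinite(self.values).all():
            raise ValueError("velocity field contains non-finite values")
        if self.values.shape[0] < 1:
            raise ValueError("nt must be >= 1")

    @classmethod
    def zeros(cls, grid: GridAxes, nt: int = 3, a: float = 500.0, p: float = 2.0):
        return cls(np.zeros((nt, grid.ndim) + grid.shape), grid, a, p)

    @property
    def nt(self) -> int:
        return self.values.shape[0]

    def sample(self, t: int, pts: np.ndarray) -> np.ndarray:
        """Velocity of timestep t at point-order positions (m, d) -> (m, d)."""
        g = self.grid.to_grid_order(pts)
        return interp(self.values[t], self.grid.axes, g).T


def integrate_velocity(v: VelocityField, direction: str = "forward") -> np.ndarray:
    """Integrate the flow of ``v`` on its own grid; returns displacement (d, *spatial).

    ``forward`` steps grid nodes along +v over timesteps 0..nt-1;
    ``backward`` integrates -v in reversed time order, yielding the inverse
    flow to first order per step.
    """
    if not np.isfinite(v.values).all():
        raise FloatingPointError("velocity field contains NaN/Inf")
    pts = v.grid.points()
    q = flow_points(v, pts, direction)
    disp = (q - pts)  # (N, d) point order
    return disp.T.reshape((v.grid.ndim,) + v.grid.shape)


def flow_points(v: VelocityField, pts: np.ndarray, direction: str = "forward") -> np.ndarray:
    """Carry point-order positions (m, d) through the flow of ``v``."""
    q = np.asarray(pts, dtype=float).copy()
    dt = 1.0 / v.nt
    if direction == "forward":
        for t in range(v.nt):
            q = q + dt * v.sample(t, q)
    elif direction == "backward":
        for t in reversed(range(v.nt)):
            q = q - dt * v.sample(t, q)
    else:
        raise ValueError("direction must be 'forward' or 'backward'")
    return q


@dataclass
class DiffeoMap:
    """Solved map phi(x) = A @ flow_1(x), with explicit forward and inverse flows.

    ``forward_disp``/``inverse_disp`` are (d, *spatial) displacement grids of
    the diffeomorphic part (no affine), sampled on ``grid``; the full
    forward map applies the flow first, then the affine.
    """

    affine: AffineTransform
    grid: Optional[GridAxes] = None
    velocity: Optional[VelocityField] = None
    forward_disp: Optional[np.ndarray] = None
    inverse_disp: Optional[np.ndarray] = None

    @classmethod
    def from_affine(cls, affine: AffineTransform) -> "DiffeoMap":
        return cls(affine=affine)

    @classmethod
    def from_velocity(cls, affine: AffineTransform, velocity: VelocityField) -> "DiffeoMap":
        return cls(
            affine=affine,
            grid=velocity.grid,
            velocity=velocity,
            forward_disp=integrate_velocity(velocity, "forward"),
            inverse_disp=integrate_velocity(velocity, "backward"),
        )

    @property
    def ndim(self) -> int:
        return self.affine.ndim

    def _disp_at(self, disp, pts):
        g = self.grid.to_grid_order(pts)
        return interp(disp, self.grid.axes, g, mode="clamp").T

    def transform_points(self, pts: np.ndarray, return_flags: bool = False):
        """Forward map: source coordinates -> target frame (flow, then affine)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if self.forward_disp is None:
            out = self.affine.apply(pts)
            inside = np.ones(len(pts), dtype=bool)
        else:
            out = self.affine.apply(pts + self._disp_at(self.forward_disp, pts))
            inside = self.grid.contains(pts)
        return (out, inside) if return_flags else out

    def transform_points_inverse(self, pts: np.ndarray, return_flags: bool = False):
        """Inverse map: target-frame coordinates -> source coordinates."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        q = self.affine.inverse().apply(pts)
        if self.inverse_disp is None:
            inside = np.ones(len(pts), dtype=bool)
            out = q
        else:
            out = q + self._disp_at(self.inverse_disp, q)
            inside = self.grid.contains(q)
        return (out, inside) if return_flags else out

    def __call__(self, pts):
        return self.transform_points(pts)

    def inverse_consistency_error(self) -> float:
        """max |inverse(forward(x)) - x| over interior grid nodes, in µm.

        The diffeomorphism contract: this should not exceed ~0.1 pixel for
        any velocity field produced during optimization.
        """
        if self.grid is None:
            return 0.0
        pts = self.grid.points()
        fwd = self.transform_points(pts)
        back = self.transform_points_inverse(fwd)
        err = np.linalg.norm(back - pts, axis=1)
        # restrict to interior nodes (one-cell margin) where the flow stays on-grid
        g = self.grid.to_grid_order(pts)
        interior = np.ones(len(pts), dtype=bool)
        for k, ax in enumerate(self.grid.axes):
            if len(ax) > 2:
                interior &= (g[:, k] > ax[0]) & (g[:, k] < ax[-1])
        return float(err[interior].max()) if interior.any() else float(err.max())

    # -- serialization -----------------------------------------------------
    def save(self, prefix: str):
        """Write ``<prefix>.json`` (header) and ``<prefix>.npz`` (arrays)."""
        header = {
            "ndim": self.ndim,
            "affine_L": self.affine.L.tolist(),
            "affine_T": self.affine.T.tolist(),
        }
        arrays = {}
        if self.grid is not None:
            header["perm"] = list(self.grid.perm)
            for i, ax in enumerate(self.grid.axes):
                arrays[f"axis{i}"] = ax
        if self.velocity is not None:
            header["nt"] = self.velocity.nt
            header["a"] = self.velocity.a
            header["p"] = self.velocity.p
            arrays["velocity"] = self.velocity.values
        if self.forward_disp is not None:
            arrays["forward_disp"] = self.forward_disp
            arrays["inverse_disp"] = self.inverse_disp
        with open(f"{prefix}.json", "w") as fh:
            json.dump(header, fh, indent=2)
        np.savez_compressed(f"{prefix}.npz", **arrays)

    @classmethod
    def load(cls, prefix: str) -> "DiffeoMap":
        with open(f"{prefix}.json") as fh:
            header = json.load(fh)
        data = np.load(f"{prefix}.npz")
        affine = AffineTransform(np.array(header["affine_L"]), np.array(header["affine_T"]))
        grid = None
        if "perm" in header:
            axes = [data[f"axis{i}"] for i in range(header["ndim"])]
            grid = GridAxes(axes, tuple(header["perm"]))
        vel = None
        if "velocity" in data:
            vel = VelocityField(data["velocity"], grid, header.get("a", 500.0), header.get("p", 2.0))
        return cls(
            affine=affine, grid=grid, velocity=vel,
            forward_disp=data["forward_disp"] if "forward_disp" in data else None,
            inverse_disp=data["inverse_disp"] if "inverse_disp" in data else None,
        )


def apply_to_points(mapping: DiffeoMap, points: PointSet, return_flags: bool = False):
    """Transform a PointSet's coordinates by the forward map.

    Points outside the map's grid are transformed by the nearest-edge
    displacement (constant extension) and flagged False in the returned
    mask when ``return_flags`` is set.
    """
    out, inside = mapping.transform_points(points.coords, return_flags=True)
    moved = points.with_coords(out)
    return (moved, inside) if return_flags else moved


def apply_to_image(mapping: DiffeoMap, image: RasterImage, out_grid=None,
                   fill: float = 0.0) -> RasterImage:
    """Pull back ``image`` through the map (resample source at inverse-mapped pixels).

    ``out_grid`` is a (row_coords, col_coords) pair defaulting to the
    image's own grid; samples that land outside the source image take
    ``fill``.
    """
    if out_grid is None:
        rows, cols = image.row_coords, image.col_coords
    else:
        rows, cols = (np.asarray(a, dtype=float) for a in out_grid)
    gx, gy = np.meshgrid(cols, rows)  # row-major target grid
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    src = mapping.transform_points_inverse(pts)
    vals = interp(image.values, image.axes, src[:, ::-1], mode="fill", fill=fill)
    return RasterImage(vals.reshape(image.n_channels, len(rows), len(cols)), rows, cols)
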