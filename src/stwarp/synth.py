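"""Synthetic tissues with known ground-truth warps.

Real evaluation data for slice alignment (MERFISH/Xenium sections, atlas
volumes) are multi-gigabyte downloads, so every stage of the pipeline is
exercised instead on generated tissues: mixtures of Gaussian "cell
clusters" plus curved laminar bands, with per-cell type labels and
Poisson-sampled marker-gene counts.  Ground-truth deformations are an
affine composed with a sum of Gaussian displacement bumps whose amplitude
bound guarantees a positive Jacobian, so the true map is analytic,
evaluable at any point, and invertible (by damped fixed-point iteration).

The default ``toy_coronal`` fixture emulates a coronal brain section at
desk scale: two mirrored blob clusters and one curved lamina, ~3000 cells,
5 cell types, 20 genes, spanning roughly 1.8 x 1.4 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import shapely

from .atlas import AtlasVolume
from .deform import AffineTransform
from .points import PointSet

__all__ = [
    "BlobComponent", "LaminarBand", "TissueSpec", "WarpSpec", "GroundTruthWarp",
    "make_tissue", "warp_points", "degrade", "make_volume", "toy_coronal",
    "sample_oblique_section",
]


@dataclass
class BlobComponent:
    """Gaussian cluster of cells: center (µm), covariance (µm²), relative weight."""

    center: np.ndarray
    cov: np.ndarray
    weight: float = 1.0
    cell_type: int = 0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.weight < 0:
            raise ValueError("component weight must be nonnegative")

    def density(self, pts: np.ndarray) -> np.ndarray:
        d = len(self.center)
        diff = pts - self.center
        P = np.linalg.inv(self.cov)
        q = np.einsum("mi,ij,mj->m", diff, P, diff)
        norm = 1.0 / np.sqrt((2 * np.pi) ** d * np.linalg.det(self.cov))
        return self.weight * norm * np.exp(-0.5 * q)


@dataclass
class LaminarBand:
    """Curved lamina: cells scattered around a parametric curve with Gaussian thickness."""

    curve: Callable[[np.ndarray], np.ndarray]  # t in [0,1] -> (m, 2) µm
    thickness: float = 50.0
    weight: float = 1.0
    cell_type: int = 0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        t = rng.uniform(0.0, 1.0, n)
        base = self.curve(t)
        return base + rng.normal(scale=self.thickness, size=base.shape)


@dataclass
class TissueSpec:
    """Recipe for a synthetic tissue section."""

    blobs: List[BlobComponent] = field(default_factory=list)
    bands: List[LaminarBand] = field(default_factory=list)
    n: int = 3000
    seed: int = 0
    n_genes: int = 20
    expression_rate: float = 5.0  # mean total counts per cell

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.blobs and not self.bands:
            raise ValueError("spec needs at least one component")
        for b in self.blobs:
            if b.weight < 0:
                raise ValueError("densities must be nonnegative")

    @property
    def n_types(self) -> int:
        types = [c.cell_type for c in self.blobs] + [c.cell_type for c in self.bands]
        return max(types) + 1


def _type_profiles(n_types: int, n_genes: int, rng: np.random.Generator) -> np.ndarray:
    """Per-type mean expression over genes: baseline plus type-specific markers."""
    prof = rng.uniform(0.05, 0.3, size=(n_types, n_genes))
    markers = np.array_split(np.arange(n_genes), n_types)
    for t, idx in enumerate(markers):
        prof[t, idx] += 2.0
    return prof


def make_tissue(spec: TissueSpec) -> PointSet:
    """Draw a tissue section from a spec: reproducible, exactly ``spec.n`` cells.

    Cells are assigned to components proportional to component weight,
    positions drawn from the component geometry, and counts drawn per cell
    from Poisson means given by its type's expression profile.  Labels are
    stored on the returned PointSet.
    """
    rng = np.random.default_rng(spec.seed)
    comps = list(spec.blobs) + list(spec.bands)
    w = np.array([c.weight for c in comps], dtype=float)
    if w.sum() <= 0:
        raise ValueError("total component weight must be positive")
    counts = rng.multinomial(spec.n, w / w.sum())
    xy, labels = [], []
    for c, k in zip(comps, counts):
        if k == 0:
            continue
        if isinstance(c, BlobComponent):
            pts = rng.multivariate_normal(c.center, c.cov, size=k)
        else:
            pts = c.sample(k, rng)
        xy.append(pts)
        labels.append(np.full(k, c.cell_type))
    pts = np.concatenate(xy)
    labels = np.concatenate(labels)
    order = rng.permutation(len(pts))
    pts, labels = pts[order], labels[order]

    prof = _type_profiles(spec.n_types, spec.n_genes, rng)
    scale = spec.expression_rate / prof.sum(axis=1, keepdims=True)
    counts_matrix = rng.poisson(prof[labels] * scale[labels])
    names = [f"gene{g:02d}" for g in range(spec.n_genes)]
    return PointSet(pts[:, 0], pts[:, 1], feature_matrix=counts_matrix,
                    feature_names=names, labels=labels)


# ---------------------------------------------------------------------------
# ground-truth warps

@dataclass
class WarpSpec:
    """Analytic diffeomorphism: affine composed with a sum of Gaussian bumps.

    forward(x) = L @ (x + sum_i amp_i * exp(-|x - c_i|^2 / (2 w_i^2))) + T

    The inner displacement has Jacobian id + Du with ||Du|| <= sum_i
    |amp_i| * exp(-1/2) / w_i; requiring that bound < 1 guarantees a
    positive Jacobian determinant everywhere, hence a true diffeomorphism.
    """

    affine: AffineTransform = field(default_factory=lambda: AffineTransform.identity(2))
    bump_centers: Sequence[np.ndarray] = ()
    bump_amps: Sequence[np.ndarray] = ()  # µm displacement vectors
    bump_widths: Sequence[float] = ()

    def __post_init__(self):
        self.bump_centers = [np.asarray(c, dtype=float) for c in self.bump_centers]
        self.bump_amps = [np.asarray(a, dtype=float) for a in self.bump_amps]
        self.bump_widths = [float(w) for w in self.bump_widths]
        if not (len(self.bump_centers) == len(self.bump_amps) == len(self.bump_widths)):
            raise ValueError("bump lists must have equal length")
        if self.jacobian_bound() >= 1.0:
            raise ValueError("not diffeomorphic: bump amplitudes too large for their widths")

    def jacobian_bound(self) -> float:
        """Upper bound on ||Du||; < 1 certifies invertibility."""
        return sum(np.linalg.norm(a) * np.exp(-0.5) / w
                   for a, w in zip(self.bump_amps, self.bump_widths))

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        u = np.zeros_like(pts)
        for c, a, w in zip(self.bump_centers, self.bump_amps, self.bump_widths):
            r2 = ((pts - c) ** 2).sum(axis=1)
            u += np.exp(-0.5 * r2 / w**2)[:, None] * a
        return u


class GroundTruthWarp:
    """Evaluable ground-truth map with analytic forward and iterative inverse."""

    def __init__(self, spec: WarpSpec, tol: float = 1e-8, max_iter: int = 200):
        self.spec = spec
        self.tol = tol
        self.max_iter = max_iter

    def forward(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return self.spec.affine.apply(pts + self.spec.displacement(pts))

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        """Damped fixed-point inversion of x + u(x) = y, to ``tol`` µm."""
        y = self.spec.affine.inverse().apply(np.atleast_2d(np.asarray(pts, dtype=float)))
        x = y.copy()
        damp = 1.0 / (1.0 + self.spec.jacobian_bound())
        for _ in range(self.max_iter):
            step = y - (x + self.spec.displacement(x))
            x = x + damp * step
            if np.abs(step).max() < self.tol * damp:
                break
        return x

    def __call__(self, pts):
        return self.forward(pts)


def warp_points(points: PointSet, warp: WarpSpec):
    """Apply the analytic forward map exactly; returns (warped, GroundTruthWarp)."""
    truth = GroundTruthWarp(warp)
    return points.with_coords(truth.forward(points.coords)), truth


def degrade(points: PointSet, drop_polygon=None, artifact_rate: float = 0.0,
            seed: int = 0) -> PointSet:
    """Remove cells inside ``drop_polygon`` and sprinkle uniform artifact cells.

    ``drop_polygon`` is an (m, 2) vertex array or shapely polygon;
    ``artifact_rate`` is the number of artifact cells added per original
    cell, scattered uniformly over the original bounding box.  Artifact
    cells carry zero counts and label -1.
    """
    if not 0.0 <= artifact_rate <= 1.0:
        raise ValueError("artifact_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = np.ones(len(points), dtype=bool)
    if drop_polygon is not None and (not hasattr(drop_polygon, "__len__") or len(drop_polygon) >= 3):
        poly = drop_polygon if isinstance(drop_polygon, shapely.Polygon) \
            else shapely.Polygon(np.asarray(drop_polygon, dtype=float))
        keep = ~shapely.contains_xy(poly, points.x, points.y)
    kept = points.subset(keep)

    n_art = int(round(artifact_rate * len(points)))
    if n_art == 0:
        return kept
    (xmin, xmax), (ymin, ymax) = points.bounding_box()
    ax = rng.uniform(xmin, xmax, n_art)
    ay = rng.uniform(ymin, ymax, n_art)
    feats = None
    if kept.feature_matrix is not None:
        feats = np.vstack([kept.feature_matrix,
                           np.zeros((n_art, kept.feature_matrix.shape[1]), dtype=kept.feature_matrix.dtype)])
    labels = None
    if kept.labels is not None:
        labels = np.concatenate([kept.labels, np.full(n_art, -1)])
    return PointSet(np.concatenate([kept.x, ax]), np.concatenate([kept.y, ay]),
                    feature_matrix=feats, feature_names=kept.feature_names, labels=labels)


# ---------------------------------------------------------------------------
# 3D volumes

def _interp_specs(specs: List[TissueSpec], frac: float):
    """Linearly interpolate blob parameters between two adjacent key specs."""
    k = len(specs) - 1
    if k == 0:
        return specs[0], specs[0], 0.0
    pos = frac * k
    i = min(int(np.floor(pos)), k - 1)
    return specs[i], specs[i + 1], pos - i


def _blob_density_2d(spec_lo: TissueSpec, spec_hi: TissueSpec, t: float,
                     pts2: np.ndarray, labels_out=None):
    dens = np.zeros((len(spec_lo.blobs), pts2.shape[0]))
    for j, (blo, bhi) in enumerate(zip(spec_lo.blobs, spec_hi.blobs)):
        b = BlobComponent((1 - t) * blo.center + t * bhi.center,
                          (1 - t) * blo.cov + t * bhi.cov,
                          (1 - t) * blo.weight + t * bhi.weight,
                          blo.cell_type)
        dens[j] = b.density(pts2)
    return dens


def make_volume(specs, n_sections: int, section_extent=None, voxel_size: float = 50.0,
                label_threshold: float = 1e-9):
    """Stack 2D blob specs into a smooth 3D atlas-style volume plus annotations.

    ``specs`` is a single TissueSpec or a list of key specs whose blob
    parameters are linearly interpolated along the out-of-plane x axis
    (``n_sections`` voxel planes, spaced ``voxel_size`` µm).  Voxel labels
    are the dominant component's cell type (+1; 0 = outside tissue) where
    total density exceeds ``label_threshold``.  Returns (AtlasVolume with
    annotation, analytic density function rho(x, y, z)).
    """
    if isinstance(specs, TissueSpec):
        specs = [specs]
    if n_sections < 3:
        raise ValueError("nz (number of sections) must be >= 3")
    nblob = {len(s.blobs) for s in specs}
    if len(nblob) != 1:
        raise ValueError("all key specs must have the same number of blobs")
    if section_extent is None:
        centers = np.concatenate([[b.center for b in s.blobs] for s in specs])
        sds = np.concatenate([[np.sqrt(np.diag(b.cov)).max() for b in s.blobs] for s in specs])
        lo = centers.min(axis=0) - 3.5 * sds.max()
        hi = centers.max(axis=0) + 3.5 * sds.max()
        section_extent = ((lo[0], hi[0]), (lo[1], hi[1]))
    (ymin, ymax), (zmin, zmax) = section_extent

    x_ax = voxel_size * (0.5 + np.arange(n_sections))
    y_ax = ymin + voxel_size * (0.5 + np.arange(max(int(np.ceil((ymax - ymin) / voxel_size)), 1)))
    z_ax = zmin + voxel_size * (0.5 + np.arange(max(int(np.ceil((zmax - zmin) / voxel_size)), 1)))
    x_span = x_ax[-1] - x_ax[0] if n_sections > 1 else 1.0

    def density_components(pts3):
        """Per-component density at (m, 3) points (x, y, z)."""
        pts3 = np.atleast_2d(np.asarray(pts3, dtype=float))
        frac = np.clip((pts3[:, 0] - x_ax[0]) / x_span, 0.0, 1.0)
        out = np.zeros((len(specs[0].blobs), pts3.shape[0]))
        # piecewise-linear in x between key specs; vectorized per segment
        k = max(len(specs) - 1, 1)
        seg = np.minimum((frac * k).astype(int), k - 1) if len(specs) > 1 else np.zeros(len(frac), int)
        for si in np.unique(seg):
            sel = seg == si
            lo = specs[si]
            hi = specs[min(si + 1, len(specs) - 1)]
            t = frac[sel] * k - si if len(specs) > 1 else np.zeros(sel.sum())
            for j, (blo, bhi) in enumerate(zip(lo.blobs, hi.blobs)):
                tt = t[:, None]
                center = (1 - tt) * blo.center + tt * bhi.center
                cov_d = (1 - t)[:, None] * np.diag(blo.cov) + t[:, None] * np.diag(bhi.cov)
                w = (1 - t) * blo.weight + t * bhi.weight
                diff = pts3[sel, 1:] - center
                q = (diff ** 2 / cov_d).sum(axis=1)
                norm = 1.0 / (2 * np.pi * np.sqrt(np.prod(cov_d, axis=1)))
                out[j, sel] = w * norm * np.exp(-0.5 * q)
        return out

    def density(pts3):
        return density_components(pts3).sum(axis=0)

    from ._interp import grid_points
    pts = grid_points([x_ax, y_ax, z_ax])
    comp = density_components(pts)
    shape = (len(x_ax), len(y_ax), len(z_ax))
    intensity = comp.sum(axis=0).reshape(shape)
    types = np.array([b.cell_type for b in specs[0].blobs])
    ann = np.where(comp.sum(axis=0) > label_threshold,
                   types[comp.argmax(axis=0)] + 1, 0).reshape(shape)
    vol = AtlasVolume(intensity, axes=[x_ax, y_ax, z_ax], annotation=ann)
    return vol, density


def sample_oblique_section(density: Callable, volume: AtlasVolume, angle_deg: float,
                           dx: float, center: Optional[np.ndarray] = None,
                           half_extent: Optional[tuple] = None):
    """Analytic oblique section of a synthetic volume, as a 2D raster.

    The section plane passes through ``center`` with normal rotated by
    ``angle_deg`` from the volume's x axis (rotation in the x-y plane), and
    is sampled on a (u, v) grid of spacing ``dx``.  Returns (RasterImage,
    function embedding (u, v) slice coordinates into 3D volume µm).
    """
    from .raster import RasterImage

    th = np.deg2rad(angle_deg)
    if center is None:
        center = np.array([np.mean([a[0], a[-1]]) for a in volume.axes])
    e_u = np.array([-np.sin(th), np.cos(th), 0.0])  # in-plane, tilted from y
    e_v = np.array([0.0, 0.0, 1.0])                 # in-plane, along z
    if half_extent is None:
        hu = (volume.axes[1][-1] - volume.axes[1][0]) / 2.0
        hv = (volume.axes[2][-1] - volume.axes[2][0]) / 2.0
    else:
        hu, hv = half_extent
    u_ax = np.arange(-hu + dx / 2.0, hu, dx)
    v_ax = np.arange(-hv + dx / 2.0, hv, dx)

    def embed(uv):
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return center + uv[:, :1] * e_u + uv[:, 1:2] * e_v

    uu, vv = np.meshgrid(u_ax, v_ax, indexing="ij")
    pts3 = embed(np.stack([uu.ravel(), vv.ravel()], axis=1))
    vals = density(pts3).reshape(len(u_ax), len(v_ax))
    # raster convention: rows = v (second slice coord), cols = u
    img = RasterImage(vals.T[None], v_ax, u_ax)
    return img, embed


# ---------------------------------------------------------------------------
# default fixture

def toy_coronal(n: int = 3000, seed: int = 0) -> TissueSpec:
    """Toy coronal section: two mirrored blob clusters plus a curved lamina."""

    def lamina(t):
        x = -650.0 + 1300.0 * t
        y = 420.0 - 900.0 * (t - 0.5) ** 2 * 4.0 * 0.45
        return np.stack([x, y], axis=1)

    blobs = [
        BlobComponent([-420.0, -120.0], np.diag([150.0**2, 210.0**2]), 1.0, cell_type=0),
        BlobComponent([420.0, -120.0], np.diag([150.0**2, 210.0**2]), 1.0, cell_type=1),
        BlobComponent([-260.0, -430.0], np.diag([110.0**2, 80.0**2]), 0.45, cell_type=2),
        BlobComponent([260.0, -430.0], np.diag([110.0**2, 80.0**2]), 0.45, cell_type=3),
        BlobComponent([0.0, 120.0], np.diag([120.0**2, 140.0**2]), 0.5, cell_type=4),
    ]
    bands = [LaminarBand(lamina, thickness=45.0, weight=0.9, cell_type=4)]
    return TissueSpec(blobs=blobs, bands=bands, n=n, seed=seed, n_genes=20)
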