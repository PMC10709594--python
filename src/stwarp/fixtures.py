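"""Reference desk-scale study conditions for the synthetic benchmarks.

These functions pin down one set of conditions — tissue, ground-truth
warp, raster geometry, optimizer configuration — that the test suite, the
acceptance script and the examples all share, so every reported number
refers to the same experiment.

The tissue is the ~3000-cell toy coronal section rasterized on a 64 x 64
grid at 30 µm; alignments run 500 iterations.  The gradient-descent step
sizes here are the package's configuration for this fixture's intensity
scale (images normalized to [0, 1], matching weight sigmaM = 0.2): raw
gradient steps scale with image intensity, pixel measure and coordinate
magnitude, so — exactly as with real datasets — the generic defaults are
retuned to the data at hand.  The mixture component parameters place
background at intensity 0 (sd 0.05) and artifact above the tissue range
(mean 2, sd 0.5), so bright structures are never absorbed by the artifact
class.
"""

from __future__ import annotations

import numpy as np

from .deform import AffineTransform
from .lddmm import LDDMMConfig
from .points import PointSet
from .raster import RasterImage, rasterize
from .synth import (BlobComponent, TissueSpec, WarpSpec, make_tissue,
                    make_volume, toy_coronal)

__all__ = [
    "TOY_EXTENT", "toy_tissue", "toy_raster", "toy_warp", "desk_config",
    "ablation_polygon", "toy_volume_specs", "toy_volume", "volume_config",
]

# 64 x 64 pixels at dx = 30 µm
TOY_EXTENT = ((-960.0, 960.0), (-960.0, 960.0))


def toy_tissue(n: int = 3000, seed: int = 0) -> PointSet:
    """The toy coronal section (two mirrored clusters + curved lamina)."""
    return make_tissue(toy_coronal(n=n, seed=seed))


def toy_raster(points: PointSet, dx: float = 30.0) -> RasterImage:
    """Rasterize on the fixed 64 x 64 fixture grid."""
    return rasterize(points, dx=dx, extent=TOY_EXTENT)


def toy_warp(amplitude: float = 60.0) -> WarpSpec:
    """Ground-truth warp: small translation + three smooth bumps.

    The default amplitude is two raster pixels (60 µm); the Jacobian bound
    stays well below 1, certifying the warp is a diffeomorphism.
    """
    s = amplitude / 60.0
    return WarpSpec(
        affine=AffineTransform(np.eye(2), [40.0, -30.0]),
        bump_centers=[[-400.0, 0.0], [350.0, -250.0], [0.0, 350.0]],
        bump_amps=[[60.0 * s, 25.0 * s], [-45.0 * s, 60.0 * s], [30.0 * s, -60.0 * s]],
        bump_widths=[350.0, 300.0, 320.0],
    )


def desk_config(niter: int = 500, affine_only: bool = False, **overrides) -> LDDMMConfig:
    """Optimizer configuration for the toy fixture (see module docstring)."""
    kw = dict(
        dx=30.0, niter=niter, sigmaM=0.2, sigmaB=0.05, sigmaA=0.5,
        muB=0.0, muA=2.0, epT=3e-4, epL=1e-9, epV=20.0,
        diffeo_start=niter if affine_only else 30,
    )
    kw.update(overrides)
    return LDDMMConfig(**kw)


def ablation_polygon(points: PointSet, fraction: float = 0.4) -> np.ndarray:
    """Vertical slab covering the leftmost ``fraction`` of cells (a torn-off piece)."""
    xs = np.sort(points.x)
    cut = xs[int(fraction * len(xs))]
    big = 10 * max(abs(points.x).max(), abs(points.y).max())
    return np.array([[-big, -big], [cut, -big], [cut, big], [-big, big]])


def _volume_key_spec(shift: float, weights) -> TissueSpec:
    blobs = [
        BlobComponent([-420.0 + shift, -120.0], np.diag([160.0**2, 210.0**2]), weights[0], 0),
        BlobComponent([420.0 - shift, -120.0], np.diag([160.0**2, 210.0**2]), weights[1], 1),
        BlobComponent([0.0, 300.0 + shift], np.diag([200.0**2, 130.0**2]), weights[2], 2),
        BlobComponent([0.0, -420.0], np.diag([260.0**2, 110.0**2]), weights[3], 3),
    ]
    return TissueSpec(blobs=blobs, n=1000)


def toy_volume_specs():
    """Key sections of the toy 3D volume: structures drift and fade along AP."""
    return [
        _volume_key_spec(-140.0, [1.2, 0.5, 0.6, 0.9]),
        _volume_key_spec(0.0, [0.9, 0.9, 1.0, 0.5]),
        _volume_key_spec(140.0, [0.4, 1.3, 0.5, 1.0]),
    ]


def toy_volume(n_sections: int = 24, voxel_size: float = 50.0):
    """(AtlasVolume with annotations, analytic density rho(x, y, z))."""
    return make_volume(toy_volume_specs(), n_sections=n_sections, voxel_size=voxel_size)


def volume_config(niter: int = 1000, affine_only: bool = True, **overrides) -> LDDMMConfig:
    """Optimizer configuration for 3D-to-2D runs on the toy volume."""
    kw = dict(
        dx=50.0, niter=niter, nt=4, sigmaM=0.2, sigmaB=0.05, sigmaA=0.5,
        muB=0.0, muA=2.0, epT=3e-4, epL=1e-8, epV=8.0,
        diffeo_start=niter if affine_only else max(niter // 10, 1),
    )
    kw.update(overrides)
    return LDDMMConfig(**kw)
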