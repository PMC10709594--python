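"""Multilinear grid interpolation with exact adjoints.

All alignment machinery (flow integration, image pull-back, velocity
gradients) is built on three primitives over a uniform rectilinear grid in
physical (µm) coordinates:

- ``interp``       : sample a gridded field at arbitrary points
- ``interp_grad``  : same, plus the exact spatial derivative of the
                     interpolant at each point
- ``scatter``      : the adjoint of ``interp`` with respect to the field
                     values (transpose of the sparse interpolation matrix)

``interp``/``scatter`` form an exact transpose pair, and ``interp_grad``
returns the exact derivative of the (piecewise-multilinear, edge-clamped)
forward computation, so reverse-mode gradients assembled from them match
finite differences of the discrete objective to rounding error.

Out-of-grid behaviour is constant (edge-clamp) extension: sample
coordinates are clamped to the grid hull, and the spatial derivative is
zero outside (the exact derivative of the clamped forward pass).
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["interp", "interp_grad", "scatter", "grid_points"]


def _locate(axes, pts, clamp=True):
    """Return corner index i0 (m,d), fraction (m,d), inside-mask (m,d).

    ``axes`` is a sequence of d strictly-increasing uniformly-spaced 1D
    coordinate arrays; ``pts`` is (m, d) in the same units.
    """
    pts = np.asarray(pts, dtype=float)
    d = len(axes)
    if pts.ndim != 2 or pts.shape[1] != d:
        raise ValueError(f"points must be (m, {d}), got {pts.shape}")
    i0 = np.empty(pts.shape, dtype=np.intp)
    frac = np.empty(pts.shape)
    inside = np.empty(pts.shape, dtype=bool)
    for k, ax in enumerate(axes):
        n = len(ax)
        dx = ax[1] - ax[0] if n > 1 else 1.0
        u = (pts[:, k] - ax[0]) / dx
        inside[:, k] = (u >= 0.0) & (u <= n - 1)
        if clamp:
            u = np.clip(u, 0.0, n - 1)
        i = np.clip(np.floor(u).astype(np.intp), 0, max(n - 2, 0))
        i0[:, k] = i
        frac[:, k] = u - i
    return i0, frac, inside


def _corner_weights(frac, corner):
    w = np.ones(frac.shape[0])
    for k, c in enumerate(corner):
        w = w * (frac[:, k] if c else 1.0 - frac[:, k])
    return w


def interp(field, axes, pts, mode="clamp", fill=0.0):
    """Multilinear sample of ``field`` (..., n0, ..., n_{d-1}) at ``pts`` (m,d).

    Returns an array of shape (..., m).  ``mode='clamp'`` extends the field
    by its edge values; ``mode='fill'`` returns ``fill`` for points outside
    the grid hull.
    """
    axes = [np.asarray(a, dtype=float) for a in axes]
    d = len(axes)
    field = np.asarray(field)
    shape = field.shape[-d:]
    lead = field.shape[:-d]
    flat = field.reshape(*lead, -1)
    strides = np.array([int(np.prod(shape[k + 1:])) for k in range(d)], dtype=np.intp)

    i0, frac, inside = _locate(axes, pts)
    out = np.zeros(lead + (pts.shape[0],))
    for corner in itertools.product((0, 1), repeat=d):
        lin = ((i0 + np.array(corner, dtype=np.intp)) * strides).sum(axis=1)
        w = _corner_weights(frac, corner)
        out += flat[..., lin] * w
    if mode == "fill":
        out = np.where(inside.all(axis=1), out, fill)
    elif mode != "clamp":
        raise ValueError(f"unknown mode {mode!r}")
    return out


def interp_grad(field, axes, pts):
    """Sample ``field`` at ``pts`` and return (values, spatial derivative).

    values: (..., m); derivative: (..., m, d) — the exact derivative of the
    edge-clamped multilinear interpolant (zero outside the grid hull).
    """
    axes = [np.asarray(a, dtype=float) for a in axes]
    d = len(axes)
    field = np.asarray(field)
    shape = field.shape[-d:]
    lead = field.shape[:-d]
    flat = field.reshape(*lead, -1)
    strides = np.array([int(np.prod(shape[k + 1:])) for k in range(d)], dtype=np.intp)
    dxs = [a[1] - a[0] if len(a) > 1 else 1.0 for a in axes]

    i0, frac, inside = _locate(axes, pts)
    m = pts.shape[0]
    val = np.zeros(lead + (m,))
    grad = np.zeros(lead + (m, d))
    for corner in itertools.product((0, 1), repeat=d):
        lin = ((i0 + np.array(corner, dtype=np.intp)) * strides).sum(axis=1)
        fv = flat[..., lin]
        val += fv * _corner_weights(frac, corner)
        for k in range(d):
            # d/dx_k of the weight product: sign on axis k, product elsewhere
            w = np.ones(m)
            for j, c in enumerate(corner):
                if j == k:
                    w = w * (1.0 if c else -1.0)
                else:
                    w = w * (frac[:, j] if c else 1.0 - frac[:, j])
            grad[..., k] += fv * (w / dxs[k])
    grad *= inside.all(axis=1)[..., :, None]
    return val, grad


def scatter(g, axes, pts, shape):
    """Adjoint of ``interp`` w.r.t. the field values.

    ``g`` has shape (..., m); returns an array of shape (..., *shape) such
    that ``<scatter(g), F> == <g, interp(F)>`` for every field F.
    """
    axes = [np.asarray(a, dtype=float) for a in axes]
    d = len(axes)
    g = np.asarray(g)
    lead = g.shape[:-1]
    out = np.zeros(lead + (int(np.prod(shape)),))
    strides = np.array([int(np.prod(shape[k + 1:])) for k in range(d)], dtype=np.intp)
    i0, frac, _ = _locate(axes, pts)
    for corner in itertools.product((0, 1), repeat=d):
        lin = ((i0 + np.array(corner, dtype=np.intp)) * strides).sum(axis=1)
        w = _corner_weights(frac, corner)
        contrib = g * w
        if lead:
            for idx in np.ndindex(*lead):
                np.add.at(out[idx], lin, contrib[idx])
        else:
            np.add.at(out, lin, contrib)
    return out.reshape(lead + tuple(shape))


def grid_points(axes, indexing="ij"):
    """Stack the mesh of ``axes`` into an (N, d) point array (C order)."""
    mesh = np.meshgrid(*axes, indexing=indexing)
    return np.stack([m.ravel() for m in mesh], axis=1)
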