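"""Affine + LDDMM alignment of raster images by steepest gradient descent.

The solved map ``phi(x) = A @ flow_1(x)`` minimizes

    E = R(v) + M(phi . I_S, I_T) [+ landmark term]

where the regularization

    R(v) = 1/(2 sigmaR^2) * sum_t dt * || (id - a^2 Lap)^p v_t ||_L2^2

penalizes non-smooth velocity fields (evaluated in the frequency domain via
the discrete Laplacian symbol), and the matching term compares the pulled-
back source image with the target under a per-pixel three-component
Gaussian mixture (matching / background / artifact) and a polynomial
contrast function mapping source intensity to target intensity.  The
mixture lets partially matched tissue — tears, missing pieces,
contaminating signal — be down-weighted instead of dragging the map; the
contrast function absorbs modality and cell-density differences.

Each iteration alternates (i) an E-step update of the mixture posteriors,
(ii) a weighted least-squares refit of the contrast polynomial, and
(iii) gradient steps on the affine translation (step ``epT``), linear part
(``epL``) and — once the iteration counter reaches ``diffeo_start`` — each
velocity timestep (``epV``).  The raw velocity gradient is smoothed by the
inverse regularization operator (id - a^2 Lap)^(-2p) before stepping
(natural gradient), which keeps updates in the space of smooth fields.

Gradients are exact reverse-mode adjoints of the discrete objective,
assembled from the interpolation primitives in ``_interp`` (they match
central finite differences on small instances; see the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._interp import interp, interp_grad, scatter
from .deform import AffineTransform, DiffeoMap, GridAxes, VelocityField
from .raster import RasterImage

__all__ = [
    "LDDMMConfig", "MixtureWeights", "ContrastModel", "AlignmentResult",
    "regularization_energy", "gmm_posteriors", "fit_contrast",
    "matching_energy", "landmark_energy", "landmark_affine", "lddmm_align",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class LDDMMConfig:
    """All tunable parameters of the alignment, with their standard defaults.

    sigmaM / sigmaR / sigmaP weight the image-matching, regularization and
    landmark functionals; sigmaB / sigmaA are the (fixed) standard
    deviations of the background and artifact mixture components; ``a`` and
    ``p`` set the smoothness scale (µm) and Laplacian power of the
    regularizer; epL/epT/epV are gradient-descent step sizes.  Either L and
    T can be specified, or A, but not both.
    """

    dx: float = 30.0
    sigmaM: float = 1.0
    sigmaR: float = 5.0e5
    sigmaP: float = 2.0e1
    sigmaA: float = 5.0
    sigmaB: float = 2.0
    a: float = 500.0
    p: float = 2.0
    niter: int = 5000
    diffeo_start: int = 0
    nt: int = 3
    epL: float = 2.0e-8
    epT: float = 2.0e-1
    epV: float = 2.0e3
    pointsI: Optional[np.ndarray] = None
    pointsJ: Optional[np.ndarray] = None
    muB: Optional[np.ndarray] = None
    muA: Optional[np.ndarray] = None
    L: Optional[np.ndarray] = None
    T: Optional[np.ndarray] = None
    A: Optional[np.ndarray] = None
    contrast_degree: int = 1
    mixture: bool = True
    normalize: bool = True

    def __post_init__(self):
        for name in ("sigmaM", "sigmaR", "sigmaP", "sigmaA", "sigmaB"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.niter < 0 or self.nt < 1:
            raise ValueError("niter must be >= 0 and nt >= 1")
        if self.A is not None and (self.L is not None or self.T is not None):
            raise ValueError("either L and T can be specified, or A, but not both")

    def initial_affine(self, d: int) -> Optional[AffineTransform]:
        if self.A is not None:
            A = np.asarray(self.A, dtype=float)
            return AffineTransform(A[:d, :d], A[:d, d])
        if self.L is not None or self.T is not None:
            L = np.eye(d) if self.L is None else np.asarray(self.L, dtype=float)
            T = np.zeros(d) if self.T is None else np.asarray(self.T, dtype=float)
            return AffineTransform(L, T)
        return None


@dataclass
class MixtureWeights:
    """Per-pixel posterior probabilities of (matching, background, artifact)."""

    values: np.ndarray  # (3, ...) summing to 1 along axis 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != 3:
            raise ValueError("expected 3 mixture components")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("posteriors must lie in [0, 1]")
        if not np.allclose(self.values.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("posteriors must sum to 1 at every pixel")

    @property
    def matching(self):
        return self.values[0]

    @property
    def background(self):
        return self.values[1]

    @property
    def artifact(self):
        return self.values[2]


@dataclass
class ContrastModel:
    """Per-target-channel polynomial mapping source intensity -> target intensity."""

    coeffs: np.ndarray  # (n_channels, degree + 1), low order first
    degree: int
    reduced: bool = False  # True when rank deficiency forced a lower degree

    def __post_init__(self):
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        if not np.isfinite(self.coeffs).all():
            raise ValueError("contrast coefficients must be finite")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")

    @classmethod
    def identity(cls, n_channels: int = 1, degree: int = 1) -> "ContrastModel":
        c = np.zeros((n_channels, degree + 1))
        if degree >= 1:
            c[:, 1] = 1.0
        return cls(c, degree)

    def apply(self, s: np.ndarray) -> np.ndarray:
        """Evaluate f(s); s is (m,) -> (n_channels, m)."""
        basis = np.vander(np.asarray(s, dtype=float).ravel(),
                          self.coeffs.shape[1], increasing=True)
        return self.coeffs @ basis.T

    def derivative(self, s: np.ndarray) -> np.ndarray:
        """f'(s) per channel, shape (n_channels, m)."""
        s = np.asarray(s, dtype=float).ravel()
        k = self.coeffs.shape[1]
        if k == 1:
            return np.zeros((self.coeffs.shape[0], s.size))
        dbasis = np.vander(s, k - 1, increasing=True) * np.arange(1, k)
        return self.coeffs[:, 1:] @ dbasis.T


@dataclass
class AlignmentResult:
    """Solved map plus everything needed to audit the optimization."""

    diffeo: DiffeoMap
    trace: dict  # per-iteration 'matching', 'regularization', 'landmark', 'total'
    weights: Optional[MixtureWeights]
    contrast: Optional[ContrastModel]
    config: LDDMMConfig
    target_grid: Optional[GridAxes] = None

    @property
    def n_iterations(self) -> int:
        return len(self.trace["total"])

    def transform_points(self, pts, **kw):
        return self.diffeo.transform_points(pts, **kw)

    def transform_points_inverse(self, pts, **kw):
        return self.diffeo.transform_points_inverse(pts, **kw)


# ---------------------------------------------------------------------------
# spec operations

def _laplacian_symbol(axes):
    """Fourier symbol of the discrete (periodic) Laplacian on the grid."""
    acc = 0.0
    nd = len(axes)
    for k, ax in enumerate(axes):
        n = len(ax)
        dxk = float(ax[1] - ax[0]) if n > 1 else 1.0
        lam = (2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(n)) - 2.0) / dxk**2
        shape = [1] * nd
        shape[k] = n
        acc = acc + lam.reshape(shape)
    return acc


def regularization_symbol(axes, a: float, p: float) -> np.ndarray:
    """Symbol of (id - a^2 Lap)^(2p) — the quadratic form of R(v)."""
    return (1.0 - a * a * _laplacian_symbol(axes)) ** (2.0 * p)


def regularization_energy(v: VelocityField, sigmaR: float,
                          a: Optional[float] = None, p: Optional[float] = None) -> float:
    """R(v) = 1/(2 sigmaR^2) * sum_t dt * ||(id - a^2 Lap)^p v_t||_L2^2.

    Evaluated in the frequency domain via Parseval; equals applying the
    spatial finite-difference operator (periodic) and summing squares.
    """
    a = v.a if a is None else a
    p = v.p if p is None else p
    LL = regularization_symbol(v.grid.axes, a, p)
    dt = 1.0 / v.nt
    cell = float(np.prod(v.grid.spacing))
    n = float(np.prod(v.grid.shape))
    spatial_axes = tuple(range(2, v.values.ndim))
    vhat = np.fft.fftn(v.values, axes=spatial_axes)
    total = (np.abs(vhat) ** 2 * LL).sum()
    return float(total * dt * cell / (2.0 * sigmaR**2 * n))


def gmm_posteriors(predicted, target, sigmaM: float = 1.0, sigmaB: float = 2.0,
                   sigmaA: float = 5.0, muB=None, muA=None) -> MixtureWeights:
    """E-step posteriors of the three-component per-pixel Gaussian mixture.

    matching: mean = predicted pixel value, sd sigmaM; background: mean muB,
    sd sigmaB; artifact: mean muA, sd sigmaA.  Components have equal priors
    and, for multichannel targets, densities are products over channels.
    When muB/muA are None they fall back to the darkest / brightest decile
    means of the target.
    """
    pred = np.asarray(predicted.values if isinstance(predicted, RasterImage) else predicted, dtype=float)
    targ = np.asarray(target.values if isinstance(target, RasterImage) else target, dtype=float)
    if pred.ndim == targ.ndim - 0 and pred.shape != targ.shape:
        raise ValueError("predicted and target must share a grid")
    C = targ.shape[0] if targ.ndim >= 2 else 1
    targ2 = targ.reshape(C, -1)
    pred2 = pred.reshape(C, -1)
    muB = _decile_means(targ2, "low") if muB is None else np.broadcast_to(np.atleast_1d(muB), (C,))
    muA = _decile_means(targ2, "high") if muA is None else np.broadcast_to(np.atleast_1d(muA), (C,))

    logs = np.stack([
        _log_gauss(targ2, pred2, sigmaM),
        _log_gauss(targ2, np.asarray(muB, dtype=float)[:, None], sigmaB),
        _log_gauss(targ2, np.asarray(muA, dtype=float)[:, None], sigmaA),
    ])
    logs -= logs.max(axis=0, keepdims=True)
    W = np.exp(logs)
    W /= W.sum(axis=0, keepdims=True)
    return MixtureWeights(W.reshape((3,) + targ.shape[1:] if targ.ndim >= 2 else (3, targ.size)))


def _log_gauss(x, mu, sigma):
    return (-0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma)).sum(axis=0)


def _decile_means(channels, which):
    out = np.empty(channels.shape[0])
    for c, vals in enumerate(channels):
        q = np.quantile(vals, 0.1 if which == "low" else 0.9)
        sel = vals <= q if which == "low" else vals >= q
        out[c] = vals[sel].mean()
    return out


def fit_contrast(source_intensity, target, weights=None, degree: int = 1) -> ContrastModel:
    """Weighted polynomial least squares of target intensity on source powers.

    One polynomial per target channel over a shared basis of powers of the
    transformed-source intensity, weighted by the matching posterior.  On
    rank deficiency (e.g. constant source) the degree is reduced to the
    largest solvable and the model flagged.
    """
    s = np.asarray(source_intensity.values if isinstance(source_intensity, RasterImage)
                   else source_intensity, dtype=float).ravel()
    targ = np.asarray(target.values if isinstance(target, RasterImage) else target, dtype=float)
    C = targ.shape[0] if targ.ndim >= 2 else 1
    J = targ.reshape(C, -1)
    if J.shape[1] != s.size:
        raise ValueError("source and target must share a grid")
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float).ravel()
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    sw = np.sqrt(w)
    deg = degree
    while True:
        B = np.vander(s, deg + 1, increasing=True)
        Bw = B * sw[:, None]
        coeffs, _, rank, _ = np.linalg.lstsq(Bw, (J * sw).T, rcond=None)
        if rank == deg + 1 or deg == 0:
            break
        deg -= 1
    model = ContrastModel(coeffs.T, deg, reduced=(deg != degree))
    if model.reduced:
        warnings.warn(f"contrast fit rank-deficient; degree reduced to {deg}")
    # keep requested shape: pad high-order coefficients with zeros
    if deg != degree:
        padded = np.zeros((C, degree + 1))
        padded[:, :deg + 1] = model.coeffs
        model = ContrastModel(padded, degree, reduced=True)
    return model


def matching_energy(transformed_source, target, weights, contrast: Optional[ContrastModel],
                    sigmaM: float = 1.0, pixel_measure: Optional[float] = None) -> float:
    """Mixture-weighted SSD between contrast-mapped source and target.

    1/(2 sigmaM^2) * sum_x W_match(x) * ||f(I_S o phi^-1)(x) - I_T(x)||^2 * dx^d
    (the background/artifact components enter only the posterior update).
    """
    s = np.asarray(transformed_source.values if isinstance(transformed_source, RasterImage)
                   else transformed_source, dtype=float)
    targ = target
    if isinstance(target, RasterImage):
        if pixel_measure is None:
            pixel_measure = target.dx ** 2
        targ = target.values
    targ = np.asarray(targ, dtype=float)
    pixel_measure = 1.0 if pixel_measure is None else pixel_measure
    C = targ.shape[0] if targ.ndim >= 2 else 1
    J = targ.reshape(C, -1)
    pred = contrast.apply(s.ravel()) if contrast is not None else s.reshape(C, -1)
    wm = weights.matching if isinstance(weights, MixtureWeights) else np.asarray(weights)
    resid = ((pred - J) ** 2).sum(axis=0)
    return float((wm.ravel() * resid).sum() * pixel_measure / (2.0 * sigmaM**2))


def landmark_energy(mapping, pointsI, pointsJ, sigmaP: float = 20.0) -> float:
    """1/(2 sigmaP^2) * sum_i ||map(pointsI_i) - pointsJ_i||^2."""
    pI = np.atleast_2d(np.asarray(pointsI, dtype=float))
    pJ = np.atleast_2d(np.asarray(pointsJ, dtype=float))
    if pI.shape != pJ.shape:
        raise ValueError("landmark lists must have equal length")
    if mapping is None:
        moved = pI
    elif isinstance(mapping, (DiffeoMap, AffineTransform)):
        moved = mapping.apply(pI) if isinstance(mapping, AffineTransform) else mapping.transform_points(pI)
    else:
        moved = np.atleast_2d(mapping(pI))
    return float(((moved - pJ) ** 2).sum() / (2.0 * sigmaP**2))


def landmark_affine(pointsI, pointsJ):
    """Least-squares affine sending pointsI onto pointsJ.

    Returns (AffineTransform, residual RMSE in µm).  Requires at least d+1
    points in general position; collinear or insufficient points raise.
    """
    pI = np.atleast_2d(np.asarray(pointsI, dtype=float))
    pJ = np.atleast_2d(np.asarray(pointsJ, dtype=float))
    if pI.shape != pJ.shape:
        raise ValueError("landmark lists must have equal length")
    n, d = pI.shape
    X = np.hstack([pI, np.ones((n, 1))])
    if n < d + 1 or np.linalg.matrix_rank(X) < d + 1:
        raise np.linalg.LinAlgError(
            "landmark affine is rank-deficient: need >= d+1 non-collinear point pairs")
    B, _, _, _ = np.linalg.lstsq(X, pJ, rcond=None)
    aff = AffineTransform(B[:d].T, B[d])
    rmse = float(np.sqrt(np.mean(np.sum((aff.apply(pI) - pJ) ** 2, axis=1))))
    return aff, rmse


# ---------------------------------------------------------------------------
# the optimizer core (dimension-agnostic)

class _PullbackTape:
    """Forward pass of the target->source pullback, with recorded positions."""

    def __init__(self, v: VelocityField, Ainv: AffineTransform, target_pts: np.ndarray):
        self.v = v
        dt = 1.0 / v.nt
        q = Ainv.apply(target_pts)
        self.q_affine = q.copy()
        self.sample_pos = [None] * v.nt
        for t in reversed(range(v.nt)):
            self.sample_pos[t] = q.copy()
            q = q - dt * v.sample(t, q)
        self.q_final = q

    def backprop(self, g_final: np.ndarray):
        """Adjoint: gradient at q_final -> (velocity grads per t, grad at q_affine)."""
        v, grid = self.v, self.v.grid
        dt = 1.0 / v.nt
        iperm = list(np.argsort(grid.perm))
        gq = g_final  # (m, d) point order
        vgrad = np.zeros_like(v.values)
        for t in range(v.nt):
            pos = grid.to_grid_order(self.sample_pos[t])
            # q_t = pos - dt * v_t(pos):  dE/dv_t = -dt * scatter(gq);  chain gq through pos
            vgrad[t] = -dt * scatter(gq.T, grid.axes, pos, grid.shape)
            _, Dv = interp_grad(v.values[t], grid.axes, pos)  # (d, m, d_gridorder)
            Dv = Dv[:, :, iperm]  # derivative w.r.t. point-order coords
            gq = gq - dt * np.einsum("imj,mi->mj", Dv, gq)
        return vgrad, gq


class _ForwardTape:
    """Forward flow of landmark points, with recorded positions (for adjoints)."""

    def __init__(self, v: VelocityField, pts: np.ndarray):
        self.v = v
        dt = 1.0 / v.nt
        r = np.asarray(pts, dtype=float).copy()
        self.sample_pos = [None] * v.nt
        for t in range(v.nt):
            self.sample_pos[t] = r.copy()
            r = r + dt * v.sample(t, r)
        self.r_final = r

    def backprop(self, g_final: np.ndarray):
        v, grid = self.v, self.v.grid
        dt = 1.0 / v.nt
        iperm = list(np.argsort(grid.perm))
        gr = g_final
        vgrad = np.zeros_like(v.values)
        for t in reversed(range(v.nt)):
            pos = grid.to_grid_order(self.sample_pos[t])
            vgrad[t] = dt * scatter(gr.T, grid.axes, pos, grid.shape)
            _, Dv = interp_grad(v.values[t], grid.axes, pos)
            Dv = Dv[:, :, iperm]
            gr = gr + dt * np.einsum("imj,mi->mj", Dv, gr)
        return vgrad, gr


def _matching_value_and_grads(source_vals, source_grid, v, affine, target_pts, J,
                              W_match, contrast, sigmaM, pixel_measure):
    """E_M and its exact gradients w.r.t. (v, homogeneous A) with W, contrast fixed.

    source_vals: (*spatial,) single source intensity channel on source_grid.
    target_pts: (m, d) point order; J: (C, m) target values; W_match: (m,).
    """
    d = source_grid.ndim
    tape = _PullbackTape(v, affine.inverse(), target_pts)
    qg = source_grid.to_grid_order(tape.q_final)
    s, ds = interp_grad(source_vals, source_grid.axes, qg)  # (m,), (m, d_gridorder)
    iperm = list(np.argsort(source_grid.perm))
    ds = ds[:, iperm]  # point order

    pred = contrast.apply(s)  # (C, m)
    resid = pred - J
    E = float((W_match * (resid ** 2).sum(axis=0)).sum() * pixel_measure / (2.0 * sigmaM**2))

    fprime = contrast.derivative(s)  # (C, m)
    gs = (W_match * (resid * fprime).sum(axis=0)) * (pixel_measure / sigmaM**2)  # (m,)
    gq = gs[:, None] * ds  # (m, d) point order

    vgrad, g_affine_pts = tape.backprop(gq)

    # q_affine = Ainv_L @ x + Ainv_T  ->  gradient w.r.t. homogeneous Ainv, then chain to A
    G = np.zeros((d + 1, d + 1))
    G[:d, :d] = g_affine_pts.T @ target_pts
    G[:d, d] = g_affine_pts.sum(axis=0)
    Minv = affine.inverse().matrix
    gA = -Minv.T @ G @ Minv.T
    return E, s, vgrad, gA


def _landmark_value_and_grads(v, affine, pointsI, pointsJ, sigmaP):
    d = affine.ndim
    tape = _ForwardTape(v, pointsI)
    moved = affine.apply(tape.r_final)
    diff = moved - pointsJ
    E = float((diff ** 2).sum() / (2.0 * sigmaP**2))
    gy = diff / sigmaP**2  # (m, d)
    gA = np.zeros((d + 1, d + 1))
    gA[:d, :d] = gy.T @ tape.r_final
    gA[:d, d] = gy.sum(axis=0)
    gr = gy @ affine.L
    vgrad, _ = tape.backprop(gr)
    return E, vgrad, gA


def _lddmm_core(source_vals, source_grid: GridAxes, target_pts, target_vals,
                pixel_measure: float, config: LDDMMConfig,
                target_shape=None) -> AlignmentResult:
    """Dimension-agnostic optimizer shared by 2D-2D and 3D-to-2D alignment."""
    d = source_grid.ndim
    nt, dt = config.nt, 1.0 / config.nt
    C = target_vals.shape[0]
    m = target_vals.shape[1]

    # initial affine: landmarks > explicit config > identity
    affine = config.initial_affine(d)
    if affine is None and config.pointsI is not None and config.pointsJ is not None:
        affine, _ = landmark_affine(config.pointsI, config.pointsJ)
    if affine is None:
        affine = AffineTransform.identity(d)
    L, T = affine.L.copy(), affine.T.copy()

    v = VelocityField.zeros(source_grid, nt=nt, a=config.a, p=config.p)
    LL = regularization_symbol(source_grid.axes, config.a, config.p)
    K = 1.0 / LL
    cell_v = float(np.prod(source_grid.spacing))
    spatial_axes = tuple(range(1, d + 1))

    muB = config.muB if config.muB is not None else _decile_means(target_vals, "low")
    muA = config.muA if config.muA is not None else _decile_means(target_vals, "high")

    contrast = ContrastModel.identity(C, config.contrast_degree)
    weights = None
    have_landmarks = config.pointsI is not None and config.pointsJ is not None
    trace = {"matching": [], "regularization": [], "landmark": [], "total": []}

    for it in range(config.niter):
        affine = AffineTransform(L, T)
        # current prediction for the E-step / contrast refit
        tape = _PullbackTape(v, affine.inverse(), target_pts)
        s = interp(source_vals, source_grid.axes, source_grid.to_grid_order(tape.q_final))
        if config.mixture:
            weights = gmm_posteriors(contrast.apply(s).reshape((C,) + (m,)), target_vals,
                                     sigmaM=config.sigmaM, sigmaB=config.sigmaB,
                                     sigmaA=config.sigmaA, muB=muB, muA=muA)
            W_match = weights.matching.ravel()
        else:
            W_match = np.ones(m)
        contrast = fit_contrast(s, target_vals, W_match, degree=config.contrast_degree)

        EM, s, vgrad_m, gA_m = _matching_value_and_grads(
            source_vals, source_grid, v, affine, target_pts, target_vals,
            W_match, contrast, config.sigmaM, pixel_measure)
        ER = regularization_energy(v, config.sigmaR)
        gA = gA_m
        vgrad = vgrad_m
        EP = 0.0
        if have_landmarks:
            EP, vgrad_l, gA_l = _landmark_value_and_grads(
                v, affine, np.asarray(config.pointsI, float),
                np.asarray(config.pointsJ, float), config.sigmaP)
            gA = gA + gA_l
            vgrad = vgrad + vgrad_l

        total = EM + ER + EP
        if not np.isfinite(total):
            raise RuntimeError(
                f"objective diverged (NaN/Inf) at iteration {it}; "
                f"reduce step sizes epL={config.epL}, epT={config.epT}, epV={config.epV}")
        trace["matching"].append(EM)
        trace["regularization"].append(ER)
        trace["landmark"].append(EP)
        trace["total"].append(total)

        T = T - config.epT * gA[:d, d]
        L = L - config.epL * gA[:d, :d]
        if it >= config.diffeo_start:
            ghat = np.fft.fftn(vgrad, axes=tuple(a + 1 for a in spatial_axes))
            smoothed = np.fft.ifftn(ghat * K, axes=tuple(a + 1 for a in spatial_axes)).real
            smoothed += (dt * cell_v / config.sigmaR**2) * v.values
            v = VelocityField(v.values - config.epV * smoothed, source_grid,
                              a=config.a, p=config.p)

    affine = AffineTransform(L, T)
    diffeo = DiffeoMap.from_velocity(affine, v)
    for key in trace:
        trace[key] = np.asarray(trace[key])
    if weights is not None and target_shape is not None:
        weights = MixtureWeights(weights.values.reshape((3,) + tuple(target_shape)))
    return AlignmentResult(diffeo=diffeo, trace=trace, weights=weights,
                           contrast=contrast, config=config)


def lddmm_align(source: RasterImage, target: RasterImage,
                config: Optional[LDDMMConfig] = None) -> AlignmentResult:
    """Solve the affine + LDDMM map aligning ``source`` onto ``target``.

    Both images are rasters in µm; the target is resampled onto the working
    ``config.dx`` grid if its pixel size differs, and both are rescaled to
    [0, 1] by their maxima when ``config.normalize`` is set (landmarks stay
    in physical µm).  Returns an :class:`AlignmentResult` whose map sends
    source cell coordinates into the target frame via ``transform_points``.
    """
    from .raster import resample_to_spacing

    config = config or LDDMMConfig()
    if not np.isclose(target.dx, config.dx):
        target = resample_to_spacing(target, config.dx)
    if config.normalize:
        source = source.normalized()
        target = target.normalized()

    source_grid = GridAxes.from_image(source)
    target_grid = GridAxes.from_image(target)
    gx, gy = np.meshgrid(target.col_coords, target.row_coords)
    target_pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    target_vals = target.values.reshape(target.n_channels, -1)

    result = _lddmm_core(source.values[0], source_grid, target_pts, target_vals,
                         pixel_measure=target.dx**2, config=config,
                         target_shape=target.values.shape[1:])
    result.target_grid = target_grid
    return result
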