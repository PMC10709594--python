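"""Objective components: energies, mixture, contrast, landmarks, gradients.

Each operation is checked against an independent brute-force oracle
(explicit operator matrices, per-pixel summation, per-pair arithmetic) and
the hand-derived adjoint gradients are checked against central finite
differences of the discrete objective.
"""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from stwarp.deform import AffineTransform, GridAxes, VelocityField
from stwarp.lddmm import (ContrastModel, LDDMMConfig, MixtureWeights,
                          _landmark_value_and_grads, _matching_value_and_grads,
                          fit_contrast, gmm_posteriors, landmark_affine,
                          landmark_energy, matching_energy,
                          regularization_energy)


from _oracles import periodic_operator_matrix

# ---------------------------------------------------------------------------
# regularization energy


@pytest.fixture
def grid16():
    return GridAxes([10.0 * (0.5 + np.arange(16)), 10.0 * (0.5 + np.arange(16))],
                    perm=(1, 0))


def test_regularization_zero_field(grid16):
    v = VelocityField.zeros(grid16, nt=3)
    assert regularization_energy(v, sigmaR=5e5) == 0.0


def test_regularization_quadratic_scaling(grid16, rng):
    vals = rng.standard_normal((2, 2, 16, 16))
    v1 = VelocityField(vals, grid16, a=40.0, p=2.0)
    v3 = VelocityField(3.0 * vals, grid16, a=40.0, p=2.0)
    assert regularization_energy(v3, 1e3) == pytest.approx(
        9.0 * regularization_energy(v1, 1e3), rel=1e-12)


def test_regularization_matches_operator_matrix_oracle(grid16, rng):
    a, p, sigmaR, dx = 35.0, 2.0, 1.0, 10.0
    vals = rng.standard_normal((2, 2, 16, 16))
    v = VelocityField(vals, grid16, a=a, p=p)
    Lmat = periodic_operator_matrix(16, 16, dx, a, p)
    total = 0.0
    for t in range(2):
        for c in range(2):
            Lv = Lmat @ vals[t, c].ravel()
            total += (Lv ** 2).sum() * dx * dx
    oracle = total * (1.0 / 2) / (2.0 * sigmaR**2)
    assert regularization_energy(v, sigmaR) == pytest.approx(oracle, rel=1e-6)


# ---------------------------------------------------------------------------
# Gaussian mixture posteriors

def test_equal_densities_give_uniform_posteriors():
    # predicted == muB == muA and equal sigmas: all three densities equal
    pred = np.full((1, 5), 0.4)
    targ = np.full((1, 5), 0.2)
    W = gmm_posteriors(pred, targ, sigmaM=1.0, sigmaB=1.0, sigmaA=1.0, muB=0.4, muA=0.4)
    np.testing.assert_allclose(W.values, 1.0 / 3.0, rtol=1e-12)


def test_exact_match_far_from_other_components():
    pred = np.array([[0.5]])
    targ = np.array([[0.5]])
    W = gmm_posteriors(pred, targ, sigmaM=0.05, sigmaB=0.05, sigmaA=0.05,
                       muB=0.5 - 6 * 0.05, muA=0.5 + 6 * 0.05)
    assert W.matching[0] >= 0.99
    # oracle: direct evaluation of the three Gaussian densities
    dens = [np.exp(-0.5 * ((0.5 - m) / 0.05) ** 2) / 0.05 for m in (0.5, 0.2, 0.8)]
    np.testing.assert_allclose(W.values[:, 0], np.array(dens) / sum(dens), rtol=1e-9)


def test_posteriors_sum_to_one_everywhere(rng):
    pred = rng.uniform(0, 1, (3, 50))
    targ = rng.uniform(0, 1, (3, 50))
    W = gmm_posteriors(pred, targ, sigmaM=0.3, sigmaB=0.2, sigmaA=0.4, muB=0.1, muA=0.9)
    np.testing.assert_allclose(W.values.sum(axis=0), 1.0, atol=1e-12)
    assert (W.values >= 0).all() and (W.values <= 1).all()


def test_mixture_weights_validate_simplex():
    with pytest.raises(ValueError):
        MixtureWeights(np.array([[0.5], [0.2], [0.2]]))


# ---------------------------------------------------------------------------
# contrast model

def test_contrast_exact_affine_recovery(rng):
    s = rng.uniform(0, 1, 200)
    target = (2.0 * s + 1.0)[None]
    model = fit_contrast(s, target, degree=1)
    np.testing.assert_allclose(model.coeffs, [[1.0, 2.0]], atol=1e-10)


def test_contrast_degree_zero_is_weighted_mean(rng):
    s = rng.uniform(0, 1, 50)
    target = rng.uniform(0, 2, 50)[None]
    w = rng.uniform(0, 3, 50)
    model = fit_contrast(s, target, weights=w, degree=0)
    assert model.coeffs[0, 0] == pytest.approx((w * target[0]).sum() / w.sum(), rel=1e-12)


def test_zero_weight_pixels_equivalent_to_deletion(rng):
    s = rng.uniform(0, 1, 80)
    target = (0.5 * s + 0.1 + 0.01 * rng.standard_normal(80))[None]
    w = np.ones(80)
    w[20:40] = 0.0  # corrupted block
    target_corrupt = target.copy()
    target_corrupt[0, 20:40] = 5.0
    full = fit_contrast(s, target_corrupt, weights=w, degree=1)
    reduced = fit_contrast(s[w > 0], target[:, w > 0], degree=1)
    np.testing.assert_allclose(full.coeffs, reduced.coeffs, atol=1e-9)


def test_constant_source_reduces_degree():
    s = np.full(30, 0.7)
    target = np.linspace(0, 1, 30)[None]
    with pytest.warns(UserWarning, match="rank-deficient"):
        model = fit_contrast(s, target, degree=1)
    assert model.reduced
    assert model.coeffs[0, 1] == 0.0  # higher order zeroed
    assert model.coeffs[0, 0] == pytest.approx(target.mean(), rel=1e-9)


# ---------------------------------------------------------------------------
# matching and landmark energies

def test_matching_energy_zero_for_perfect_match(rng):
    s = rng.uniform(0, 1, 16)
    f = ContrastModel.identity(1, 1)
    W = rng.uniform(0, 1, 16)
    assert matching_energy(s, s[None], W, f, sigmaM=0.5, pixel_measure=4.0) == 0.0


def test_matching_energy_linear_in_weights(rng):
    s = rng.uniform(0, 1, 16)
    J = rng.uniform(0, 1, (1, 16))
    f = ContrastModel.identity(1, 1)
    W = rng.uniform(0, 1, 16)
    full = matching_energy(s, J, W, f, 1.0, 9.0)
    half = matching_energy(s, J, 0.5 * W, f, 1.0, 9.0)
    assert half == pytest.approx(0.5 * full, rel=1e-12)


def test_matching_energy_matches_hand_sum():
    s = np.arange(16, dtype=float) / 16.0
    J = (s[::-1]).reshape(1, 16).copy()
    W = np.linspace(0.1, 1.0, 16)
    f = ContrastModel(np.array([[0.05, 1.1]]), 1)
    sigmaM, meas = 0.7, 2.5
    expected = sum(W[k] * (0.05 + 1.1 * s[k] - J[0, k]) ** 2 for k in range(16))
    expected *= meas / (2 * sigmaM**2)
    assert matching_energy(s, J, W, f, sigmaM, meas) == pytest.approx(expected, rel=1e-12)


def test_landmark_energy_examples(rng):
    aff = AffineTransform.identity(2)
    assert landmark_energy(aff, [[1.0, 2.0]], [[1.0, 2.0]], sigmaP=3.0) == 0.0
    # single pair offset by (3, 4), sigmaP = 1 -> 25/2
    assert landmark_energy(aff, [[0.0, 0.0]], [[3.0, 4.0]], sigmaP=1.0) == pytest.approx(12.5)
    pI = rng.uniform(0, 100, (7, 2))
    pJ = rng.uniform(0, 100, (7, 2))
    oracle = sum(np.sum((pI[i] - pJ[i]) ** 2) for i in range(7)) / (2 * 4.0**2)
    assert landmark_energy(aff, pI, pJ, sigmaP=4.0) == pytest.approx(oracle, rel=1e-12)


def test_landmark_energy_length_mismatch():
    with pytest.raises(ValueError, match="equal length"):
        landmark_energy(AffineTransform.identity(2), [[0.0, 0.0]],
                        [[1.0, 1.0], [2.0, 2.0]])


# ---------------------------------------------------------------------------
# landmark affine

def test_landmark_affine_identity():
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    aff, rmse = landmark_affine(pts, pts)
    np.testing.assert_allclose(aff.L, np.eye(2), atol=1e-12)
    np.testing.assert_allclose(aff.T, 0.0, atol=1e-12)
    assert rmse == pytest.approx(0.0, abs=1e-12)


def test_landmark_affine_recovers_rotation(rng):
    rot = np.array([[0.0, -1.0], [1.0, 0.0]])
    T = np.array([5.0, -2.0])
    pI = rng.uniform(-50, 50, (6, 2))
    pJ = pI @ rot.T + T
    aff, rmse = landmark_affine(pI, pJ)
    np.testing.assert_allclose(aff.L, rot, atol=1e-10)
    np.testing.assert_allclose(aff.T, T, atol=1e-9)
    np.testing.assert_allclose(aff.apply(pI), pJ, atol=1e-9)
    assert rmse < 1e-9


def test_landmark_affine_degenerate_inputs():
    with pytest.raises(np.linalg.LinAlgError):
        landmark_affine([[0.0, 0.0], [1.0, 1.0]], [[0.0, 0.0], [2.0, 2.0]])
    collinear = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
    with pytest.raises(np.linalg.LinAlgError):
        landmark_affine(collinear, collinear)


# ---------------------------------------------------------------------------
# gradient adjoints vs finite differences

@pytest.fixture
def small_problem(rng):
    rows = 10.0 * (0.5 + np.arange(9))
    cols = 10.0 * (0.5 + np.arange(8))
    grid = GridAxes([rows, cols], perm=(1, 0))
    vals = np.stack([
        np.stack([gaussian_filter(rng.standard_normal(grid.shape), 2.0) * 8.0
                  for _ in range(2)]) for _ in range(2)])
    v = VelocityField(vals, grid, a=50.0)
    aff = AffineTransform(np.eye(2) + 0.05 * rng.standard_normal((2, 2)),
                          3.0 * rng.standard_normal(2))
    src = gaussian_filter(rng.standard_normal(grid.shape), 1.5)
    tp = np.column_stack([rng.uniform(15, 60, 40), rng.uniform(15, 75, 40)])
    J = rng.standard_normal((1, 40))
    W = rng.uniform(0.2, 1.0, 40)
    con = ContrastModel(np.array([[0.1, 1.2]]), 1)
    return grid, v, aff, src, tp, J, W, con


def test_matching_gradients_match_finite_differences(small_problem, rng):
    grid, v, aff, src, tp, J, W, con = small_problem
    sigmaM, meas = 0.8, 100.0

    def energy(vals, L, T):
        vv = VelocityField(vals, grid, a=50.0)
        E, *_ = _matching_value_and_grads(src, grid, vv, AffineTransform(L, T),
                                          tp, J, W, con, sigmaM, meas)
        return E

    _, _, vgrad, gA = _matching_value_and_grads(src, grid, v, aff, tp, J, W,
                                                con, sigmaM, meas)
    eps = 1e-5
    for _ in range(10):
        t, c = rng.integers(2), rng.integers(2)
        i, j = rng.integers(9), rng.integers(8)
        vp, vm = v.values.copy(), v.values.copy()
        vp[t, c, i, j] += eps
        vm[t, c, i, j] -= eps
        fd = (energy(vp, aff.L, aff.T) - energy(vm, aff.L, aff.T)) / (2 * eps)
        assert vgrad[t, c, i, j] == pytest.approx(fd, rel=1e-4, abs=1e-10)
    for i in range(2):
        for j in range(3):
            Lp, Lm = aff.L.copy(), aff.L.copy()
            Tp, Tm = aff.T.copy(), aff.T.copy()
            if j < 2:
                Lp[i, j] += eps
                Lm[i, j] -= eps
            else:
                Tp[i] += eps
                Tm[i] -= eps
            fd = (energy(v.values, Lp, Tp) - energy(v.values, Lm, Tm)) / (2 * eps)
            an = gA[i, j] if j < 2 else gA[i, 2]
            assert an == pytest.approx(fd, rel=1e-5, abs=1e-10)


def test_landmark_gradients_match_finite_differences(small_problem, rng):
    grid, v, aff, *_ = small_problem
    pI = np.column_stack([rng.uniform(15, 60, 5), rng.uniform(15, 75, 5)])
    pJ = pI + 5.0 * rng.standard_normal((5, 2))

    def energy(vals, L, T):
        vv = VelocityField(vals, grid, a=50.0)
        E, _, _ = _landmark_value_and_grads(vv, AffineTransform(L, T), pI, pJ, 2.0)
        return E

    _, vgrad, gA = _landmark_value_and_grads(v, aff, pI, pJ, 2.0)
    eps = 1e-5
    for _ in range(8):
        t, c = rng.integers(2), rng.integers(2)
        i, j = rng.integers(9), rng.integers(8)
        vp, vm = v.values.copy(), v.values.copy()
        vp[t, c, i, j] += eps
        vm[t, c, i, j] -= eps
        fd = (energy(vp, aff.L, aff.T) - energy(vm, aff.L, aff.T)) / (2 * eps)
        assert vgrad[t, c, i, j] == pytest.approx(fd, rel=1e-5, abs=1e-10)
    for i in range(2):
        Tp, Tm = aff.T.copy(), aff.T.copy()
        Tp[i] += eps
        Tm[i] -= eps
        fd = (energy(v.values, aff.L, Tp) - energy(v.values, aff.L, Tm)) / (2 * eps)
        assert gA[i, 2] == pytest.approx(fd, rel=1e-6)


# ---------------------------------------------------------------------------
# config validation

def test_config_rejects_both_LT_and_A():
    with pytest.raises(ValueError, match="not both"):
        LDDMMConfig(L=np.eye(2), A=np.eye(3))


def test_config_rejects_nonpositive_sigmas():
    with pytest.raises(ValueError):
        LDDMMConfig(sigmaM=0.0)
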