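"""Regularisation terms against brute-force oracles and closed forms."""

import numpy as np
import pytest
from scipy.ndimage import convolve

from hsdemosaic import (
    LossConfig,
    combined_regularisation,
    gradient_consistency_loss,
    gradient_correlation_term,
    mrae_loss,
    spatial_gradients,
    tikhonov_loss,
    tv_loss,
)
from hsdemosaic.autodiff import Tensor


def pearson_oracle(u, v):
    u = u.ravel() - u.mean()
    v = v.ravel() - v.mean()
    return float((u * v).mean() / (u.std() * v.std() + 1e-8))


class TestSpatialGradients:
    def test_constant_band_zero(self):
        gx, gy = spatial_gradients(np.full((5, 5, 2), 3.0))
        assert np.all(gx == 0) and np.all(gy == 0)

    def test_row_ramp_closed_form(self):
        cube = np.tile(np.arange(6.0)[:, None, None], (1, 4, 2))
        gx, gy = spatial_gradients(cube)
        assert np.all(gx == 1.0) and np.all(gy == 0.0)

    def test_matches_loop_oracle(self, rng):
        cube = rng.random((5, 5, 1))
        gx, gy = spatial_gradients(cube)
        for x in range(4):
            for y in range(5):
                assert gx[x, y, 0] == cube[x + 1, y, 0] - cube[x, y, 0]
        for x in range(5):
            for y in range(4):
                assert gy[x, y, 0] == cube[x, y + 1, 0] - cube[x, y, 0]

    def test_single_pixel_dim_rejected(self):
        with pytest.raises(ValueError):
            spatial_gradients(np.ones((1, 5, 2)))


class TestGradientCorrelation:
    def test_positive_affine_gives_minus_two(self, rng):
        base = rng.random((6, 6))
        cube = np.stack([base, 3.0 * base + 0.5], axis=-1)
        assert np.isclose(gradient_correlation_term(cube, 0, 1), -2.0, atol=1e-5)

    def test_negated_band_gives_plus_two(self, rng):
        base = rng.random((6, 6))
        cube = np.stack([base, -base], axis=-1)
        assert np.isclose(gradient_correlation_term(cube, 0, 1), 2.0, atol=1e-5)

    def test_matches_pearson_oracle(self, rng):
        cube = rng.random((6, 6, 2))
        gx, gy = spatial_gradients(cube)
        expected = -pearson_oracle(gx[:, :, 0], gx[:, :, 1]) - pearson_oracle(
            gy[:, :, 0], gy[:, :, 1]
        )
        assert np.isclose(gradient_correlation_term(cube, 0, 1), expected, atol=1e-10)

    def test_constant_band_degenerate_is_zero(self, rng):
        cube = np.stack([np.full((5, 5), 2.0), rng.random((5, 5))], axis=-1)
        assert gradient_correlation_term(cube, 0, 1) == 0.0

    def test_bounded(self, rng):
        for _ in range(5):
            cube = rng.random((5, 7, 3))
            v = gradient_correlation_term(cube, 0, 2)
            assert -2.0 <= v <= 2.0


class TestGradientConsistency:
    def test_identical_bands_unit_weights(self, rng):
        C = 4
        cube = np.repeat(rng.random((6, 6, 1)), C, axis=2)
        loss = gradient_consistency_loss(cube, np.ones((C, C)))
        assert np.isclose(loss, -2.0 * C * (C - 1), rtol=1e-5)

    def test_zero_offdiagonal_weights(self, rng):
        cube = rng.random((6, 6, 3))
        assert gradient_consistency_loss(cube, np.eye(3)) == 0.0

    def test_matches_pair_loop_oracle(self, rng):
        cube = rng.random((6, 6, 3))
        W = rng.random((3, 3))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        expected = sum(
            W[a, b] * gradient_correlation_term(cube, a, b)
            for a in range(3)
            for b in range(3)
            if a != b
        )
        assert np.isclose(gradient_consistency_loss(cube, W), expected, atol=1e-10)

    def test_weight_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="match"):
            gradient_consistency_loss(rng.random((5, 5, 3)), np.ones((4, 4)))

    def test_affine_rescale_invariance(self, rng):
        cube = rng.random((6, 6, 3))
        scaled = cube * np.array([2.0, 5.0, 0.3]) + np.array([1.0, -0.2, 4.0])
        W = np.ones((3, 3))
        assert np.isclose(
            gradient_consistency_loss(cube, W),
            gradient_consistency_loss(scaled, W),
            atol=1e-6,
        )


class TestTikhonov:
    def test_constant_zero(self):
        assert tikhonov_loss(np.full((5, 5, 3), 2.0)) == 0.0

    def test_plane_is_harmonic(self):
        x, y = np.meshgrid(np.arange(7.0), np.arange(7.0), indexing="ij")
        cube = (x + 2 * y)[:, :, None]
        assert np.isclose(tikhonov_loss(cube), 0.0, atol=1e-20)

    def test_matches_convolution_oracle(self, rng):
        cube = rng.random((7, 7, 2))
        k = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
        lap = np.stack(
            [convolve(cube[:, :, c], k)[1:-1, 1:-1] for c in range(2)], axis=-1
        )
        assert np.isclose(tikhonov_loss(cube), (lap**2).mean(), atol=1e-12)

    def test_shift_invariance(self, rng):
        cube = rng.random((7, 7, 2))
        assert np.isclose(tikhonov_loss(cube), tikhonov_loss(cube + 10.0), atol=1e-10)


class TestTV:
    def test_constant_zero(self):
        assert tv_loss(np.full((4, 4, 2), 1.5)) == 0.0

    def test_row_ramp_closed_form(self):
        cube = np.tile(np.arange(8.0)[:, None, None], (1, 6, 1))
        assert np.isclose(tv_loss(cube), 1.0)

    def test_matches_loop_oracle(self, rng):
        cube = rng.random((6, 5, 3))
        gx = np.abs(cube[1:] - cube[:-1]).mean()
        gy = np.abs(cube[:, 1:] - cube[:, :-1]).mean()
        assert np.isclose(tv_loss(cube), gx + gy, atol=1e-12)

    def test_shift_invariance(self, rng):
        cube = rng.random((6, 6, 2))
        assert np.isclose(tv_loss(cube), tv_loss(cube - 3.0), atol=1e-12)


class TestCombined:
    def test_all_zero_lambdas(self, rng):
        cfg = LossConfig(lambda_tik=0.0, lambda_tv=0.0, lambda_rho=0.0)
        total, terms = combined_regularisation(rng.random((6, 6, 3)), np.ones((3, 3)), cfg)
        assert total == 0.0
        assert set(terms) == {"tikhonov", "tv", "gradient_consistency"}

    def test_default_lambdas_equal_hand_sum(self, rng):
        cube = rng.random((7, 7, 3))
        W = np.ones((3, 3))
        cfg = LossConfig()
        total, terms = combined_regularisation(cube, W, cfg)
        expected = (
            1.0 * tikhonov_loss(cube)
            + 1e-3 * tv_loss(cube)
            + 1.0 * gradient_consistency_loss(cube, W, cfg.eps)
        )
        assert np.isclose(total, expected, atol=1e-12)

    @pytest.mark.parametrize("active", ["lambda_tik", "lambda_tv", "lambda_rho"])
    def test_single_term_recovered(self, rng, active):
        cube = rng.random((6, 6, 2))
        W = np.ones((2, 2))
        kwargs = {"lambda_tik": 0.0, "lambda_tv": 0.0, "lambda_rho": 0.0, active: 2.0}
        cfg = LossConfig(**kwargs)
        total, terms = combined_regularisation(cube, W, cfg)
        name = {"lambda_tik": "tikhonov", "lambda_tv": "tv", "lambda_rho": "gradient_consistency"}[active]
        assert np.isclose(total, 2.0 * terms[name], atol=1e-12)

    def test_descent_decreases_loss(self, rng):
        """Plain gradient descent on a noisy cube lowers the combined loss."""
        from hsdemosaic.training import Adam

        cube = Tensor(rng.random((12, 12, 4)), requires_grad=True)
        W = np.ones((4, 4)) * 0.5
        np.fill_diagonal(W, 1.0)
        cfg = LossConfig()
        first = None
        opt = Adam([cube], lr=1e-3)
        for _ in range(100):
            total, _ = combined_regularisation(cube, W, cfg)
            if first is None:
                first = float(total.data)
            opt.zero_grad()
            total.backward()
            opt.step()
        final, _ = combined_regularisation(cube, W, cfg)
        assert float(final.data) < first


class TestMRAE:
    def test_identical_zero(self, rng):
        cube = rng.random((5, 5, 3))
        assert mrae_loss(cube, cube) == 0.0

    def test_constant_closed_form(self):
        pred = np.full((4, 4, 2), 1.1)
        truth = np.ones((4, 4, 2))
        assert np.isclose(mrae_loss(pred, truth), 0.1 / (1 + 1e-6), atol=1e-9)

    def test_matches_voxel_loop_oracle(self, rng):
        pred = rng.random((4, 5, 2))
        truth = rng.random((4, 5, 2))
        expected = np.mean(np.abs(pred - truth) / (np.abs(truth) + 1e-6))
        assert np.isclose(mrae_loss(pred, truth), expected, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            mrae_loss(rng.random((4, 4, 2)), rng.random((4, 4, 3)))


def test_edge_alignment_improves_under_consistency_descent(rng):
    """Descending the negative-correlation term drags a misaligned band's
    edge toward the reference band's edge position."""
    from hsdemosaic.training import Adam

    X = 16
    ref = np.zeros((X, X))
    ref[:, 8:] = 1.0  # sharp vertical edge at column 8
    shifted = np.zeros((X, X))
    shifted[:, 10:] = 1.0  # same edge two columns off
    cube = Tensor(np.stack([ref, shifted], axis=-1), requires_grad=True)
    W = np.ones((2, 2))
    ref_const = cube.data[:, :, 0].copy()

    def misalignment():
        prof = np.abs(np.diff(cube.data[:, :, 1], axis=1)).mean(axis=0)
        return float(np.abs(np.argmax(prof) - 7))

    before = gradient_consistency_loss(cube, W).data
    opt = Adam([cube], lr=5e-3)
    for _ in range(200):
        loss = gradient_consistency_loss(cube, W)
        opt.zero_grad()
        loss.backward()
        cube.grad[:, :, 0] = 0.0  # hold the reference band fixed
        opt.step()
        cube.data[:, :, 0] = ref_const
    after = gradient_consistency_loss(cube, W).data
    assert after < before
    assert misalignment() <= 1.0
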