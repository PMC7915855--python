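import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nirvein.rtv import (
    RTVParams,
    gaussian_kernel,
    gaussian_weight,
    partials,
    rtv_objective,
    rtv_smooth,
    windowed_variation,
)
from oracles import rtv_energy_naive, window_matrix

small_images = arrays(
    np.float64,
    (8, 8),
    elements=st.floats(0.0, 1.0, allow_nan=False, width=64),
)


class TestGaussianWeight:
    def test_zero_offset_is_one(self):
        for h in (0.5, 2.5, 10.0):
            assert gaussian_weight(0, 0, h) == 1.0

    def test_characteristic_distance(self):
        # squared distance 2h^2 evaluates to exp(-1)
        h = 2.5
        dx = math.sqrt(2) * h
        assert gaussian_weight(dx, 0, h) == pytest.approx(math.exp(-1), abs=1e-12)
        assert gaussian_weight(h, h, h) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_symmetry(self):
        assert gaussian_weight(1.5, -2.0, 2.5) == gaussian_weight(-1.5, 2.0, 2.5)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            gaussian_weight(0, 0, 0.0)
        with pytest.raises(ValueError):
            gaussian_kernel(-1.0)

    def test_kernel_truncation_radius(self):
        K = gaussian_kernel(2.5)
        assert K.shape == (17, 17)  # ceil(3 * 2.5) = 8
        assert K[8, 8] == 1.0  # unnormalized: peak exactly 1


class TestPartials:
    def test_constant_image(self):
        gx, gy = partials(np.full((5, 7), 0.3))
        assert not gx.any() and not gy.any()

    def test_vertical_step(self):
        I = np.zeros((4, 6))
        I[:, 3:] = 1.0
        gx, gy = partials(I)
        assert (gx[:, 2] == 1.0).all()
        assert gx.sum() == 4.0  # only the step column
        assert not gy.any()

    def test_matches_elementwise_definition(self):
        rng = np.random.default_rng(3)
        S = rng.uniform(size=(4, 4))
        gx, gy = partials(S)
        for i in range(4):
            for j in range(4):
                ex = S[i, j + 1] - S[i, j] if j < 3 else 0.0
                ey = S[i + 1, j] - S[i, j] if i < 3 else 0.0
                assert gx[i, j] == pytest.approx(ex, abs=1e-15)
                assert gy[i, j] == pytest.approx(ey, abs=1e-15)


class TestWindowedVariation:
    def test_constant_image_all_zero(self):
        maps = windowed_variation(np.full((10, 10), 0.7), h=2.5)
        for m in (maps.Dx, maps.Dy, maps.Lx, maps.Ly):
            assert not m.any()

    @given(small_images)
    @settings(max_examples=30, deadline=None)
    def test_inherent_never_exceeds_total(self, I):
        """Triangle inequality: |sum rho*g| <= sum rho*|g| pixel-wise."""
        maps = windowed_variation(I, h=2.5)
        assert (maps.Lx <= maps.Dx + 1e-12).all()
        assert (maps.Ly <= maps.Dy + 1e-12).all()

    def test_pure_texture_cancels_inherent_variation(self):
        # Alternating +-delta columns: gradients alternate sign, so the
        # windowed signed sum nearly cancels while the absolute sum does not.
        delta = 0.1
        I = np.tile(np.array([0.4, 0.4 + delta]), (16, 8))
        maps = windowed_variation(I, h=2.5)
        interior = (slice(4, 12), slice(4, 12))
        ratio = maps.Lx[interior] / maps.Dx[interior]
        assert ratio.max() < 0.1
        # Dx itself matches the direct summation oracle
        M = window_matrix(I.shape, 2.5)
        gx, _ = partials(I)
        Dx_naive = (M @ np.abs(gx).ravel()).reshape(I.shape)
        np.testing.assert_allclose(maps.Dx, Dx_naive, rtol=1e-10)


class TestObjective:
    def test_zero_at_fixpoint_constant(self):
        I = np.full((8, 8), 0.5)
        assert rtv_objective(I, I, RTVParams(lam=0.02)) == 0.0

    def test_lambda_zero_is_sum_of_squares(self):
        rng = np.random.default_rng(0)
        I = rng.uniform(size=(6, 6))
        S = rng.uniform(size=(6, 6))
        assert rtv_objective(S, I, RTVParams(lam=0.0)) == pytest.approx(
            ((S - I) ** 2).sum(), rel=1e-14
        )

    def test_matches_naive_summation(self):
        rng = np.random.default_rng(12)
        I = rng.uniform(size=(8, 8))
        S = np.clip(I + 0.05 * rng.standard_normal((8, 8)), 0, 1)
        ours = rtv_objective(S, I, RTVParams(lam=0.01, h=2.5, eps=1e-5))
        ref = rtv_energy_naive(S, I, lam=0.01, h=2.5, eps=1e-5)
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rtv_objective(np.zeros((4, 4)), np.zeros((4, 5)), RTVParams())


class TestSmooth:
    def test_lambda_zero_returns_input_exactly(self):
        rng = np.random.default_rng(1)
        I = rng.uniform(size=(12, 12))
        np.testing.assert_array_equal(rtv_smooth(I, RTVParams(lam=0.0)), I)

    def test_constant_input_is_fixed_point(self):
        I = np.full((16, 16), 0.42)
        S = rtv_smooth(I, RTVParams(lam=0.05))
        np.testing.assert_allclose(S, I, atol=1e-10)

    def test_identity_limit_small_lambda(self):
        rng = np.random.default_rng(2)
        I = rng.uniform(size=(16, 16))
        S = rtv_smooth(I, RTVParams(lam=1e-12))
        assert np.abs(S - I).max() < 1e-6

    def test_gray_shift_equivariance(self):
        rng = np.random.default_rng(4)
        I = rng.uniform(0.1, 0.6, size=(16, 16))
        c = 0.25
        S0 = rtv_smooth(I, RTVParams(lam=1e-3))
        S1 = rtv_smooth(I + c, RTVParams(lam=1e-3))
        assert np.abs(S1 - (S0 + c)).max() < 1e-8

    @pytest.mark.parametrize("lam", [1e-3, 1e-2, 1e-1])
    def test_energy_never_increases(self, lam, small_phantom):
        (nir, _, _), _ = small_phantom
        params = RTVParams(lam=lam)
        S = rtv_smooth(nir, params)
        assert rtv_objective(S, nir, params) <= rtv_objective(nir, nir, params)

    def test_texture_suppressed_edge_preserved(self):
        """Flat-region variance drops >= 90% while the step survives >= 80%."""
        rng = np.random.default_rng(7)
        from scipy.ndimage import gaussian_filter

        I = np.full((64, 64), 0.3)
        I[:, 32:] = 0.7
        tex = gaussian_filter(rng.standard_normal((64, 64)), 1.0, mode="wrap")
        I = np.clip(I + 0.05 * tex / tex.std(), 0, 1)
        S = rtv_smooth(I, RTVParams())
        left, right = (slice(None), slice(4, 28)), (slice(None), slice(36, 60))
        assert S[left].var() <= 0.1 * I[left].var()
        step_in = I[right].mean() - I[left].mean()
        step_out = S[right].mean() - S[left].mean()
        assert step_out >= 0.8 * step_in

    def test_energy_trace_logged(self, step_texture_16):
        S, trace = rtv_smooth(step_texture_16, RTVParams(lam=1e-3, n_iters=4), return_trace=True)
        assert len(trace) == 4
        assert all(np.isfinite(trace))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RTVParams(lam=-1.0)
        with pytest.raises(ValueError):
            RTVParams(h=0.0)
        with pytest.raises(ValueError):
            RTVParams(eps=0.0)
        with pytest.raises(ValueError):
            RTVParams(n_iters=0)
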