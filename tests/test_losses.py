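import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctdenoise import (
    FilterKind,
    HybridConfig,
    WeightConfig,
    compute_patch_weights,
    dft2,
    hf_loss,
    hf_loss_grad,
    highpass_image,
    hybrid_loss,
    hybrid_loss_grad,
    idft2,
    make_highpass_mask,
    partition_patches,
    wp_loss,
    wp_loss_grad,
    wp_loss_with_weights,
)
from conftest import naive_dft2, naive_hf_loss


def make_patch_mae_image(maes, grid=(2, 2), patch=(4, 4)):
    """Image pair whose per-patch MAEs are exactly ``maes``."""
    h, w = grid[0] * patch[0], grid[1] * patch[1]
    target = np.zeros((h, w))
    gen = np.zeros((h, w))
    k = 0
    for r in range(grid[0]):
        for c in range(grid[1]):
            gen[r * patch[0] : (r + 1) * patch[0], c * patch[1] : (c + 1) * patch[1]] = maes[k]
            k += 1
    return gen, target


class TestPartition:
    def test_tiling_counts_and_shapes(self):
        g = np.zeros((224, 224))
        pairs = partition_patches(g, g, WeightConfig(4, 4))
        assert len(pairs) == 16
        assert all(p[0].shape == (56, 56) for p in pairs)

    def test_small_grid(self):
        g = np.zeros((8, 8))
        pairs = partition_patches(g, g, WeightConfig(2, 2))
        assert len(pairs) == 4 and pairs[0][0].shape == (4, 4)

    def test_tiles_cover_image_exactly_once(self, rng):
        g = rng.standard_normal((12, 16))
        pairs = partition_patches(g, g, WeightConfig(3, 4))
        reassembled = np.block(
            [[pairs[r * 4 + c][0] for c in range(4)] for r in range(3)]
        )
        np.testing.assert_array_equal(reassembled, g)

    def test_non_divisible_rejected(self):
        g = np.zeros((9, 9))
        with pytest.raises(ValueError, match="divisible"):
            partition_patches(g, g, WeightConfig(2, 2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            partition_patches(np.zeros((8, 8)), np.zeros((8, 12)), WeightConfig(2, 2))


class TestPatchWeights:
    @pytest.mark.parametrize(
        "losses,expected",
        [
            ([1, 2, 3, 4], [0.4, 0.8, 1.2, 1.6]),       # median 2.5, clamp inactive
            ([5, 5, 5, 5], [1, 1, 1, 1]),               # equal losses
            ([0.1, 10, 10, 10], [0.25, 1, 1, 1]),       # 0.01 clamped up
            ([0, 0, 0, 0], [1, 1, 1, 1]),               # degenerate zero median
        ],
    )
    def test_median_normalized_clamped_weights(self, losses, expected):
        np.testing.assert_allclose(compute_patch_weights(losses), expected)

    def test_negative_losses_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_patch_weights([1.0, -0.1, 2.0, 3.0])

    def test_invalid_clamp_rejected(self):
        with pytest.raises(ValueError, match="w_min"):
            WeightConfig(w_min=2.0, w_max=1.5)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=64,
        )
    )
    def test_clamp_and_degeneracy_invariants(self, losses):
        w = compute_patch_weights(losses)
        assert np.all(w >= 0.25 - 1e-12) and np.all(w <= 4.0 + 1e-12)
        if len(set(losses)) == 1:
            np.testing.assert_array_equal(w, 1.0)

    def test_unclamped_weight_conservation(self, rng):
        # mean(w_i * median) == mean(l_i) when the clamp is inactive
        losses = rng.uniform(0.5, 2.0, size=10)
        w = compute_patch_weights(losses, WeightConfig(w_min=1e-9, w_max=1e9))
        assert np.mean(w * np.median(losses)) == pytest.approx(np.mean(losses))


class TestWPLoss:
    def test_identical_images_zero_loss_unit_weights(self, rng):
        g = rng.standard_normal((8, 8))
        value, grid = wp_loss(g, g, WeightConfig(2, 2))
        assert value == 0.0
        np.testing.assert_array_equal(grid.weights, 1.0)

    def test_uniform_offset_gives_n_times_offset(self, rng):
        t = rng.standard_normal((16, 16))
        d = 0.37
        value, grid = wp_loss(t + d, t, WeightConfig(4, 4))
        np.testing.assert_allclose(grid.weights, 1.0)
        assert value == pytest.approx(16 * d)

    def test_worked_fixture_totals_twelve(self):
        gen, target = make_patch_mae_image([1, 2, 3, 4])
        value, grid = wp_loss(gen, target, WeightConfig(2, 2))
        np.testing.assert_allclose(grid.patch_losses, [1, 2, 3, 4])
        np.testing.assert_allclose(grid.weights, [0.4, 0.8, 1.2, 1.6])
        assert value == pytest.approx(12.0)

    def test_single_patch_error_increase_raises_loss(self):
        # keep clamp inactive and the median fixed while one patch worsens
        base = [1.0, 2.0, 3.0, 4.0]
        worse = [1.0, 2.0, 3.0, 4.5]
        cfg = WeightConfig(2, 2)
        v0, _ = wp_loss(*make_patch_mae_image(base), cfg)
        v1, _ = wp_loss(*make_patch_mae_image(worse), cfg)
        assert v1 > v0


class TestDFT:
    def test_constant_image_concentrates_at_dc(self):
        F = dft2(np.full((6, 4), 3.0))
        assert F[0, 0] == pytest.approx(72.0)
        F[0, 0] = 0
        np.testing.assert_allclose(np.abs(F), 0.0, atol=1e-9)

    def test_two_by_two_worked_example(self):
        F = dft2(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(F, [[10, -2], [-4, 0]], atol=1e-12)

    def test_matches_naive_double_sum(self, rng):
        f = rng.standard_normal((5, 7))
        np.testing.assert_allclose(dft2(f), naive_dft2(f), atol=1e-9)

    def test_inversion_identity(self, rng):
        f = rng.standard_normal((16, 16))
        np.testing.assert_allclose(np.real(idft2(dft2(f))), f, atol=1e-9)


class TestHighpassMask:
    def test_r0_zero_removes_only_dc(self):
        mask = make_highpass_mask((8, 8), 0.0).mask
        assert mask[0, 0] == 0.0
        assert mask.sum() == 63

    def test_saturating_cutoff_zeroes_everything(self, rng):
        from ctdenoise.losses import make_highpass_mask as mk

        mask = mk((8, 8), 0.71, _allow_large_cutoff=True)
        assert mask.mask.sum() == 0.0
        np.testing.assert_allclose(highpass_image(rng.standard_normal((8, 8)), mask), 0.0)

    def test_ideal_mask_matches_radius_enumeration(self):
        # enumerate all 16 centered radii of a 4x4 grid by hand
        mask = make_highpass_mask((4, 4), 0.25).mask
        freqs = [0.0, 0.25, -0.5, -0.25]
        for u in range(4):
            for v in range(4):
                rho = np.hypot(freqs[u], freqs[v])
                assert mask[u, v] == (1.0 if rho > 0.25 else 0.0)

    def test_mask_symmetric_under_negation(self):
        for kind in (FilterKind.IDEAL, FilterKind.GAUSSIAN):
            m = make_highpass_mask((6, 8), 0.2, kind).mask
            np.testing.assert_allclose(m, m[(-np.arange(6)) % 6][:, (-np.arange(8)) % 8])

    def test_out_of_range_cutoff_rejected(self):
        with pytest.raises(ValueError):
            make_highpass_mask((8, 8), 0.6)

    def test_gaussian_mask_zero_dc_and_bounded(self):
        m = make_highpass_mask((8, 8), 0.15, FilterKind.GAUSSIAN).mask
        assert m[0, 0] == 0.0
        assert 0.0 <= m.min() and m.max() <= 1.0


class TestHighpassImage:
    def test_constant_image_maps_to_zero(self):
        mask = make_highpass_mask((8, 8), 0.0)
        np.testing.assert_allclose(highpass_image(np.full((8, 8), 5.0), mask), 0.0, atol=1e-10)

    def test_dc_offset_invariance(self, rng):
        mask = make_highpass_mask((8, 8), 0.2)
        x = rng.standard_normal((8, 8))
        np.testing.assert_allclose(
            highpass_image(x + 7.3, mask), highpass_image(x, mask), atol=1e-10
        )

    def test_impulse_matches_brute_force(self):
        from conftest import naive_idft2

        imp = np.zeros((8, 8))
        imp[0, 0] = 1.0
        mask = make_highpass_mask((8, 8), 0.2)
        expected = np.real(naive_idft2(mask.mask * naive_dft2(imp)))
        np.testing.assert_allclose(highpass_image(imp, mask), expected, atol=1e-9)

    def test_output_mean_is_zero(self, rng):
        mask = make_highpass_mask((12, 12), 0.1)
        out = highpass_image(rng.standard_normal((12, 12)), mask)
        assert abs(out.mean()) < 1e-12

    def test_shape_mismatch_rejected(self):
        mask = make_highpass_mask((8, 8), 0.1)
        with pytest.raises(ValueError, match="shape"):
            highpass_image(np.zeros((8, 10)), mask)


class TestHFLoss:
    def test_identical_and_offset_pairs_cost_nothing(self, rng):
        mask = make_highpass_mask((8, 8), 0.2)
        x = rng.standard_normal((8, 8))
        assert hf_loss(x, x, mask) == 0.0
        assert hf_loss(x + 7.3, x, mask) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_nonnegativity(self, rng):
        mask = make_highpass_mask((8, 8), 0.2)
        for _ in range(10):
            a, b = rng.standard_normal((2, 8, 8))
            v = hf_loss(a, b, mask)
            assert v >= 0
            assert v == pytest.approx(hf_loss(b, a, mask), rel=1e-12)

    def test_matches_naive_oracle(self, rng):
        mask = make_highpass_mask((8, 8), 0.2)
        for _ in range(5):
            a, b = rng.standard_normal((2, 8, 8))
            assert hf_loss(a, b, mask) == pytest.approx(
                naive_hf_loss(a, b, mask.mask), abs=1e-9
            )


class TestHybrid:
    def test_single_term_limits(self, rng):
        a, b = rng.standard_normal((2, 8, 8))
        wp_only = hybrid_loss(a, b, HybridConfig(alpha1=2.0, alpha2=0.0, weight_config=WeightConfig(2, 2)))
        assert wp_only.hybrid_loss == pytest.approx(2.0 * wp_only.wp_loss)
        hf_only = hybrid_loss(a, b, HybridConfig(alpha1=0.0, alpha2=3.0, weight_config=WeightConfig(2, 2)))
        assert hf_only.hybrid_loss == pytest.approx(3.0 * hf_only.hf_loss)

    def test_decomposition_over_random_alphas(self, rng):
        a, b = rng.standard_normal((2, 8, 8))
        for _ in range(20):
            a1, a2 = rng.uniform(0, 5, 2)
            if a1 + a2 == 0:
                continue
            cfg = HybridConfig(alpha1=a1, alpha2=a2, weight_config=WeightConfig(2, 2))
            rep = hybrid_loss(a, b, cfg)
            assert rep.hybrid_loss == pytest.approx(a1 * rep.wp_loss + a2 * rep.hf_loss, rel=1e-15, abs=1e-15)

    def test_positive_homogeneity(self, rng):
        a, b = rng.standard_normal((2, 8, 8))
        cfg = HybridConfig(weight_config=WeightConfig(2, 2))
        base = hybrid_loss(a, b, cfg).hybrid_loss
        for scale in (0.1, 2.0, 17.0):
            scaled = hybrid_loss(scale * a, scale * b, cfg).hybrid_loss
            assert scaled == pytest.approx(scale * base, rel=1e-10)

    def test_worked_fixture_sum_of_components(self):
        gen, target = make_patch_mae_image([1, 2, 3, 4])
        cfg = HybridConfig(weight_config=WeightConfig(2, 2), cutoff_fraction=0.2)
        rep = hybrid_loss(gen, target, cfg)
        mask = make_highpass_mask(gen.shape, 0.2)
        assert rep.wp_loss == pytest.approx(12.0)
        assert rep.hybrid_loss == pytest.approx(12.0 + naive_hf_loss(gen, target, mask.mask), abs=1e-9)

    def test_zero_alphas_rejected(self):
        with pytest.raises(ValueError):
            HybridConfig(alpha1=0.0, alpha2=0.0)

    def test_report_serializable(self, rng):
        a, b = rng.standard_normal((2, 8, 8))
        rep = hybrid_loss(a, b, HybridConfig(weight_config=WeightConfig(2, 2)))
        d = rep.to_dict()
        assert set(d) >= {"wp_loss", "hf_loss", "hybrid_loss", "patch_weights"}


def _finite_diff(fn, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return g


class TestGradients:
    """Analytic loss gradients vs central finite differences.

    Weights (and the DFT mask) are held constant per the training
    contract, so the finite differences are taken on the frozen-weight
    loss at the expansion point.
    """

    def test_wp_gradient_matches_frozen_weight_finite_diff(self, rng):
        cfg = WeightConfig(2, 2)
        g = rng.standard_normal((8, 8))
        t = rng.standard_normal((8, 8))
        _, grid = wp_loss(g, t, cfg)
        w0 = grid.weights
        analytic = wp_loss_grad(g, t, cfg)
        numeric = _finite_diff(lambda z: wp_loss_with_weights(z, t, w0, cfg), g)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-4, atol=1e-10)

    def test_hf_gradient_matches_finite_diff(self, rng):
        mask = make_highpass_mask((8, 8), 0.2)
        g, t = rng.standard_normal((2, 8, 8))
        analytic = hf_loss_grad(g, t, mask)
        numeric = _finite_diff(lambda z: hf_loss(z, t, mask), g)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-4, atol=1e-8)

    def test_hf_l2_gradient_matches_finite_diff(self, rng):
        mask = make_highpass_mask((8, 8), 0.2)
        g, t = rng.standard_normal((2, 8, 8))
        analytic = hf_loss_grad(g, t, mask, distance="l2")
        numeric = _finite_diff(lambda z: hf_loss(z, t, mask, distance="l2"), g)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-4, atol=1e-8)

    def test_hybrid_gradient_matches_finite_diff(self, rng):
        cfg = HybridConfig(alpha1=1.3, alpha2=0.7, weight_config=WeightConfig(2, 2), cutoff_fraction=0.2)
        g, t = rng.standard_normal((2, 8, 8))
        _, grid = wp_loss(g, t, cfg.weight_config)
        w0 = grid.weights
        mask = make_highpass_mask(g.shape, 0.2)
        frozen = lambda z: cfg.alpha1 * wp_loss_with_weights(z, t, w0, cfg.weight_config) + cfg.alpha2 * hf_loss(z, t, mask)
        analytic = hybrid_loss_grad(g, t, cfg)
        numeric = _finite_diff(frozen, g)
        denom = max(np.abs(numeric).max(), 1e-12)
        assert np.abs(analytic - numeric).max() / denom < 1e-4
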