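"""PCANet stages against hand arithmetic and brute-force references."""

import numpy as np
import pytest

from fatiguenet import (
    ConfigurationError,
    GeometryError,
    PCANetSpec,
    binary_hash,
    block_histogram,
    convolve_same,
    extract_patches,
    learn_filters,
    pcanet_fit,
    pcanet_transform,
)
from fatiguenet.pcanet import PatchMatrix, fit_transform, n_blocks
from naive_ref import (
    naive_block_histogram,
    naive_conv_same,
    naive_filters,
    naive_hash,
    naive_patches,
    naive_transform,
)

SMALL = PCANetSpec(k1=3, k2=3, L1=2, L2=2, block_h=2, block_w=2)


class TestExtractPatches:
    def test_column_count_formula(self, rng):
        spec = PCANetSpec()
        pm = extract_patches(rng.standard_normal((32, 20)), spec)
        assert pm.columns.shape == (25, 28 * 16)

    def test_constant_map_annihilated(self):
        pm = extract_patches(np.full((6, 6), 3.7), SMALL)
        np.testing.assert_allclose(pm.columns, 0.0, atol=1e-12)

    def test_single_patch_equals_vectorized_map(self, rng):
        arr = rng.standard_normal((3, 3))
        pm = extract_patches(arr, SMALL)
        assert pm.columns.shape == (9, 1)
        np.testing.assert_allclose(
            pm.columns[:, 0], arr.flatten(order="F") - arr.mean()
        )

    def test_matches_naive_reference(self, rng):
        arr = rng.standard_normal((7, 9))
        pm = extract_patches(arr, SMALL)
        np.testing.assert_allclose(pm.columns, naive_patches(arr, 3, 3),
                                   atol=1e-12)

    def test_too_small_map_rejected(self, rng):
        with pytest.raises(GeometryError):
            extract_patches(rng.standard_normal((2, 5)), SMALL)


class TestLearnFilters:
    def test_rank_one_patches_recover_direction(self, rng):
        v = rng.standard_normal(9)
        v -= v.mean()  # patch columns are mean-removed by construction
        v /= np.linalg.norm(v)
        coeffs = rng.standard_normal(40)
        pm = PatchMatrix(columns=np.outer(v, coeffs))
        bank = learn_filters([pm], 2, SMALL)
        w0 = bank.filters[0].flatten(order="F")
        assert abs(abs(w0 @ v) - 1.0) < 1e-10

    def test_orthonormality(self, rng):
        pms = [extract_patches(rng.standard_normal((8, 8)), SMALL)
               for _ in range(3)]
        bank = learn_filters(pms, 4, SMALL)
        w = bank.as_matrix()
        np.testing.assert_allclose(w.T @ w, np.eye(4), atol=1e-10)

    def test_matches_dense_eigensolver(self, rng):
        pms = [PatchMatrix(columns=rng.standard_normal((9, 8)))
               for _ in range(2)]
        # mean-remove columns as the pipeline guarantees
        for pm in pms:
            pm.columns -= pm.columns.mean(axis=0, keepdims=True)
        bank = learn_filters(pms, 3, SMALL)
        ref = naive_filters([pm.columns for pm in pms], 3, 3, 3)
        for got, want in zip(bank.filters, ref):
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_oversized_L_rejected(self, rng):
        pm = extract_patches(rng.standard_normal((6, 6)), SMALL)
        with pytest.raises(ConfigurationError):
            learn_filters([pm], 10, SMALL)


class TestConvolveSame:
    def test_delta_kernel_is_identity(self, rng):
        arr = rng.standard_normal((6, 7))
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        np.testing.assert_allclose(convolve_same(arr, delta), arr)

    def test_ones_kernel_padding_counts(self):
        out = convolve_same(np.ones((4, 4)), np.ones((3, 3)))
        assert out[1, 1] == pytest.approx(9.0)
        assert out[0, 0] == pytest.approx(4.0)
        assert out[0, 1] == pytest.approx(6.0)

    def test_matches_naive_cross_correlation(self, rng):
        arr = rng.standard_normal((6, 6))
        filt = rng.standard_normal((3, 3))
        np.testing.assert_allclose(
            convolve_same(arr, filt), naive_conv_same(arr, filt), atol=1e-12
        )

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(GeometryError):
            convolve_same(rng.standard_normal((5, 5)),
                          rng.standard_normal((2, 3)))


class TestBinaryHash:
    def test_all_positive_saturates(self):
        maps = [np.ones((3, 3))] * 4
        np.testing.assert_array_equal(binary_hash(maps),
                                      np.full((3, 3), 15))

    def test_nonpositive_is_zero(self):
        maps = [np.zeros((2, 2)), -np.ones((2, 2))]
        np.testing.assert_array_equal(binary_hash(maps), np.zeros((2, 2)))

    def test_sign_pattern_arithmetic(self):
        # signs (+, -, +) in p-order: 1*1 + 2*0 + 4*1 = 5
        maps = [np.array([[0.3]]), np.array([[-0.2]]), np.array([[7.0]])]
        assert binary_hash(maps)[0, 0] == 5

    def test_matches_naive(self, rng):
        maps = [rng.standard_normal((5, 4)) for _ in range(3)]
        np.testing.assert_array_equal(binary_hash(maps), naive_hash(maps))


class TestBlockHistogram:
    def test_hand_counted_histogram(self):
        spec = PCANetSpec(k1=3, k2=3, L1=2, L2=2, block_h=2, block_w=2)
        hist = block_histogram(np.array([[0, 1], [1, 3]]), spec, L2=2)
        np.testing.assert_array_equal(hist, [1, 2, 0, 1])

    def test_histograms_conserve_block_size(self, rng):
        spec = PCANetSpec(k1=3, k2=3, L1=2, L2=3, block_h=3, block_w=4)
        hm = rng.integers(0, 8, size=(9, 12))
        hist = block_histogram(hm, spec, L2=3)
        per_block = hist.reshape(-1, 8).sum(axis=1)
        np.testing.assert_array_equal(per_block, 12)

    def test_default_tiling_of_reduced_geometry(self):
        assert n_blocks(PCANetSpec(), (32, 20)) == 16

    def test_matches_naive(self, rng):
        spec = PCANetSpec(k1=3, k2=3, L1=2, L2=2, block_h=2, block_w=3)
        hm = rng.integers(0, 4, size=(7, 8))
        np.testing.assert_array_equal(
            block_histogram(hm, spec, 2),
            naive_block_histogram(hm, 2, 3, 2),
        )

    def test_block_larger_than_map_rejected(self):
        spec = PCANetSpec(k1=3, k2=3, block_h=8, block_w=8)
        with pytest.raises(GeometryError):
            block_histogram(np.zeros((4, 4), dtype=int), spec, 2)


class TestFitTransform:
    def test_structural_fit(self, rng):
        epochs = [rng.standard_normal((8, 6)) for _ in range(4)]
        model = pcanet_fit(epochs, SMALL)
        assert len(model.bank1) == 2 and len(model.bank2_for(0)) == 2
        w1, w2 = model.bank1.as_matrix(), model.bank2_for(0).as_matrix()
        np.testing.assert_allclose(w1.T @ w1, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(w2.T @ w2, np.eye(2), atol=1e-10)

    def test_fit_deterministic(self, rng):
        epochs = [rng.standard_normal((8, 6)) for _ in range(4)]
        m1 = pcanet_fit(epochs, SMALL)
        m2 = pcanet_fit(epochs, SMALL)
        for a, b in zip(m1.bank1.filters, m2.bank1.filters):
            np.testing.assert_array_equal(a, b)

    def test_feature_length_formula(self, rng):
        epochs = [rng.standard_normal((32, 20)) for _ in range(4)]
        model, feats = fit_transform(epochs, PCANetSpec())
        assert feats.shape == (4, 256 * 8 * 16)

    def test_zero_epoch_concentrates_in_bin_zero(self, rng):
        train = [rng.standard_normal((8, 6)) for _ in range(3)]
        model = pcanet_fit(train, SMALL)
        f = pcanet_transform(model, np.zeros((8, 6)))
        per_group = f.reshape(-1, 4)  # 2^L2 bins per (l, block) group
        assert np.all(per_group[:, 0] == per_group.sum(axis=1))

    def test_histogram_mass_conserved_per_group(self, rng):
        train = [rng.standard_normal((8, 6)) for _ in range(3)]
        model = pcanet_fit(train, SMALL)
        f = pcanet_transform(model, rng.standard_normal((8, 6)))
        groups = f.reshape(-1, 4).sum(axis=1)
        np.testing.assert_array_equal(groups, 4.0)  # 2x2 blocks

    def test_scale_invariance(self, rng):
        train = [rng.standard_normal((8, 6)) for _ in range(3)]
        model = pcanet_fit(train, SMALL)
        x = rng.standard_normal((8, 6))
        for c in (0.3, 7.0, 1234.5):
            np.testing.assert_array_equal(
                pcanet_transform(model, x), pcanet_transform(model, c * x)
            )

    def test_geometry_mismatch_rejected(self, rng):
        model = pcanet_fit([rng.standard_normal((8, 6))], SMALL)
        with pytest.raises(GeometryError):
            pcanet_transform(model, rng.standard_normal((9, 6)))

    def test_transform_matches_naive_chain(self, rng):
        """End-to-end oracle: with the learned banks, the vectorized
        transform equals the looped reference exactly on a small map."""
        train = [rng.standard_normal((8, 8)) for _ in range(3)]
        model = pcanet_fit(train, SMALL)
        x = rng.standard_normal((8, 8))
        got = pcanet_transform(model, x)
        want = naive_transform(
            x, model.bank1.filters, model.bank2_for(0).filters, 2, 2, 2
        )
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_per_map_mode_learns_one_bank_per_filter(self, rng):
        spec = PCANetSpec(k1=3, k2=3, L1=2, L2=2, block_h=2, block_w=2,
                          layer2_mode="per_map")
        epochs = [rng.standard_normal((8, 6)) for _ in range(4)]
        model = pcanet_fit(epochs, spec)
        assert isinstance(model.bank2, list) and len(model.bank2) == 2
        f = pcanet_transform(model, epochs[0])
        assert f.shape == (4 * 2 * n_blocks(spec, (8, 6)),)


def test_model_round_trip(tmp_path, rng):
    epochs = [rng.standard_normal((8, 6)) for _ in range(3)]
    model = pcanet_fit(epochs, SMALL)
    path = tmp_path / "model.npz"
    model.save(path)
    from fatiguenet import PCANetModel

    loaded = PCANetModel.load(path)
    x = rng.standard_normal((8, 6))
    np.testing.assert_array_equal(
        pcanet_transform(model, x), pcanet_transform(loaded, x)
    )
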