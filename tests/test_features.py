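"""Feature processor: attention rows, Gaussian kernel, pruning, GCN."""

import numpy as np
import pytest
from scipy import ndimage, stats

from segcn.autodiff import Tensor
from segcn.features import (
    ConfigError,
    GaussianKernelSpec,
    ProcessorParams,
    attention_adjacency,
    build_gaussian_kernel,
    convolve2d_replicate,
    gaussian_prune,
    gcn_layer,
    process,
)

RNG = np.random.default_rng(303)


def random_row_stochastic(n, rng, sharp=False):
    if sharp:
        m = np.full((n, n), 1e-6)
        m[np.arange(n), rng.integers(0, n, size=n)] = 1.0
    else:
        m = rng.gamma(1.0, 1.0, size=(n, n))
    return m / m.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------- attention


class TestAttentionAdjacency:
    def test_single_token_gives_unit_matrix_per_head(self):
        h = Tensor(RNG.normal(size=(1, 8)))
        W = Tensor(RNG.normal(size=(8, 8)))
        for S in attention_adjacency(h, W, W, heads=2):
            np.testing.assert_allclose(S.data, [[1.0]])

    def test_zero_projections_give_uniform_rows(self):
        h = Tensor(RNG.normal(size=(5, 8)))
        Z = Tensor(np.zeros((8, 8)))
        for S in attention_adjacency(h, Z, Z, heads=4):
            np.testing.assert_allclose(S.data, np.full((5, 5), 0.2))

    def test_rows_sum_to_one(self):
        h = Tensor(RNG.normal(size=(5, 8)))
        Wq, Wk = Tensor(RNG.normal(size=(8, 8))), Tensor(RNG.normal(size=(8, 8)))
        for S in attention_adjacency(h, Wq, Wk, heads=2):
            np.testing.assert_allclose(S.data.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(S.data >= 0)

    def test_masked_columns_get_zero_weight(self):
        h = Tensor(RNG.normal(size=(4, 8)))
        Wq, Wk = Tensor(RNG.normal(size=(8, 8))), Tensor(RNG.normal(size=(8, 8)))
        mask = np.array([True, True, True, False])
        for S in attention_adjacency(h, Wq, Wk, heads=2, mask=mask):
            np.testing.assert_allclose(S.data[:, 3], 0.0, atol=1e-12)
            np.testing.assert_allclose(S.data[:, :3].sum(axis=1), 1.0, atol=1e-6)

    def test_width_must_divide_heads(self):
        h = Tensor(RNG.normal(size=(3, 6)))
        W = Tensor(np.zeros((6, 6)))
        with pytest.raises(ConfigError):
            attention_adjacency(h, W, W, heads=4)


# ------------------------------------------------------------------- kernel


class TestGaussianKernel:
    def test_size_one_is_amplitude_or_unit(self):
        spec = GaussianKernelSpec(size=1, amplitude=2.5, normalize=False)
        np.testing.assert_allclose(build_gaussian_kernel(spec), [[2.5]])
        np.testing.assert_allclose(
            build_gaussian_kernel(GaussianKernelSpec(size=1)), [[1.0]]
        )

    def test_closed_form_center_entry_size3_sigma1(self):
        k = build_gaussian_kernel(GaussianKernelSpec(size=3, sigma_x=1.0, sigma_y=1.0))
        expected_center = 1.0 / (1 + 4 * np.exp(-0.5) + 4 * np.exp(-1.0))
        assert k[1, 1] == pytest.approx(expected_center, abs=1e-10)
        assert k.sum() == pytest.approx(1.0)
        # symmetric in both axes
        np.testing.assert_allclose(k, k.T)
        np.testing.assert_allclose(k, k[::-1, ::-1])

    def test_large_sigma_tends_to_uniform(self):
        k = build_gaussian_kernel(GaussianKernelSpec(size=3, sigma_x=100.0, sigma_y=100.0))
        np.testing.assert_allclose(k, np.full((3, 3), 1 / 9), atol=1e-3)

    def test_amplitude_cancels_when_normalized(self):
        a = build_gaussian_kernel(GaussianKernelSpec(size=5, amplitude=1.0))
        b = build_gaussian_kernel(GaussianKernelSpec(size=5, amplitude=7.3))
        np.testing.assert_allclose(a, b)

    @pytest.mark.parametrize("kwargs", [dict(size=2), dict(size=-1), dict(sigma_x=0.0)])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            GaussianKernelSpec(**kwargs)


# ------------------------------------------------------------------ pruning


class TestGaussianPrune:
    def test_delta_kernel_is_identity_bit_exact(self):
        m = random_row_stochastic(6, RNG)
        out = gaussian_prune(Tensor(m), np.array([[1.0]]))
        np.testing.assert_array_equal(out.data, m)

    def test_constant_matrix_is_fixed_point(self):
        n = 5
        m = np.full((n, n), 1 / n)
        kernel = build_gaussian_kernel(GaussianKernelSpec())
        np.testing.assert_allclose(gaussian_prune(Tensor(m), kernel).data, m, atol=1e-12)

    def test_convolution_matches_scipy_replicate_padding(self):
        kernel = build_gaussian_kernel(GaussianKernelSpec())
        for n in (3, 5, 9):
            m = random_row_stochastic(n, RNG)
            ours = convolve2d_replicate(Tensor(m), kernel).data
            ref = ndimage.correlate(m, kernel, mode="nearest")
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_entries_bounded_by_receptive_field(self):
        kernel = build_gaussian_kernel(GaussianKernelSpec())
        m = random_row_stochastic(7, RNG, sharp=True)
        padded = np.pad(m, 1, mode="edge")
        out = convolve2d_replicate(Tensor(m), kernel).data
        for i in range(7):
            for j in range(7):
                window = padded[i : i + 3, j : j + 3]
                assert window.min() - 1e-12 <= out[i, j] <= window.max() + 1e-12

    def test_rows_renormalized_and_entropy_rises_on_sharp_input(self):
        kernel = build_gaussian_kernel(GaussianKernelSpec())
        m = random_row_stochastic(8, RNG, sharp=True)
        out = gaussian_prune(Tensor(m), kernel).data
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
        # independent entropy routine on each row
        for before, after in zip(m, out):
            assert stats.entropy(after) > stats.entropy(before)
        assert out.max() < 1.0

    def test_oversized_kernel_cropped(self):
        m = random_row_stochastic(2, RNG)
        kernel = build_gaussian_kernel(GaussianKernelSpec(size=5))
        out = gaussian_prune(Tensor(m), kernel).data
        assert out.shape == (2, 2)
        np.testing.assert_allclose(out.sum(axis=1), 1.0)


# ---------------------------------------------------------------------- gcn


class TestGcnLayer:
    def test_no_edges_reduces_to_per_node_transform(self):
        H = RNG.normal(size=(4, 6))
        W = RNG.normal(size=(6, 3))
        out = gcn_layer(Tensor(H), Tensor(np.zeros((4, 4))), Tensor(W))
        np.testing.assert_allclose(out.data, np.maximum(H @ W, 0.0), atol=1e-12)

    def test_identity_weight_no_edges_no_activation_is_identity(self):
        H = RNG.normal(size=(4, 4))
        out = gcn_layer(Tensor(H), Tensor(np.zeros((4, 4))), Tensor(np.eye(4)), activation=None)
        np.testing.assert_allclose(out.data, H, atol=1e-12)

    def test_row_stochastic_adjacency_matches_dense_hand_computation(self):
        A = random_row_stochastic(4, RNG)
        H = RNG.normal(size=(4, 5))
        W = RNG.normal(size=(5, 2))
        out = gcn_layer(Tensor(H), Tensor(A), Tensor(W))
        A_tilde = A + np.eye(4)
        D = A_tilde.sum(axis=1)
        np.testing.assert_allclose(D, 2.0)  # row sum 1 + self loop
        ref = np.maximum((A_tilde / D[:, None]) @ H @ W, 0.0)
        np.testing.assert_allclose(out.data, ref, atol=1e-10)

    def test_permutation_equivariance(self):
        n = 5
        A = random_row_stochastic(n, RNG)
        H = RNG.normal(size=(n, 4))
        W = RNG.normal(size=(4, 4))
        perm = RNG.permutation(n)
        out = gcn_layer(Tensor(H), Tensor(A), Tensor(W)).data
        out_p = gcn_layer(Tensor(H[perm]), Tensor(A[np.ix_(perm, perm)]), Tensor(W)).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)

    def test_negative_adjacency_rejected(self):
        with pytest.raises(ValueError):
            gcn_layer(Tensor(np.ones((2, 2))), Tensor(-np.ones((2, 2))), Tensor(np.eye(2)))


# ------------------------------------------------------------ full processor


class TestProcess:
    def make(self, d=8, heads=2, layers=1, seed=0):
        return ProcessorParams.init(d, heads, layers, d, d, np.random.default_rng(seed))

    def test_output_shape_fixed_by_out_dim(self):
        h = Tensor(RNG.normal(size=(6, 8)))
        kernel = build_gaussian_kernel(GaussianKernelSpec())
        for heads, layers in [(1, 1), (2, 2), (4, 3)]:
            params = ProcessorParams.init(8, heads, layers, 8, 5, np.random.default_rng(1))
            out = process(h, params, kernel=kernel)
            assert out.shape == (6, 5)

    def test_single_head_no_prune_equals_manual_composition(self):
        h = Tensor(RNG.normal(size=(5, 8)))
        params = self.make(heads=1, layers=1, seed=2)
        out = process(h, params, use_pruning=False)
        (S,) = attention_adjacency(h, params.W_q, params.W_k, heads=1)
        manual = gcn_layer(h, S, params.gcn_weights[0][0]).data @ params.W_mix.data + params.b_mix.data
        np.testing.assert_allclose(out.data, manual, atol=1e-10)

    def test_pruning_changes_output_on_sharp_attention(self):
        h = Tensor(RNG.normal(size=(5, 8)) * 5)  # large scale -> sharp attention
        params = self.make(seed=3)
        kernel = build_gaussian_kernel(GaussianKernelSpec())
        a = process(h, params, kernel=kernel, use_pruning=True).data
        b = process(h, params, use_pruning=False).data
        assert not np.allclose(a, b)

    def test_feature_capture_off_is_identity(self):
        h = Tensor(RNG.normal(size=(4, 8)))
        params = self.make(seed=4)
        out = process(h, params, use_pruning=False, use_feature_capture=False)
        np.testing.assert_array_equal(out.data, h.data)

    def test_contradictory_ablation_flags_rejected(self):
        h = Tensor(RNG.normal(size=(4, 8)))
        with pytest.raises(ConfigError):
            process(h, self.make(), use_pruning=True, use_feature_capture=False)

    def test_row_stochasticity_preserved_through_pruning(self):
        h = Tensor(RNG.normal(size=(7, 8)))
        params = self.make(seed=5)
        kernel = build_gaussian_kernel(GaussianKernelSpec())
        _, graph = process(h, params, kernel=kernel, return_graph=True)
        for mat in graph.raw + graph.pruned:
            np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-6)
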