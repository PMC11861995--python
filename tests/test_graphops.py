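"""Kernel-level contracts: normalization spectrum, the propagation rule
against a per-node oracle, pooling symmetry, skip concatenation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connectogcn.graphops import (
    concat_skip,
    gcn_layer,
    global_pool,
    node_aggregate,
    normalize_adjacency,
)
from conftest import random_symmetric_graph


def gcn_layer_oracle(H, A_star, W, b, activation="relu"):
    """Per-node message-passing loop: for each node v, sum A*[v,u] (H[u] W),
    add the bias, apply the activation."""
    n = A_star.shape[0]
    out = np.zeros((n, W.shape[1]))
    for v in range(n):
        acc = np.zeros(W.shape[1])
        for u in range(n):
            acc += A_star[v, u] * (H[u] @ W)
        out[v] = acc + b
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation == "tanh":
        return np.tanh(out)
    return out


class TestNormalizeAdjacency:
    def test_zero_matrix_with_self_loops_is_identity(self):
        np.testing.assert_array_equal(normalize_adjacency(np.zeros((3, 3))), np.eye(3))

    def test_two_node_graph_hand_computed(self):
        # A+I = ones(2,2), degrees (2,2): D^-1/2 (A+I) D^-1/2 = 0.5 everywhere
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(A), np.full((2, 2), 0.5))

    def test_isolated_node_maps_to_zero_row(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 2.0
        out = normalize_adjacency(A, add_self_loops=False)
        np.testing.assert_array_equal(out[2], 0.0)
        assert np.isfinite(out).all()

    def test_output_shape_matches_input(self, rng):
        A = random_symmetric_graph(rng, 379)
        assert normalize_adjacency(A).shape == (379, 379)

    def test_asymmetric_input_rejected_with_entry(self):
        A = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match=r"not symmetric at \(0,1\)"):
            normalize_adjacency(A)

    def test_negative_input_rejected_with_entry(self):
        A = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            normalize_adjacency(A)

    @given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=50, deadline=None)
    def test_spectral_radius_bounded(self, n, seed):
        A = random_symmetric_graph(np.random.default_rng(seed), n)
        radius = np.abs(np.linalg.eigvalsh(normalize_adjacency(A))).max()
        assert radius <= 1 + 1e-9


class TestGCNLayer:
    def test_zero_weights_give_zero_output(self, rng):
        A = normalize_adjacency(random_symmetric_graph(rng, 6))
        H = rng.random((6, 4))
        out = gcn_layer(H, A, np.zeros((4, 3)), np.zeros(3))
        np.testing.assert_array_equal(out, np.zeros((6, 3)))

    def test_single_node_relu_clips_negative(self):
        out = gcn_layer(np.array([[2.0, -3.0]]), np.array([[1.0]]), np.eye(2), np.zeros(2))
        np.testing.assert_array_equal(out, [[2.0, 0.0]])

    @pytest.mark.parametrize("activation", ["relu", "tanh", "identity"])
    def test_matches_per_node_oracle(self, activation):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(2, 11))
            A = normalize_adjacency(random_symmetric_graph(rng, n))
            H = rng.normal(size=(n, 4))
            W = rng.normal(size=(4, 3))
            b = rng.normal(size=3)
            np.testing.assert_allclose(
                gcn_layer(H, A, W, b, activation),
                gcn_layer_oracle(H, A, W, b, activation),
                rtol=1e-6, atol=1e-12,
            )

    def test_tanh_keeps_embeddings_bounded(self, rng):
        A = normalize_adjacency(random_symmetric_graph(rng, 8))
        out = gcn_layer(rng.normal(size=(8, 5)) * 10, A, rng.normal(size=(5, 4)) * 10,
                        rng.normal(size=4), "tanh")
        assert (np.abs(out) <= 1.0).all()

    def test_permutation_equivariance(self, rng):
        n = 7
        A = normalize_adjacency(random_symmetric_graph(rng, n))
        H = rng.normal(size=(n, 3))
        W = rng.normal(size=(3, 2))
        b = rng.normal(size=2)
        P = np.eye(n)[rng.permutation(n)]
        lhs = gcn_layer(P @ H, P @ A @ P.T, W, b)
        rhs = P @ gcn_layer(H, A, W, b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    @pytest.mark.parametrize(
        "H, W, b",
        [
            (np.zeros((3, 2)), np.zeros((4, 3)), np.zeros(3)),  # inner dims disagree
            (np.zeros((3, 2)), np.zeros((2, 3)), np.zeros(5)),  # bias length wrong
        ],
    )
    def test_dimension_mismatch_rejected(self, H, W, b):
        A = np.eye(3)
        with pytest.raises(ValueError):
            gcn_layer(H, A, W, b)

    def test_non_finite_weights_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            gcn_layer(np.zeros((2, 2)), np.eye(2), np.full((2, 2), np.nan), np.zeros(2))


class TestPoolingAndSkips:
    def test_mean_pool_of_identical_rows(self):
        v = np.array([1.5, -2.0, 3.0])
        H = np.tile(v, (5, 1))
        np.testing.assert_array_equal(global_pool(H, "mean"), v)
        np.testing.assert_array_equal(node_aggregate(H, "mean"), v)

    def test_max_pool_column_maxima(self):
        np.testing.assert_array_equal(global_pool(np.array([[1.0, 4.0], [3.0, 2.0]]), "max"),
                                      [3.0, 4.0])

    def test_aggregate_column_means(self):
        np.testing.assert_array_equal(node_aggregate(np.array([[0.0, 1.0], [2.0, 3.0]]), "mean"),
                                      [1.0, 2.0])

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=25, deadline=None)
    def test_row_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        H = rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        for kind in ("mean", "max"):
            np.testing.assert_allclose(global_pool(H[perm], kind), global_pool(H, kind),
                                       atol=1e-12)

    def test_empty_embedding_rejected(self):
        with pytest.raises(ValueError):
            global_pool(np.zeros((0, 3)))

    def test_concat_in_layer_order(self):
        np.testing.assert_array_equal(concat_skip([np.array([1.0, 2.0]), np.array([3.0])]),
                                      [1.0, 2.0, 3.0])

    def test_concat_single_part_identity(self):
        v = np.array([4.0, 5.0])
        np.testing.assert_array_equal(concat_skip([v]), v)

    def test_concat_three_width_32_parts(self, rng):
        parts = [rng.normal(size=32) for _ in range(3)]
        assert concat_skip(parts).shape == (96,)

    def test_concat_empty_list_rejected(self):
        with pytest.raises(ValueError):
            concat_skip([])
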