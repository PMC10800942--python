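"""Graph-construction and efficiency contracts: correlation matrices,
proportional thresholding, BFS hop counts against a brute-force
Floyd-Warshall oracle, analytic efficiency values, and cohort scaling."""

import numpy as np
import pytest

from neuroexposome.connectome import (
    BinaryGraph,
    ConnectivityMatrix,
    binarize_proportional,
    global_efficiency,
    pearson_matrix,
    scale_and_adjust,
    shortest_paths,
)
from neuroexposome.synthetic import Demographics


def floyd_warshall(A):
    """Brute-force all-pairs hop counts; the independent oracle."""
    N = A.shape[0]
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(N):
        for i in range(N):
            for j in range(N):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def random_adjacency(rng, n, p):
    A = (rng.random((n, n)) < p).astype(int)
    A = np.triu(A, 1)
    return A + A.T


def path_graph(n):
    A = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1
    return A


class TestPearsonMatrix:
    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        C = pearson_matrix(np.column_stack([x, x, rng.standard_normal(100)])).C
        assert C[0, 1] == pytest.approx(1.0)

    def test_antiphase_columns_correlate_negatively(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        C = pearson_matrix(np.column_stack([x, -x])).C
        assert C[0, 1] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        C = pearson_matrix(rng.standard_normal((100_000, 4))).C
        off = C[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_constant_column_rejected_by_name(self):
        Y = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.raises(ValueError, match="node000"):
            pearson_matrix(Y)


class TestBinarizeProportional:
    def test_full_density_on_positive_matrix_gives_complete_graph(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((200, 5)) + 5 * rng.standard_normal((200, 1))
        g = binarize_proportional(pearson_matrix(Y), 1.0)
        assert g.n_edges == 5 * 4 // 2

    def test_three_node_rank_and_cut(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.9
        C[0, 2] = C[2, 0] = 0.5
        C[1, 2] = C[2, 1] = 0.1
        g = binarize_proportional(ConnectivityMatrix(C=C), 1 / 3)
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 1] = expected[1, 0] = 1
        assert np.array_equal(g.A, expected)

    def test_all_negative_matrix_rejected(self):
        C = np.eye(3) - 0.4 * (1 - np.eye(3))
        with pytest.raises(ValueError, match="positive"):
            binarize_proportional(ConnectivityMatrix(C=C), 0.5)

    def test_edge_count_matches_density(self):
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((500, 20)) + 2 * rng.standard_normal((500, 1))
        for density in (0.05, 0.15, 0.4):
            g = binarize_proportional(pearson_matrix(Y), density)
            assert g.n_edges == round(density * 20 * 19 / 2)

    def test_zero_edge_density_rejected(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.5
        with pytest.raises(ValueError, match="zero edges"):
            binarize_proportional(ConnectivityMatrix(C=C), 0.01)


class TestShortestPaths:
    def test_chain_distance(self):
        D = shortest_paths(path_graph(3))
        assert D[0, 2] == 2

    def test_complete_graph_all_direct(self):
        A = 1 - np.eye(4, dtype=int)
        D = shortest_paths(A)
        off = D[~np.eye(4, dtype=bool)]
        assert (off == 1).all()

    def test_disconnected_pairs_are_infinite(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = 1
        D = shortest_paths(A)
        assert np.isinf(D[0, 2])

    def test_bfs_matches_floyd_warshall_oracle(self):
        """100 random graphs: the BFS implementation equals the brute-force
        Floyd-Warshall oracle everywhere."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            A = random_adjacency(rng, 10, 0.3)
            assert np.array_equal(shortest_paths(A), floyd_warshall(A))


class TestGlobalEfficiency:
    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_complete_graph_is_one(self, n):
        assert global_efficiency(1 - np.eye(n, dtype=int)) == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        assert global_efficiency(np.zeros((5, 5), dtype=int)) == 0.0

    def test_path_graph_p3_analytic(self):
        # ordered pairs: 4 at distance 1, 2 at distance 2 -> (4 + 1)/6
        assert global_efficiency(path_graph(3)) == pytest.approx(5 / 6)

    def test_matches_networkx_on_random_graphs(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(6)
        for _ in range(20):
            A = random_adjacency(rng, 12, 0.25)
            expected = nx.global_efficiency(nx.from_numpy_array(A))
            assert global_efficiency(A) == pytest.approx(expected)

    def test_adding_edges_never_decreases_efficiency(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            A = random_adjacency(rng, 9, 0.2)
            before = global_efficiency(A)
            absent = np.argwhere(np.triu(A == 0, 1))
            if len(absent) == 0:
                continue
            i, j = absent[rng.integers(len(absent))]
            A2 = A.copy()
            A2[i, j] = A2[j, i] = 1
            assert global_efficiency(A2) >= before - 1e-12

    def test_one_attained_only_by_complete_graph(self):
        A = 1 - np.eye(4, dtype=int)
        A[0, 1] = A[1, 0] = 0
        assert global_efficiency(A) < 1.0


class TestScaleAndAdjust:
    def _demo(self, n, seed=0, const_sex=False):
        rng = np.random.default_rng(seed)
        return [
            Demographics(f"s{i:02d}", age=float(rng.uniform(13, 25)), sex=0 if const_sex else int(rng.integers(2)))
            for i in range(n)
        ]

    def test_minmax_endpoints(self):
        table = scale_and_adjust([0.2, 0.5, 0.8], self._demo(3))
        assert np.allclose(table["ge_scaled"], [0.0, 0.5, 1.0])

    def test_adjusted_scores_standardized(self):
        rng = np.random.default_rng(8)
        table = scale_and_adjust(rng.random(40), self._demo(40, seed=9))
        assert table["ge_adj"].mean() == pytest.approx(0.0, abs=1e-10)
        assert table["ge_adj"].std(ddof=1) == pytest.approx(1.0)

    def test_orthogonal_covariates_reduce_to_zscores(self):
        """When age/sex carry no information about efficiency, adjustment is
        plain standardization of the scaled values."""
        rng = np.random.default_rng(10)
        ge = rng.random(30)
        scaled = (ge - ge.min()) / np.ptp(ge)
        # age constructed exactly orthogonal to scaled ge (and to intercept)
        raw_age = rng.standard_normal(30)
        Q = np.column_stack([np.ones(30), scaled])
        age = raw_age - Q @ np.linalg.lstsq(Q, raw_age, rcond=None)[0]
        demo = [Demographics(f"s{i:02d}", age=float(a), sex=0) for i, a in enumerate(age)]
        table = scale_and_adjust(ge, demo)  # constant sex spans the intercept
        z = (scaled - scaled.mean()) / scaled.std(ddof=1)
        assert np.allclose(table["ge_adj"], z)

    def test_max_mode_divides_by_maximum(self):
        table = scale_and_adjust([0.2, 0.5, 0.8], self._demo(3), scale_mode="max")
        assert np.allclose(table["ge_scaled"], [0.25, 0.625, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            scale_and_adjust([0.5, 0.5, 0.5], self._demo(3))


class TestBinaryGraphInvariants:
    def test_asymmetric_adjacency_rejected(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            BinaryGraph(A=A, density=0.1)

    def test_self_loops_rejected(self):
        A = np.eye(3, dtype=int)
        with pytest.raises(ValueError, match="diagonal"):
            BinaryGraph(A=A, density=0.1)
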