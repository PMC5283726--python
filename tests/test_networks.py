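import networkx as nx
import numpy as np
import pytest

from sisnet import (ConstraintFailure, Network, cayley_tree_size,
                    fit_degree_distribution, generate_cayley_tree,
                    generate_heterogeneous, generate_k_regular,
                    point_mass_spec)


class TestKRegular:
    def test_odd_degree_sum_rejected(self):
        with pytest.raises(ValueError):
            generate_k_regular(5, 3)

    def test_eight_cycle_is_unique_2_regular_girth6_graph(self):
        net = generate_k_regular(8, 2, seed=0, min_girth=6)
        assert all(d == 2 for d in net.degree_sequence)
        g = net.to_networkx()
        assert nx.is_connected(g)          # two 4-cycles are excluded
        assert nx.girth(g) == 8

    @pytest.mark.parametrize("N,k", [(2000, 3), (1000, 4)])
    def test_regularity_and_girth(self, N, k):
        net = generate_k_regular(N, k, seed=3, min_girth=6)
        assert set(net.degree_sequence) == {k}
        assert nx.girth(net.to_networkx()) >= 6
        assert sum(net.degree_sequence) == 2 * net.n_edges

    def test_seed_reproducibility(self):
        a = generate_k_regular(500, 3, seed=9)
        b = generate_k_regular(500, 3, seed=9)
        assert a.edges == b.edges

    def test_adjacency_contract(self, ring8):
        assert ring8.A(0, 1) == 1 == ring8.A(1, 0)
        assert ring8.A(0, 0) == 0
        assert ring8.A(0, 4) == 0


class TestCayley:
    @pytest.mark.parametrize("k,depth,expected", [
        (3, 1, 4), (3, 2, 10), (2, 5, 11)])
    def test_known_sizes(self, k, depth, expected):
        net = generate_cayley_tree(k, depth)
        assert net.N == expected
        assert net.n_edges == net.N - 1  # a tree

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("depth", [1, 3, 5, 8])
    def test_size_formula(self, k, depth):
        net = generate_cayley_tree(k, depth)
        assert net.N == cayley_tree_size(k, depth)
        deg = np.array(net.degree_sequence)
        assert deg[0] == k                       # root
        assert set(deg) <= {1, k}
        if k == 2:
            assert nx.diameter(net.to_networkx()) == 2 * depth  # a path

    def test_invalid_degree(self):
        with pytest.raises(ValueError):
            generate_cayley_tree(1, 3)


class TestDegreeDistribution:
    def test_zero_variance_degenerates_to_point_mass(self):
        spec = fit_degree_distribution(3, 0.0, k_min=2)
        assert spec.pmf[spec.support == 3] == pytest.approx(1.0)
        assert spec.mean == pytest.approx(3.0)

    @pytest.mark.parametrize("mean,var", [(3, 1.5), (4, 4), (6, 1)])
    def test_fitted_moments(self, mean, var):
        spec = fit_degree_distribution(mean, var, k_min=2)
        assert spec.mean == pytest.approx(mean, rel=1e-6)
        assert spec.variance == pytest.approx(var, rel=1e-6)
        # direct summation cross-check of the stated functional form
        k = spec.support
        w = spec.rho * np.exp(-spec.alpha * (k - spec.K) ** 2)
        assert w.sum() == pytest.approx(1.0, rel=1e-9)
        assert (k * w).sum() == pytest.approx(mean, rel=1e-6)

    def test_geometric_tail_boundary_case(self):
        # at mean 3 the family's variance is maximised by the geometric
        # tail (alpha -> 0), which gives variance exactly 2
        spec = fit_degree_distribution(3, 2, k_min=2)
        assert spec.mean == pytest.approx(3.0, rel=1e-6)
        assert spec.variance == pytest.approx(2.0, rel=1e-6)

    def test_infeasible_targets_fail(self):
        with pytest.raises(ConstraintFailure):
            fit_degree_distribution(1.5, 1.0, k_min=2)  # mean below k_min
        with pytest.raises(ConstraintFailure):
            fit_degree_distribution(3.0, 4.0, k_min=2)  # above the tail bound


class TestHeterogeneous:
    def test_point_mass_matches_regular_contract(self):
        net = generate_heterogeneous(point_mass_spec(3), 1000, seed=4)
        assert set(net.degree_sequence) == {3}
        g = net.to_networkx()
        assert not list(nx.selfloop_edges(g))

    def test_empirical_mean_within_clt_band(self):
        spec = fit_degree_distribution(4, 4, k_min=2)
        net = generate_heterogeneous(spec, 20000, seed=5)
        deg = np.array(net.degree_sequence, dtype=float)
        se = np.sqrt(spec.variance / len(deg))
        assert abs(deg.mean() - 4.0) < 3 * se
        assert sum(net.degree_sequence) == 2 * net.n_edges

    def test_infeasible_wiring_fails(self):
        with pytest.raises((ConstraintFailure, ValueError)):
            generate_heterogeneous(point_mass_spec(30), 12, seed=0)


class TestIO:
    def test_edgelist_roundtrip(self, tmp_path, regular_k3_small):
        path = tmp_path / "net.edges"
        regular_k3_small.write_edgelist(path)
        back = Network.read_edgelist(path)
        assert back.N == regular_k3_small.N
        assert back.edges == regular_k3_small.edges
        assert back.meta["k"] == 3

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            Network.from_edges(3, [(0, 0)])        # self edge
        with pytest.raises(ValueError):
            Network.from_edges(2, [(0, 5)])        # out of range
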