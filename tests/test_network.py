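"""Contact kernel, MI estimators, graph construction, paths, centrality."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allopath.network import (AllostericNetworkModel, KernelParams,
                              MISettings, betweenness, build_network,
                              contact_map, detect_region, kernel, min_path,
                              mutual_information, mutual_information_matrix)
from conftest import brute_force_betweenness, brute_force_min_path


class TestKernel:
    def test_plateau_calibration_and_truncation(self):
        p = KernelParams()
        assert kernel(5.0, p) == 1.0
        assert kernel(7.0, p) == 1.0
        # sigma solved from K(d_cut) = 1e-5
        assert p.sigma_effective == pytest.approx(0.6252, abs=5e-4)
        assert kernel(10.0, p) == pytest.approx(1e-5, rel=1e-9)
        assert kernel(25.0, p) == 0.0

    def test_explicit_sigma_accepted(self):
        p = KernelParams(sigma=1.48)
        assert p.sigma_effective == 1.48
        assert kernel(8.0, p) == pytest.approx(math.exp(-1.0 / (2 * 1.48**2)))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel(-0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=30.0))
    def test_bounded_and_nonincreasing(self, d):
        p = KernelParams()
        v = kernel(d, p)
        assert 0.0 <= v <= 1.0
        assert kernel(d + 0.5, p) <= v + 1e-12


class TestContactMap:
    def _anchors(self, dists, n_frames):
        """Two nodes separated by dists[t] along x at frame t."""
        a = np.zeros((2, n_frames, 3))
        a[1, :, 0] = dists
        return a

    def test_always_in_contact(self):
        C = contact_map(self._anchors(np.full(50, 4.0), 50))
        assert C[0, 1] == 1.0 and C[0, 0] == 1.0

    def test_half_occupancy(self):
        d = np.where(np.arange(100) < 50, 4.0, 20.0)
        C = contact_map(self._anchors(d, 100))
        assert C[0, 1] == pytest.approx(0.5)

    def test_matches_direct_average(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(3.0, 12.0, 200)
        C = contact_map(self._anchors(d, 200))
        assert C[0, 1] == pytest.approx(np.mean(kernel(d)), rel=1e-12)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            contact_map(np.zeros((2, 0, 3)))


class TestMutualInformation:
    def test_identical_series_saturate(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((500, 3))
        e = mutual_information(x, x.copy())
        assert e.M_hat == 1.0
        assert e.M == pytest.approx(e.H_ij)

    def test_gaussian_estimator_closed_form(self):
        rho = 0.8
        rng = np.random.default_rng(1)
        z = rng.standard_normal((20000, 2))
        y = rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1]
        e = mutual_information(z[:, 0], y,
                               MISettings(estimator="gaussian"))
        assert e.M == pytest.approx(-0.5 * math.log(1 - rho**2), rel=0.05)

    def test_degenerate_series_zero_with_warning(self):
        x = np.zeros((200, 3))
        y = np.random.default_rng(0).standard_normal((200, 3))
        with pytest.warns(UserWarning, match="degenerate"):
            e = mutual_information(x, y)
        assert e.M_hat == 0.0

    def test_short_series_rejected(self):
        x = np.zeros((50, 3))
        with pytest.raises(ValueError, match="samples"):
            mutual_information(x, x)

    def test_joint_mode_agrees_on_1d(self):
        """For 1-D series the factorized and joint estimators coincide."""
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 1000))
        a = mutual_information(x, y, MISettings(mode="factorized"))
        b = mutual_information(x, y, MISettings(mode="joint"))
        assert a.M == pytest.approx(b.M)
        assert a.H_ij == pytest.approx(b.H_ij)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 300, 3))
        y[:, 0] += 0.5 * x[:, 0]
        a = mutual_information(x, y)
        b = mutual_information(y, x)
        assert a.M == pytest.approx(b.M)
        assert 0.0 <= a.M_hat <= 1.0
        assert a.M >= 0.0

    def test_matrix_is_symmetric_unit_diagonal(self, toy_node_series):
        mi = mutual_information_matrix(
            np.stack([n.displacement for n in toy_node_series[:6]]))
        np.testing.assert_allclose(mi.M_hat, mi.M_hat.T)
        np.testing.assert_allclose(np.diag(mi.M_hat), 1.0)


class TestBuildNetwork:
    def test_log_identities(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        M = np.array([[1.0, math.exp(-2)], [math.exp(-2), 1.0]])
        G = build_network(C, M)
        assert G[0][1]["weight"] == pytest.approx(2.0)
        M2 = np.ones((2, 2))
        assert build_network(C, M2)[0][1]["weight"] == 0.0

    def test_no_contact_no_edge(self):
        C = np.array([[1.0, 0.0], [0.0, 1.0]])
        M = np.ones((2, 2))
        G = build_network(C, M)
        assert G.number_of_edges() == 0
        assert G.number_of_nodes() == 2

    def test_no_self_edges_and_finite_weights(self, toy_node_series):
        model = AllostericNetworkModel(toy_node_series)
        G = model.fit().graph
        assert all(u != v for u, v in G.edges)
        w = [d["weight"] for _, _, d in G.edges(data=True)]
        assert np.all(np.isfinite(w)) and np.all(np.asarray(w) >= 0)

    def test_exclude_adjacent_mask(self):
        C = np.ones((3, 3))
        M = np.ones((3, 3))
        G = build_network(C, M, exclude_adjacent=1)
        assert set(G.edges) == {(0, 2)}


class TestDetectRegion:
    def _fixed(self, offsets):
        n = len(offsets)
        a = np.zeros((n, 10, 3))
        for i, off in enumerate(offsets):
            a[i, :, 0] = off
        return a

    def test_always_inside_included(self):
        region = detect_region(self._fixed([0.0, 5.0, 12.0]), center=0,
                               radius=7.0)
        assert region == {0, 1}

    def test_partial_occupancy_excluded(self):
        a = np.zeros((2, 100, 3))
        a[1, :, 0] = np.where(np.arange(100) < 60, 5.0, 12.0)  # 60% inside
        assert detect_region(a, 0, 7.0, occupancy_threshold=0.70) == {0}
        assert detect_region(a, 0, 7.0, occupancy_threshold=0.55) == {0, 1}

    def test_zero_radius_only_center(self):
        assert detect_region(self._fixed([0.0, 1.0]), 0, radius=0.0) == {0}

    def test_unknown_center_rejected(self):
        with pytest.raises(KeyError):
            detect_region(self._fixed([0.0]), 5)


def _random_graph(seed, n=8, p=0.6):
    rng = np.random.default_rng(seed)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                G.add_edge(i, j, weight=float(rng.uniform(0.1, 5.0)))
    return G


class TestMinPath:
    def test_single_edge(self):
        G = nx.Graph()
        G.add_edge("s", "t", weight=3.0)
        r = min_path(G, {"s"}, {"t"})
        assert r.d_min == 3.0 and r.best_path == ["s", "t"]
        assert r.coupling_efficiency() == pytest.approx(math.exp(-3.0))

    def test_six_node_toy_graph_matches_enumeration(self):
        G = nx.Graph()
        edges = [(0, 1, 1.0), (1, 2, 1.0), (2, 5, 1.0), (0, 3, 0.5),
                 (3, 4, 2.0), (4, 5, 0.4), (1, 4, 1.2), (2, 3, 0.3)]
        G.add_weighted_edges_from(edges)
        r = min_path(G, {0}, {5})
        d_bf, p_bf = brute_force_min_path(G, {0}, {5})
        assert r.d_min == pytest.approx(d_bf)
        assert r.best_path == p_bf

    def test_unreachable_flagged(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=1.0)
        G.add_node(2)
        r = min_path(G, {0}, {2})
        assert math.isinf(r.d_min) and not r.reachable
        assert r.best_path is None
        assert r.coupling_efficiency() == 0.0

    def test_region_minimum_over_pairs(self):
        G = nx.Graph()
        G.add_weighted_edges_from([(0, 2, 5.0), (1, 2, 1.0), (2, 3, 1.0),
                                   (2, 4, 2.0)])
        r = min_path(G, {0, 1}, {3, 4})
        assert r.d_min == 2.0
        assert r.best_path == [1, 2, 3]

    def test_co_minimal_ties_lexicographic(self):
        G = nx.Graph()
        G.add_weighted_edges_from([("a", "b", 1.0), ("b", "d", 1.0),
                                   ("a", "c", 1.0), ("c", "d", 1.0)])
        r = min_path(G, {"a"}, {"d"})
        assert len(r.co_minimal_paths) == 2
        assert r.best_path == ["a", "b", "d"]

    def test_input_contracts(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=1.0)
        with pytest.raises(ValueError):
            min_path(G, set(), {1})
        with pytest.raises(ValueError):
            min_path(G, {0}, {0, 1})
        with pytest.raises(KeyError):
            min_path(G, {0}, {99})


class TestBetweenness:
    def test_path_graph_closed_form(self):
        G = nx.Graph()
        G.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0)])
        b = betweenness(G)
        assert b["b"] == 1.0 and b["a"] == 0.0 and b["c"] == 0.0

    def test_star_graph_closed_form(self):
        G = nx.star_graph(4)
        nx.set_edge_attributes(G, 1.0, "weight")
        b = betweenness(G)
        assert b[0] == 1.0
        assert all(b[i] == 0.0 for i in range(1, 5))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_graphs_match_brute_force(self, seed):
        G = _random_graph(seed)
        b = betweenness(G)
        b_bf = brute_force_betweenness(G)
        for v in G.nodes:
            assert b[v] == pytest.approx(b_bf[v], abs=1e-9)


class TestModelResults:
    def test_planted_chain_is_shortest(self, toy_node_series):
        res = AllostericNetworkModel(toy_node_series).fit()
        r = res.min_path({0}, {9})
        assert r.best_path == list(range(10))

    def test_monotone_in_rho(self, toy_channel):
        """Stronger planted correlation never lengthens the planted path."""
        from allopath.synthetic import PlantedCovariance, generate_trajectory
        from allopath.trajectory import extract_node_series, load_system

        dmins = []
        for rho in (0.5, 0.7, 0.9):
            cov = PlantedCovariance(path_nodes=tuple(range(10)), rho_path=rho)
            traj = generate_trajectory(toy_channel, cov, 500, seed=21)
            series = extract_node_series(
                load_system(None, universe=traj.to_universe()))
            res = AllostericNetworkModel(series).fit()
            dmins.append(res.min_path({0}, {9}).d_min)
        assert dmins[0] > dmins[1] > dmins[2]

    def test_region_queries_and_labels(self, toy_node_series):
        res = AllostericNetworkModel(toy_node_series).fit()
        region = res.detect_region("A:ALA1", radius=7.0)
        assert res.index_of("A:ALA1") in region
        assert region == res.detect_region(0, radius=7.0)

    def test_summary_and_exports(self, toy_node_series, tmp_path):
        res = AllostericNetworkModel(toy_node_series[:12]).fit()
        text = res.summary()
        assert "nodes" in text and "sigma" in text
        edge_file = res.to_edge_list(tmp_path / "edges.tsv")
        lines = edge_file.read_text().splitlines()
        assert lines[0].startswith("node_i") and len(lines) > 1
        res.to_graphml(tmp_path / "net.graphml")
        H = nx.read_graphml(tmp_path / "net.graphml")
        assert H.number_of_nodes() == 12
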