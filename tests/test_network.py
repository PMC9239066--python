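"""Co-occurrence networks: filtering, inference, modules, statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizolink.network import (
    Network,
    StarsConfig,
    covariance_to_correlation,
    detect_modules,
    infer_network,
    module_abundances,
    network_filter,
    network_stats,
    subset_strong_edges,
)


class TestNetworkFilter:
    def test_boundaries(self):
        counts = pd.DataFrame(
            {
                "three_samples": [50, 50, 50] + [0] * 7,
                "abundant": [60] * 10,
                "rare": [1] * 10,
                "filler": [900, 900, 900] + [939, 999, 999, 999, 999, 999, 999][:7],
            }
        )
        keep = network_filter(counts, min_samples=4, min_mean_rel_abund=0.005)
        assert "three_samples" not in keep  # present in only 3 samples
        assert "abundant" in keep  # ~6% mean abundance in 10 samples
        assert "rare" not in keep  # ~0.1% mean abundance

    def test_matches_brute_force(self, toy_counts):
        keep = network_filter(toy_counts, min_samples=3, min_mean_rel_abund=0.05)
        rel = toy_counts.div(toy_counts.sum(axis=1), axis=0).mean()
        present = (toy_counts > 0).sum()
        expected = [
            f for f in toy_counts.columns if present[f] >= 3 and rel[f] > 0.05
        ]
        assert keep == expected

    def test_empty_is_error(self):
        counts = pd.DataFrame({"a": [1, 0, 0, 0, 0, 0, 0, 0, 0, 100]})
        with pytest.raises(ValueError):
            network_filter(counts, min_samples=9, min_mean_rel_abund=0.5)


class TestCov2Cor:
    def test_identity(self):
        assert np.allclose(covariance_to_correlation(np.eye(3)), np.eye(3))

    def test_hand_computed(self):
        corr = covariance_to_correlation(np.array([[4.0, 2.0], [2.0, 9.0]]))
        assert corr[0, 1] == pytest.approx(2 / 6)
        assert np.allclose(np.diag(corr), 1)

    def test_diagonal_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((4, 4))
        cov = A @ A.T + 4 * np.eye(4)
        d = np.diag([2.0, 0.5, 3.0, 1.0])
        assert np.allclose(
            covariance_to_correlation(cov), covariance_to_correlation(d @ cov @ d)
        )

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            covariance_to_correlation(np.array([[0.0, 0], [0, 1]]))


def graph_from_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_weighted_edges_from(edges)
    return g


class TestDetectModules:
    def test_two_positive_cliques(self):
        edges = [(a, b, 0.8) for a in "abc" for b in "abc" if a < b]
        edges += [(a, b, 0.8) for a in "xyz" for b in "xyz" if a < b]
        labels = detect_modules(graph_from_edges(edges), seed=0)
        assert len(set(labels.values())) == 2
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["x"] == labels["y"] == labels["z"]
        assert labels["a"] != labels["x"]

    def test_all_negative_edges_give_singletons(self):
        edges = [("a", "b", -0.5), ("b", "c", -0.9)]
        labels = detect_modules(graph_from_edges(edges), seed=0)
        assert len(set(labels.values())) == 3

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        edges = [
            (f"v{i}", f"v{j}", float(rng.uniform(0.1, 1)))
            for i in range(12) for j in range(i + 1, 12) if rng.random() < 0.4
        ]
        g = graph_from_edges(edges)
        assert detect_modules(g, seed=5) == detect_modules(g, seed=5)


class TestNetworkStats:
    def test_triangle(self):
        g = graph_from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        s = network_stats(g)
        assert s.n_vertices == 3 and s.n_edges == 3
        assert s.mean_degree == 2
        assert s.mean_strength == 2
        assert s.n_modules >= 1

    def test_single_edge_mean_weight(self):
        g = graph_from_edges([("a", "b", 0.5)])
        assert network_stats(g).mean_weight == pytest.approx(0.5)

    def test_matches_brute_force_on_random_graph(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(15, 0.3, seed=4)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(-1, 1))
        s = network_stats(g)
        V, E = g.number_of_nodes(), g.number_of_edges()
        assert s.mean_degree == pytest.approx(2 * E / V)
        degs = [d for _, d in g.degree()]
        assert sum(degs) == 2 * E
        strengths = [
            sum(abs(g[u][v]["weight"]) for v in g[u]) for u in g.nodes
        ]
        assert s.mean_strength == pytest.approx(np.mean(strengths))
        weights = [d["weight"] for _, _, d in g.edges(data=True)]
        assert s.mean_weight == pytest.approx(np.mean(weights))


class TestSubsetStrongEdges:
    def test_equal_weights_give_empty_subnetwork(self):
        edges = [("g1", "a", 0.3), ("g1", "b", 0.3), ("a", "b", 0.3)]
        sub, dropped, (q1, q3) = subset_strong_edges(graph_from_edges(edges), ["g1"])
        assert q1 == q3 == 0.3
        assert sub.number_of_edges() == 0
        assert "g1" in dropped

    def test_quartile_thresholding(self):
        edges = [("g1", "a", 0.9), ("a", "b", 0.1), ("b", "c", 0.0), ("c", "d", -0.5)]
        g = graph_from_edges(edges)
        sub, dropped, (q1, q3) = subset_strong_edges(g, ["g1"])
        # quartiles of {-0.5, 0, 0.1, 0.9}: the 0.9 edge exceeds Q3
        assert ("g1", "a") in sub.edges
        assert not dropped

    def test_growth_vertex_without_strong_edges_reported(self):
        edges = [
            ("g1", "a", 0.2), ("a", "b", 0.9), ("b", "c", -0.9),
            ("c", "d", 0.25), ("d", "a", 0.21),
        ]
        g = graph_from_edges(edges)
        sub, dropped, _ = subset_strong_edges(g, ["g1"])
        assert "g1" in dropped
        assert "g1" not in sub.nodes

    def test_matches_brute_force_membership(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(20, 0.25, seed=9)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(-1, 1))
        growth = [0, 1, 2]
        sub, dropped, (q1, q3) = subset_strong_edges(g, growth)
        weights = [d["weight"] for _, _, d in g.edges(data=True)]
        eq1, eq3 = np.quantile(weights, [0.25, 0.75])
        assert (q1, q3) == (pytest.approx(eq1), pytest.approx(eq3))
        strong = [
            (u, v) for u, v, d in g.edges(data=True)
            if d["weight"] > eq3 or d["weight"] < eq1
        ]
        expect_nodes = set()
        for u, v in strong:
            if u in growth or v in growth:
                expect_nodes.update((u, v))
        assert set(sub.nodes) == expect_nodes

    def test_no_growth_ids_warns_empty(self, caplog):
        g = graph_from_edges([("a", "b", 0.5)])
        sub, dropped, _ = subset_strong_edges(g, ["missing"])
        assert sub.number_of_nodes() == 0


class TestModuleAbundances:
    def test_singleton_and_pair_sums(self, toy_counts):
        labels = {"asvA": "M1", "asvB": "M2", "asvC": "M2"}
        mod = module_abundances(toy_counts, labels)
        assert (mod["M1"] == toy_counts["asvA"]).all()
        assert (mod["M2"] == toy_counts["asvB"] + toy_counts["asvC"]).all()
        # unassigned features are excluded: module sums never exceed totals
        assert (mod.sum(axis=1) <= toy_counts.sum(axis=1)).all()

    def test_full_cover_conserves_reads(self, toy_counts):
        labels = {f: "M1" for f in toy_counts.columns}
        mod = module_abundances(toy_counts, labels)
        assert (mod.sum(axis=1) == toy_counts.sum(axis=1)).all()


class TestInferNetwork:
    def test_independent_features_give_few_edges(self):
        rng = np.random.default_rng(6)
        # draw counts with a diagonal latent precision: no true edges
        z = rng.standard_normal((150, 12))
        probs = np.exp(z)
        probs /= probs.sum(axis=1, keepdims=True)
        counts = pd.DataFrame(
            np.vstack([rng.multinomial(5000, p) for p in probs]),
            columns=[f"f{i}" for i in range(12)],
        )
        nw = infer_network(counts, stability=StarsConfig(n_subsamples=20), seed=0)
        possible = 12 * 11 / 2
        assert nw.graph.number_of_edges() / possible <= 0.05

    def test_small_instance_matches_direct_solver(self):
        # 3-feature chain precision: the penalized precision at a fixed
        # penalty must match an independent convex solve of the
        # graphical-lasso objective
        from scipy.optimize import minimize

        from rhizolink.network import _glasso_support, clr

        rng = np.random.default_rng(7)
        omega = np.array([[1.0, -0.4, 0.0], [-0.4, 1.0, -0.4], [0.0, -0.4, 1.0]])
        cov = np.linalg.inv(omega)
        z = rng.multivariate_normal(np.zeros(3), cov, size=400)
        probs = np.exp(z - z.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        counts = pd.DataFrame(
            np.vstack([rng.multinomial(20000, p) for p in probs]),
            columns=list("abc"),
        )
        S = np.cov(clr(counts).to_numpy(), rowvar=False)
        lam = 0.3 * np.abs(S - np.diag(np.diag(S))).max()
        _, ours = _glasso_support(S, lam)

        def objective(flat):
            P = flat.reshape(3, 3)
            P = (P + P.T) / 2
            if np.linalg.eigvalsh(P).min() <= 1e-8:
                return 1e8
            off = P - np.diag(np.diag(P))
            return (
                -np.log(np.linalg.det(P)) + np.trace(S @ P) + lam * np.abs(off).sum()
            )

        res = minimize(objective, np.diag(1 / np.diag(S)).ravel(),
                       method="Nelder-Mead",
                       options={"maxiter": 40000, "xatol": 1e-9, "fatol": 1e-12})
        direct = res.x.reshape(3, 3)
        direct = (direct + direct.T) / 2
        assert np.allclose(ours, direct, atol=0.02)
        assert np.array_equal(
            np.abs(direct - np.diag(np.diag(direct))) > 5e-3,
            np.abs(ours - np.diag(np.diag(ours))) > 5e-3,
        )

    def test_rejects_tiny_inputs(self):
        counts = pd.DataFrame(np.ones((5, 5)))
        with pytest.raises(ValueError):
            infer_network(counts)
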