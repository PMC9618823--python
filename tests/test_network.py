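"""Correlation networks, quantile thresholding, intersection, DN subtraction."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dnet import (
    DegenerateInputError,
    build_network,
    correlation_matrix,
    differential_network,
    intersect_networks,
)


def _corr(labels, pairs):
    """Symmetric unit-diagonal correlation matrix from a pair->r mapping."""
    n = len(labels)
    m = pd.DataFrame(np.eye(n), index=labels, columns=labels)
    for (a, b), r in pairs.items():
        m.loc[a, b] = m.loc[b, a] = r
    return m


class TestCorrelationMatrix:
    def test_perfect_linear_relation(self):
        m = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8]], index=["x", "y"],
                         columns=list("abcd"))
        c = correlation_matrix(m)
        assert c.loc["x", "y"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        m = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["x", "y"], columns=list("abc"))
        assert correlation_matrix(m).loc["x", "y"] == pytest.approx(-1.0)

    def test_independent_series_mean_near_zero(self):
        rng = np.random.default_rng(42)
        m = pd.DataFrame(rng.normal(10, 1, (100, 24)),
                         index=[f"g{i}" for i in range(100)],
                         columns=[f"t{j}" for j in range(24)])
        c = correlation_matrix(m).to_numpy()
        vals = c[np.triu_indices(100, k=1)]
        assert len(vals) > 1000
        assert abs(vals.mean()) < 0.05

    def test_zero_variance_row_rejected(self):
        m = pd.DataFrame([[1, 1, 1], [1, 2, 3]], index=["flat", "g"],
                         columns=list("abc"))
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(m)


class TestBuildNetwork:
    def test_three_gene_median_threshold(self):
        c = _corr(list("ABC"), {("A", "B"): 0.99, ("A", "C"): 0.10, ("B", "C"): 0.05})
        G = build_network(c, quantile=0.5)
        assert G.graph["threshold"] == pytest.approx(0.10)
        assert set(map(frozenset, G.edges())) == {frozenset("AB"), frozenset("AC")}
        assert "C" in G  # incident to AC, not a singleton

    def test_top_quantile_on_distinct_values_keeps_rank_counted_edges(self):
        # 210 distinct pair values: the 0.995 quantile interpolates at rank
        # 0.995*(210-1) = 207.955, strictly between the 208th and 209th order
        # statistics, so exactly the top two values pass the >= cutoff.
        rng = np.random.default_rng(0)
        n = 21
        vals = rng.permutation(np.linspace(-0.9, 0.9, n * (n - 1) // 2))
        labels = [f"g{i}" for i in range(n)]
        c = pd.DataFrame(np.eye(n), index=labels, columns=labels)
        iu, ju = np.triu_indices(n, k=1)
        for (i, j), v in zip(zip(iu, ju), vals):
            c.iloc[i, j] = c.iloc[j, i] = v
        G = build_network(c, quantile=0.995)
        assert G.number_of_edges() == 2
        top = sorted((d["weight"] for _, _, d in G.edges(data=True)), reverse=True)
        assert top == pytest.approx(sorted(vals)[-2:][::-1])

    def test_singleton_nodes_excluded(self):
        c = _corr(list("ABCD"), {("A", "B"): 0.9, ("A", "C"): 0.1, ("B", "C"): 0.2,
                                 ("A", "D"): -0.5, ("B", "D"): -0.4, ("C", "D"): -0.3})
        G = build_network(c, quantile=0.9)
        assert "D" not in G

    def test_identical_correlations_degenerate(self):
        c = _corr(list("ABC"), {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5})
        with pytest.raises(DegenerateInputError):
            build_network(c)

    def test_determinism(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(30, 10)),
                         index=[f"g{i}" for i in range(30)],
                         columns=[f"t{j}" for j in range(10)])
        c = correlation_matrix(m)
        g1, g2 = build_network(c, 0.9), build_network(c, 0.9)
        assert nx.utils.graphs_equal(g1, g2)

    def test_retains_at_most_tail_fraction_plus_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(10, 40)
            m = pd.DataFrame(rng.normal(size=(n, 8)),
                             index=[f"g{i}" for i in range(n)],
                             columns=[f"t{j}" for j in range(8)])
            c = correlation_matrix(m)
            G = build_network(c, 0.995)
            n_pairs = n * (n - 1) // 2
            vals = c.to_numpy()[np.triu_indices(n, k=1)]
            ties = int((vals == G.graph["threshold"]).sum())
            assert G.number_of_edges() <= int(np.ceil(0.005 * n_pairs)) + ties


class TestIntersect:
    def test_self_intersection_is_identity(self):
        a = nx.Graph()
        a.add_edge("A", "B", weight=0.9)
        a.add_edge("B", "C", weight=0.8)
        r = intersect_networks(a, a)
        assert nx.utils.graphs_equal(r, a)

    def test_disjoint_edge_sets_give_empty_network(self):
        a, b = nx.Graph(), nx.Graph()
        a.add_edge("A", "B", weight=0.9)
        b.add_edge("C", "D", weight=0.9)
        assert intersect_networks(a, b).number_of_edges() == 0

    def test_weights_averaged_and_singletons_dropped(self):
        a, b = nx.Graph(), nx.Graph()
        a.add_edge("A", "B", weight=0.9)
        a.add_edge("B", "C", weight=0.8)
        b.add_edge("A", "B", weight=0.7)
        r = intersect_networks(a, b)
        assert set(r.nodes()) == {"A", "B"}
        assert r["A"]["B"]["weight"] == pytest.approx(0.8)

    def test_commutative_in_edge_membership(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(1e6)))
            b = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(1e6)))
            nx.set_edge_attributes(a, 0.5, "weight")
            nx.set_edge_attributes(b, 0.7, "weight")
            ab = intersect_networks(a, b)
            ba = intersect_networks(b, a)
            assert set(map(frozenset, ab.edges())) == set(map(frozenset, ba.edges()))


class TestDifferentialNetwork:
    def test_basic_subtraction(self):
        t, u = nx.Graph(), nx.Graph()
        t.add_edge("A", "B", weight=0.9)
        t.add_edge("B", "C", weight=0.8)
        u.add_edge("B", "C", weight=0.6)
        dn = differential_network(t, u)
        assert set(map(frozenset, dn.edges())) == {frozenset("AB")}
        assert set(dn.nodes()) == {"A", "B"}
        assert dn["A"]["B"]["weight"] == pytest.approx(0.9)  # treated weight kept

    def test_identical_networks_give_empty_dn(self):
        t = nx.Graph([("A", "B"), ("B", "C")])
        assert differential_network(t, t.copy()).number_of_edges() == 0

    def test_matches_bruteforce_set_difference_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(10, 50))
            t = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1e6)))
            u = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1e6)))
            nx.set_edge_attributes(t, 0.9, "weight")
            nx.set_edge_attributes(u, 0.9, "weight")
            dn = differential_network(t, u)
            expected = set()
            for a, b in itertools.combinations(range(n), 2):
                if t.has_edge(a, b) and not u.has_edge(a, b):
                    expected.add(frozenset((a, b)))
            got = set(map(frozenset, dn.edges()))
            assert got == expected
            assert all(dn.degree(v) >= 1 for v in dn.nodes())
            # invariant: DN edges disjoint from untreated, subset of treated
            assert not any(u.has_edge(*e) for e in dn.edges())
            assert all(t.has_edge(*e) for e in dn.edges())
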