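import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ripnet.core_io import AbundanceTable, ValidationError
from ripnet.conet import (
    build_network,
    compare_robustness,
    detect_modules,
    modularity_q,
    natural_connectivity,
    network_metrics,
    robustness_curve,
    spearman_filtered,
    zipi_roles,
)


def _table(rows: dict, groups="G"):
    c = pd.DataFrame(rows).T
    c.columns = [f"s{i}" for i in range(c.shape[1])]
    return AbundanceTable(
        counts=c,
        taxonomy=pd.Series("U", index=c.index),
        groups=pd.Series(groups, index=c.columns),
    )


class TestSpearmanFiltered:
    def test_perfect_monotone_pair_retained_positive(self):
        up = list(range(1, 9))
        t = _table({"a": up, "b": [2 * v for v in up], "noise": [3, 1, 4, 1, 5, 9, 2, 6]})
        edges = spearman_filtered(t, r_min=0.6, alpha=0.05)
        pair = edges[(edges.source == "a") & (edges.target == "b")]
        assert len(pair) == 1
        assert pair.iloc[0]["spearman_r"] == pytest.approx(1.0)
        assert pair.iloc[0]["sign"] == "+"
        assert pair.iloc[0]["p"] == np.finfo(float).tiny  # |rho|=1 convention

    def test_anti_monotone_pair_negative_sign(self):
        up = list(range(1, 9))
        t = _table({"a": up, "b": up[::-1]})
        edges = spearman_filtered(t, r_min=0.6, alpha=0.05)
        assert len(edges) == 1
        assert edges.iloc[0]["spearman_r"] == pytest.approx(-1.0)
        assert edges.iloc[0]["sign"] == "-"

    def test_moderate_correlation_fails_r_min(self):
        # rho = 0.5 < 0.6 must be excluded regardless of p
        a = [1, 2, 3, 4, 5, 6, 7, 8]
        b = [1, 2, 4, 6, 7, 8, 5, 3]
        t = _table({"a": a, "b": b})
        from scipy.stats import spearmanr

        rho = spearmanr(a, b).statistic
        assert abs(rho) < 0.6
        edges = spearman_filtered(t, r_min=0.6, alpha=0.99)
        assert len(edges) == 0

    def test_constant_taxon_skipped(self):
        up = list(range(1, 9))
        t = _table({"a": up, "flat": [5] * 8})
        edges = spearman_filtered(t, r_min=0.1, alpha=0.99)
        assert "flat" not in set(edges.source) | set(edges.target)

    def test_too_few_samples_rejected(self):
        t = _table({"a": [1, 2, 3], "b": [1, 2, 3]})
        with pytest.raises(ValidationError, match="4 samples"):
            spearman_filtered(t)

    def test_matches_scipy_pvalues(self):
        rng = np.random.default_rng(0)
        t = _table({f"t{i}": rng.integers(1, 100, 12) for i in range(6)})
        edges = spearman_filtered(t, r_min=1e-9, alpha=1 - 1e-9)
        from scipy.stats import spearmanr

        for row in edges.itertuples():
            x = t.counts.loc[row.source].to_numpy()
            y = t.counts.loc[row.target].to_numpy()
            ref = spearmanr(x, y)
            assert row.spearman_r == pytest.approx(ref.statistic, abs=1e-10)
            assert row.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestBuildNetwork:
    def test_triangle(self):
        edges = pd.DataFrame(
            {"source": ["a", "b", "c"], "target": ["b", "c", "a"],
             "spearman_r": [0.9, 0.8, -0.7], "p": [0.01] * 3, "sign": ["+", "+", "-"]}
        )
        g = build_network(edges)
        assert sorted(d for _, d in g.degree()) == [2, 2, 2]

    def test_empty_edge_list(self):
        g = build_network(pd.DataFrame(columns=["source", "target", "spearman_r", "p", "sign"]))
        m = network_metrics(g)
        assert m.n_nodes == 0 and m.n_edges == 0

    def test_duplicate_pair_deduplicated(self):
        edges = pd.DataFrame(
            {"source": ["a", "a"], "target": ["b", "b"],
             "spearman_r": [0.9, 0.8], "p": [0.01, 0.02], "sign": ["+", "+"]}
        )
        g = build_network(edges)
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["spearman_r"] == 0.9


class TestNetworkMetrics:
    def test_triangle_complete(self):
        m = network_metrics(nx.complete_graph(3))
        assert (m.n_nodes, m.n_edges) == (3, 3)
        assert m.average_degree == pytest.approx(2.0)
        assert m.density == pytest.approx(1.0)
        assert m.clustering == pytest.approx(1.0)

    def test_path_three_nodes(self):
        m = network_metrics(nx.path_graph(3))
        assert m.clustering == pytest.approx(0.0)
        assert m.density == pytest.approx(2 / 3)

    def test_star_k14(self):
        m = network_metrics(nx.star_graph(4))  # K_{1,4}: 5 nodes, 4 edges
        assert m.average_degree == pytest.approx(8 / 5)
        assert m.clustering == pytest.approx(0.0)


class TestModules:
    def test_two_disconnected_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        part, q = detect_modules(g, seed=0)
        assert len(set(part.values())) == 2
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_bridged_triangles_hand_modularity(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        g.add_edge(0, 3)  # bridge -> 7 edges
        planted = {n: 0 if n < 3 else 1 for n in g.nodes}
        assert modularity_q(g, planted) == pytest.approx(5 / 14, abs=1e-12)

    def test_complete_graph_no_structure(self):
        g = nx.complete_graph(6)
        part, q = detect_modules(g, seed=0)
        # any split of a complete graph has Q <= 0
        assert q <= 1e-12
        split = {n: n % 2 for n in g.nodes}
        assert modularity_q(g, split) < 0

    def test_q_matches_hand_formula_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for k in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            part, q = detect_modules(g, seed=k)
            assert q == pytest.approx(modularity_q(g, part), abs=1e-12)

    def test_empty_graph(self):
        part, q = detect_modules(nx.Graph(), seed=0)
        assert part == {} and q is None


class TestZiPi:
    def test_all_links_internal_gives_pi_zero(self):
        g = nx.complete_graph(4)
        modules = {n: 0 for n in g.nodes}
        z = zipi_roles(g, modules)
        assert (z["Pi"] == 0).all()

    def test_bridge_node_pi(self):
        # node with k=3: 2 in-module, 1 out -> Pi = 1 - (4/9 + 1/9) = 4/9
        g = nx.Graph([(0, 1), (0, 2), (0, 3)])
        modules = {0: 0, 1: 0, 2: 0, 3: 1}
        z = zipi_roles(g, modules)
        assert z.loc[0, "Pi"] == pytest.approx(4 / 9, abs=1e-12)
        assert z.loc[1, "Pi"] == 0.0

    def test_equal_within_degree_gives_zero_zi(self):
        g = nx.cycle_graph(4)
        modules = {n: 0 for n in g.nodes}
        z = zipi_roles(g, modules)
        assert (z["Zi"] == 0).all()
        assert (z["role"] == "peripheral").all()

    def test_roles_partition_exhaustively(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(30, 0.2, seed=5)
        part, _ = detect_modules(g, seed=0)
        z = zipi_roles(g, part)
        assert len(z) == g.number_of_nodes()
        assert set(z["role"]) <= {"peripheral", "connector", "module hub", "network hub"}
        # threshold cells are exclusive by construction: re-derive from Zi/Pi
        for _, row in z.iterrows():
            expect = (
                ("network hub" if row.Pi >= 0.62 else "module hub")
                if row.Zi >= 2.5
                else ("connector" if row.Pi >= 0.62 else "peripheral")
            )
            assert row.role == expect

    def test_degree_bookkeeping_conserved(self):
        g = nx.gnp_random_graph(25, 0.15, seed=3)
        part, _ = detect_modules(g, seed=0)
        # sum over modules of links equals degree, so Pi in [0, 1)
        z = zipi_roles(g, part)
        assert ((z["Pi"] >= 0) & (z["Pi"] < 1)).all()


class TestNaturalConnectivity:
    def test_edgeless_graph_zero(self):
        g = nx.empty_graph(7)
        assert natural_connectivity(g) == 0.0

    def test_triangle_closed_form(self):
        # spectrum {2, -1, -1}
        expect = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
        assert natural_connectivity(nx.complete_graph(3)) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.9963, abs=5e-5)

    def test_path_three_closed_form(self):
        # spectrum {sqrt2, 0, -sqrt2}
        s = np.sqrt(2)
        expect = np.log((np.exp(s) + 1 + np.exp(-s)) / 3)
        assert natural_connectivity(nx.path_graph(3)) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.5797, abs=5e-5)
        assert natural_connectivity(nx.complete_graph(3)) > expect

    def test_brute_force_oracle_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            g = nx.gnp_random_graph(n, float(rng.uniform(0, 0.6)),
                                    seed=int(rng.integers(1e6)))
            a = nx.to_numpy_array(g)
            lam = np.linalg.eigvals(a).real  # independent dense route
            expect = np.log(np.exp(lam).mean())
            got = natural_connectivity(g)
            assert got == pytest.approx(expect, abs=1e-10)
            assert got >= -1e-12  # Jensen bound

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(8)
        for k in range(20):
            g = nx.gnp_random_graph(10, 0.3, seed=k)
            before = natural_connectivity(g)
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            u, v = non_edges[int(rng.integers(len(non_edges)))]
            g.add_edge(u, v)
            assert natural_connectivity(g) >= before - 1e-12


class TestRobustness:
    def test_no_removal_limit(self):
        g = nx.complete_graph(8)
        base = natural_connectivity(g)
        curve = robustness_curve(g, fractions=[0.1], reps=3, seed=0)
        assert curve.points["lambda_bar"].max() <= base + 1e-12

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(15, 0.3, seed=1)
        c1 = robustness_curve(g, fractions=[0.2, 0.4], reps=1, seed=5)
        c2 = robustness_curve(g, fractions=[0.2, 0.4], reps=1, seed=5)
        pd.testing.assert_frame_equal(c1.points, c2.points)
        assert c1.slope == c2.slope

    def test_full_removal_rejected(self):
        g = nx.complete_graph(4)
        with pytest.raises(ValidationError, match="every node"):
            robustness_curve(g, fractions=[0.99], reps=1, seed=0)

    def test_dense_graph_has_steeper_absolute_decline_than_tree(self):
        # lambda_bar of K_n is ~n-1-ln(n), so a complete graph starts far
        # higher and loses far more connectivity per removed fraction than
        # a tree whose spectrum is bounded; the ordering holds in raw and
        # in relative (lambda_bar / initial) terms
        fr = [0.1, 0.3, 0.5]
        steeper = 0
        for seed in range(20):
            k12 = robustness_curve(nx.complete_graph(12), fr, reps=10, seed=seed)
            tree = robustness_curve(nx.random_labeled_tree(12, seed=seed),
                                    fr, reps=10, seed=seed)
            steeper += k12.slope < tree.slope
        assert steeper >= 19

    def test_identical_curves_no_difference(self):
        g = nx.gnp_random_graph(15, 0.4, seed=2)
        c = robustness_curve(g, fractions=[0.1, 0.3, 0.5], reps=10, seed=3)
        res = compare_robustness(c, c)
        assert res.delta_slope == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_single_fraction_slope_unidentifiable(self):
        g = nx.complete_graph(10)
        c = robustness_curve(g, fractions=[0.2], reps=5, seed=0)
        with pytest.raises(ValidationError, match="not identifiable"):
            compare_robustness(c, c)
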