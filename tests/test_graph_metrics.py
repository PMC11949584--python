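import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from calltif import (
    NodePartition,
    SummaryGraph,
    TimeSeriesPanel,
    degree_and_flow,
    evaluate,
    functional_graph,
    group_average,
    group_intersection,
    lag_contribution,
    subnetwork_graph,
)


def edges_to_adj(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = 1
    return a


def int_to_adj(n, bits):
    """Enumerate digraphs: bit k of `bits` is entry (k // n, k % n)."""
    a = np.zeros((n, n), dtype=np.int8)
    for k in range(n * n):
        if (bits >> k) & 1:
            a[k // n, k % n] = 1
    return a


def brute_force_evaluate(t, p):
    """Loop-based confusion counts over every ordered pair and every
    unordered pair; independent of the vectorized implementation."""
    n = t.shape[0]
    tp = fp = fn = tn = 0
    for i in range(n):
        for j in range(n):
            if t[i, j] and p[i, j]:
                tp += 1
            elif not t[i, j] and p[i, j]:
                fp += 1
            elif t[i, j] and not p[i, j]:
                fn += 1
            else:
                tn += 1
    tpa = fpa = fna = tna = 0
    for i in range(n):
        for j in range(i + 1, n):
            tt = t[i, j] or t[j, i]
            pp = p[i, j] or p[j, i]
            if tt and pp:
                tpa += 1
            elif not tt and pp:
                fpa += 1
            elif tt and not pp:
                fna += 1
            else:
                tna += 1
    return (tp, fp, fn, tn), (tpa, fpa, fna, tna)


def brute_force_degree_flow(a):
    n = a.shape[0]
    deg = np.zeros(n)
    flow = np.zeros(n)
    for i in range(n):
        out_i = sum(a[i, j] for j in range(n))
        in_i = sum(a[j, i] for j in range(n))
        deg[i] = (out_i + in_i) / n
        flow[i] = (out_i - in_i) / n
    return deg, flow


class TestEvaluate:
    def test_perfect_prediction(self):
        t = edges_to_adj(3, [(0, 1), (1, 2), (2, 2)])
        rep = evaluate(t, t)
        assert rep.f1_directed == 1.0
        assert rep.f1_adjacency == 1.0
        assert rep.precision_directed == rep.recall_adjacency == 1.0

    def test_empty_prediction(self):
        t = edges_to_adj(3, [(0, 1)])
        rep = evaluate(t, np.zeros((3, 3)))
        assert rep.recall_directed == 0.0
        assert rep.f1_directed == 0.0
        assert rep.f1_adjacency == 0.0

    def test_hand_enumerated_example(self):
        # truth {1->2, 2->3, 3->1, 1->1}, predicted {1->2, 2->3, 2->1}
        t = edges_to_adj(3, [(0, 1), (1, 2), (2, 0), (0, 0)])
        p = edges_to_adj(3, [(0, 1), (1, 2), (1, 0)])
        rep = evaluate(t, p)
        assert rep.counts_directed[:3] == (2, 1, 2)
        assert rep.precision_directed == pytest.approx(2 / 3)
        assert rep.recall_directed == pytest.approx(1 / 2)
        assert rep.f1_directed == pytest.approx(4 / 7)
        assert rep.counts_adjacency[:3] == (2, 0, 1)
        assert rep.f1_adjacency == pytest.approx(0.8)

    def test_node_set_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_exhaustive_two_node_pairs(self):
        for bt in range(16):
            for bp in range(16):
                t, p = int_to_adj(2, bt), int_to_adj(2, bp)
                rep = evaluate(t, p)
                cd, ca = brute_force_evaluate(t, p)
                assert rep.counts_directed == cd
                assert rep.counts_adjacency == ca

    def test_sampled_three_four_node_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = int(rng.integers(3, 5))
            t = int_to_adj(n, int(rng.integers(0, 2 ** (n * n))))
            p = int_to_adj(n, int(rng.integers(0, 2 ** (n * n))))
            rep = evaluate(t, p)
            cd, ca = brute_force_evaluate(t, p)
            assert rep.counts_directed == cd
            assert rep.counts_adjacency == ca

    def test_collapse_commutes_with_relabeling(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = 5
            t = (rng.random((n, n)) < 0.3).astype(np.int8)
            p = (rng.random((n, n)) < 0.3).astype(np.int8)
            perm = rng.permutation(n)
            r1 = evaluate(t, p)
            r2 = evaluate(t[np.ix_(perm, perm)], p[np.ix_(perm, perm)])
            assert r1.counts_directed == r2.counts_directed
            assert r1.counts_adjacency == r2.counts_adjacency


class TestDegreeAndFlow:
    def test_isolated_node(self):
        deg, flow = degree_and_flow(np.zeros((4, 4)))
        assert np.all(deg == 0) and np.all(flow == 0)

    def test_direct_formula(self):
        a = np.zeros((10, 10))
        a[0, [1, 2, 3]] = 1  # 3 out
        a[4, 0] = 1          # 1 in
        deg, flow = degree_and_flow(a)
        assert deg[0] == pytest.approx(0.4)
        assert flow[0] == pytest.approx(0.2)

    def test_exhaustive_three_node(self):
        for bits in range(512):
            a = int_to_adj(3, bits)
            deg, flow = degree_and_flow(a)
            bd, bf = brute_force_degree_flow(a)
            assert np.allclose(deg, bd) and np.allclose(flow, bf)

    def test_exhaustive_four_node(self):
        for bits in range(65536):
            a = int_to_adj(4, bits)
            deg, flow = degree_and_flow(a)
            bd, bf = brute_force_degree_flow(a)
            assert np.array_equal(deg, bd) and np.array_equal(flow, bf)
            assert flow.sum() == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(arrays(float, (6, 6), elements=st.floats(-5, 5)))
    def test_flow_conservation_weighted(self, a):
        _, flow = degree_and_flow(a)
        assert abs(flow.sum()) < 1e-9


class TestSubnetworkGraph:
    def part(self):
        return NodePartition({
            "a0": ("A", "L"), "a1": ("A", "L"),
            "b0": ("B", "R"), "b1": ("B", "R"), "b2": ("B", "R"),
        })

    def test_complete_bipartite(self):
        labels = ["a0", "a1", "b0", "b1", "b2"]
        a = np.zeros((5, 5))
        a[0:2, 2:5] = 1  # every A node to every B node
        w, subs = subnetwork_graph(a, self.part(), node_labels=labels)
        ia, ib = subs.index("A"), subs.index("B")
        assert w[ia, ib] == 1.0
        assert w[ib, ia] == 0.0

    def test_half_of_pairs(self):
        labels = ["a0", "a1", "b0", "b1", "b2"]
        a = np.zeros((5, 5))
        a[0, 2] = a[0, 3] = a[1, 4] = 1  # 3 of the 6 A->B pairs
        w, subs = subnetwork_graph(a, self.part(), node_labels=labels)
        assert w[subs.index("A"), subs.index("B")] == 0.5

    def test_threshold_removal(self):
        labels = ["a0", "a1", "b0", "b1", "b2"]
        a = np.zeros((5, 5))
        a[0, 2] = a[0, 3] = a[1, 4] = 1  # weight 0.5
        a[2, 0] = 1                      # B->A weight 1/6
        w, subs = subnetwork_graph(a, self.part(), node_labels=labels,
                                   threshold=0.5)
        ia, ib = subs.index("A"), subs.index("B")
        assert w[ia, ib] == 0.5  # kept (not strictly below)
        assert w[ib, ia] == 0.0  # removed

    def test_diagonal_normalization_excludes_self(self):
        labels = ["a0", "a1"]
        part = NodePartition({"a0": ("A", "L"), "a1": ("A", "L")})
        a = np.array([[1, 1], [0, 1]])  # self-loops must not count
        w, subs = subnetwork_graph(a, part, node_labels=labels)
        assert w[0, 0] == pytest.approx(1 / 2)  # 1 of |A|(|A|-1)=2 pairs

    def test_missing_node_in_partition(self):
        part = NodePartition({"a0": ("A", "L")})
        with pytest.raises(ValueError, match="missing"):
            subnetwork_graph(np.zeros((2, 2)), part, node_labels=["a0", "x"])

    def test_brute_force_random_graphs(self):
        rng = np.random.default_rng(7)
        labels = ["a0", "a1", "b0", "b1", "b2"]
        part = self.part()
        members = {"A": [0, 1], "B": [2, 3, 4]}
        for _ in range(100):
            a = (rng.random((5, 5)) < 0.4).astype(np.int8)
            w, subs = subnetwork_graph(a, part, node_labels=labels)
            for s1, s2 in itertools.product(("A", "B"), repeat=2):
                count = sum(a[u, v] for u in members[s1] for v in members[s2]
                            if u != v)
                poss = (len(members[s1]) * (len(members[s1]) - 1)
                        if s1 == s2
                        else len(members[s1]) * len(members[s2]))
                assert w[subs.index(s1), subs.index(s2)] == pytest.approx(
                    count / poss
                )


class TestGroupGraphs:
    def test_identical_graphs(self):
        g = edges_to_adj(3, [(0, 1), (2, 0)])
        assert np.array_equal(group_average([g, g, g]), g)
        assert np.array_equal(group_intersection([g, g, g]), g)

    def test_shared_edge_only(self):
        g1 = edges_to_adj(3, [(0, 1), (1, 2)])
        g2 = edges_to_adj(3, [(0, 1), (2, 0)])
        inter = group_intersection([g1, g2])
        assert inter[0, 1] == 1 and inter.sum() == 1

    def test_three_of_four(self):
        gs = [edges_to_adj(2, [(0, 1)])] * 3 + [edges_to_adj(2, [])]
        avg = group_average(gs)
        assert avg[0, 1] == 0.75
        assert group_intersection(gs)[0, 1] == 0

    def test_mismatched_sizes(self):
        with pytest.raises(ValueError, match="mismatch"):
            group_average([np.zeros((2, 2)), np.zeros((3, 3))])


class TestFunctionalGraph:
    def test_duplicated_column(self, rng):
        x = rng.standard_normal((50, 1))
        panel = TimeSeriesPanel(np.hstack([x, x, rng.standard_normal((50, 1))]),
                                ["a", "b", "c"])
        fg = functional_graph(panel, alpha=0.01)
        assert fg[0, 1] == 1 and fg[1, 0] == 1

    def test_null_calibration(self):
        hits = total = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            panel = TimeSeriesPanel(r.standard_normal((200, 6)),
                                    [f"n{i}" for i in range(6)])
            fg = functional_graph(panel, alpha=0.01)
            iu = np.triu_indices(6, k=1)
            hits += int(fg[iu].sum())
            total += len(iu[0])
        assert hits / total == pytest.approx(0.01, abs=0.01)

    def test_alpha_zero_empty(self, rng):
        panel = TimeSeriesPanel(rng.standard_normal((50, 4)), list("abcd"))
        assert functional_graph(panel, alpha=0.0).sum() == 0

    def test_constant_column_warns_and_isolated(self, rng):
        x = rng.standard_normal((50, 3))
        x[:, 1] = 2.0
        panel = TimeSeriesPanel(x, ["a", "b", "c"])
        with pytest.warns(UserWarning, match="constant"):
            fg = functional_graph(panel)
        assert fg[1].sum() == 0 and fg[:, 1].sum() == 0


def make_summary(n, tau_max, provenance_edges):
    prov = np.zeros((n, n, tau_max + 1), dtype=bool)
    for i, j, taus in provenance_edges:
        for tau in taus:
            prov[i, j, tau] = True
    adj = prov.any(axis=2).astype(np.int8)
    return SummaryGraph(adjacency=adj, strength=np.ones((n, n)),
                        lag_provenance=prov,
                        node_labels=[f"n{i}" for i in range(n)],
                        alpha_level=0.01)


class TestLagContribution:
    def test_all_lag0(self):
        g = make_summary(3, 2, [(0, 1, [0]), (1, 2, [0])])
        assert np.array_equal(lag_contribution(g), [100.0, 0.0, 0.0])

    def test_mixed_shares(self):
        # 10 edges: 7 only-lag-0, 2 only-lag-1, 1 multi-lag
        edges = [(i, (i + 1) % 4, [0]) for i in range(4)]
        edges += [(0, 2, [0]), (1, 3, [0]), (2, 0, [0])]
        edges += [(3, 1, [1]), (0, 3, [1])]
        edges += [(1, 0, [0, 1])]
        g = make_summary(4, 1, edges)
        shares = lag_contribution(g)
        assert shares[0] == pytest.approx(70.0)
        assert shares[1] == pytest.approx(20.0)
        assert shares.sum() == pytest.approx(90.0)  # 10% multi-lag

    def test_empty_graph_warns(self):
        g = make_summary(3, 2, [])
        with pytest.warns(UserWarning, match="empty"):
            shares = lag_contribution(g)
        assert np.all(shares == 0.0)

    def test_shares_sum_at_most_100(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            prov = rng.random((4, 4, 3)) < 0.3
            adj = prov.any(axis=2).astype(np.int8)
            if adj.sum() == 0:
                continue
            g = SummaryGraph(adjacency=adj, strength=np.ones((4, 4)),
                             lag_provenance=prov, node_labels=list("abcd"),
                             alpha_level=0.01)
            assert lag_contribution(g).sum() <= 100.0 + 1e-9

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            prov = rng.random((4, 4, 3)) < 0.35
            adj = prov.any(axis=2).astype(np.int8)
            if adj.sum() == 0:
                continue
            g = SummaryGraph(adjacency=adj, strength=np.ones((4, 4)),
                             lag_provenance=prov, node_labels=list("abcd"),
                             alpha_level=0.01)
            shares = lag_contribution(g)
            for tau in range(3):
                only = sum(
                    1
                    for i in range(4)
                    for j in range(4)
                    if prov[i, j, tau] and prov[i, j].sum() == 1
                )
                assert shares[tau] == pytest.approx(100 * only / adj.sum())
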