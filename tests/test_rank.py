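import math

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from dnrs import (
    ExpressionMatrix,
    PPINetwork,
    StageSeries,
    TransitionSystem,
    build_transition_system,
    classical_pagerank,
    global_dnrs,
    personalized_pagerank,
    random_transition_system,
    stage_rank,
)
from dnrs.network import DirectedStageNetwork


def dense_solve(ts: TransitionSystem) -> np.ndarray:
    """Independent linear-solve oracle: (I - a H' - a tau d') s = (1-a) tau."""
    H = ts.H.toarray()
    k = ts.k
    A = np.eye(k) - ts.alpha * H.T - ts.alpha * np.outer(ts.tau, ts.d)
    return np.linalg.solve(A, (1 - ts.alpha) * ts.tau)


def _net_from_edges(genes, edges, label="t"):
    g = nx.DiGraph()
    g.add_nodes_from(genes)
    for u, v, w in edges:
        g.add_edge(u, v, w=w)
    return DirectedStageNetwork(label, list(genes), g)


class TestBuildTransitionSystem:
    genes = ["A", "B", "C"]

    def _expr(self, values=None):
        rng = np.random.default_rng(0)
        return ExpressionMatrix(
            self.genes, values if values is not None else rng.random((3, 5)), "t"
        )

    def test_row_normalization(self):
        net = _net_from_edges(self.genes, [("A", "B", 2.0), ("A", "C", 2.0)])
        ts = build_transition_system(net, self._expr())
        np.testing.assert_allclose(ts.H.toarray()[0], [0.0, 0.5, 0.5])
        assert ts.d[0] == 0.0
        ts.validate_rows()

    def test_isolated_node_is_dangling_zero_row(self):
        net = _net_from_edges(self.genes, [("A", "B", 1.0)])
        ts = build_transition_system(net, self._expr())
        assert ts.d.tolist() == [0.0, 1.0, 1.0]
        np.testing.assert_array_equal(ts.H.toarray()[1], 0.0)
        np.testing.assert_array_equal(ts.H.toarray()[2], 0.0)

    def test_selfloop_variant_places_unit_selfloops(self):
        net = _net_from_edges(self.genes, [("A", "B", 1.0)])
        ts = build_transition_system(net, self._expr(), dangling="selfloop-renormalize")
        H = ts.H.toarray()
        assert H[1, 1] == 1.0 and H[2, 2] == 1.0
        assert ts.d.tolist() == [0.0, 1.0, 1.0]

    def test_constant_gene_keeps_zero_teleport_mass(self):
        values = np.vstack([np.full(5, 3.0), np.arange(5.0), np.arange(5.0) * 2])
        net = _net_from_edges(self.genes, [("A", "B", 1.0)])
        ts = build_transition_system(net, self._expr(values))
        assert ts.tau[0] == 0.0
        assert ts.tau.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_constant_falls_back_to_uniform_with_warning(self):
        values = np.ones((3, 4))
        net = _net_from_edges(self.genes, [("A", "B", 1.0)])
        with pytest.warns(UserWarning, match="uniform"):
            ts = build_transition_system(net, self._expr(values))
        np.testing.assert_allclose(ts.tau, 1 / 3)

    def test_universe_mismatch(self):
        net = _net_from_edges(["A", "B"], [("A", "B", 1.0)])
        with pytest.raises(ValueError, match="universe"):
            build_transition_system(net, self._expr())


class TestPersonalizedPagerank:
    def test_single_node(self):
        ts = TransitionSystem(sp.csr_matrix((1, 1)), [1.0], [1.0])
        np.testing.assert_allclose(personalized_pagerank(ts), [1.0])

    def test_three_node_chain_matches_linear_solve(self):
        H = sp.csr_matrix(
            np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        )
        ts = TransitionSystem(H, [0.0, 0.0, 1.0], np.full(3, 1 / 3), 0.85)
        s = personalized_pagerank(ts)
        np.testing.assert_allclose(s, dense_solve(ts), atol=1e-10)
        assert s.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_solve_on_random_systems(self, seed):
        rng = np.random.default_rng(seed)
        ts = random_transition_system(rng)
        s = personalized_pagerank(ts)
        assert np.all(s >= 0)
        assert s.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(s, dense_solve(ts), atol=1e-8)

    def test_classical_limit_and_networkx_cross_check(self):
        """With no dangling nodes and uniform teleport the iteration is
        classical PageRank on the unit-weight digraph."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            k = int(rng.integers(3, 20))
            # random strongly-connected graph: a cycle plus extras
            adj = np.zeros((k, k))
            for i in range(k):
                adj[i, (i + 1) % k] = 1.0
            extra = rng.random((k, k)) < 0.3
            np.fill_diagonal(extra, False)
            adj[extra] = 1.0
            H = adj / adj.sum(axis=1, keepdims=True)
            ts = TransitionSystem(
                sp.csr_matrix(H), np.zeros(k), np.full(k, 1 / k), 0.85
            )
            s = personalized_pagerank(ts)
            np.testing.assert_allclose(s, classical_pagerank(adj), atol=1e-10)
            g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
            nx_pr = np.array(list(nx.pagerank(g, alpha=0.85, tol=1e-12).values()))
            np.testing.assert_allclose(s, nx_pr, atol=1e-8)

    def test_mass_conserved_at_every_iterate(self):
        rng = np.random.default_rng(3)
        ts = random_transition_system(rng)
        s = ts.tau.copy()
        HT = ts.H.T.tocsr()
        for _ in range(50):
            s = ts.alpha * (HT @ s) + ts.alpha * float(ts.d @ s) * ts.tau \
                + (1 - ts.alpha) * ts.tau
            assert s.sum() == pytest.approx(1.0, abs=1e-9)

    def test_geometric_contraction(self):
        rng = np.random.default_rng(4)
        ts = random_transition_system(rng)
        s = ts.tau.copy()
        HT = ts.H.T.tocsr()
        residuals = []
        prev = s
        for _ in range(40):
            s = ts.alpha * (HT @ prev) + ts.alpha * float(ts.d @ prev) * ts.tau \
                + (1 - ts.alpha) * ts.tau
            residuals.append(float(np.abs(s - prev).sum()))
            prev = s
        for l in range(len(residuals) - 10):
            assert residuals[l + 10] <= ts.alpha**10 * residuals[l] * (1 + 1e-6)

    def test_non_convergence_reports_residual(self):
        rng = np.random.default_rng(5)
        ts = random_transition_system(rng)
        with pytest.raises(RuntimeError, match="residual"):
            personalized_pagerank(ts, tol=1e-15, max_iter=2)

    def test_selfloop_variant_still_sums_to_one(self):
        genes = ["A", "B", "C"]
        net = _net_from_edges(genes, [("A", "B", 1.0)])
        expr = ExpressionMatrix(genes, np.random.default_rng(0).random((3, 6)), "t")
        ts = build_transition_system(net, expr, dangling="selfloop-renormalize")
        s = personalized_pagerank(ts)
        assert s.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(s >= 0)

    def test_monotone_response_to_inbound_edges(self):
        """Adding an inbound edge never decreases the target's score
        (checked via the linear-solve oracle on random small graphs)."""
        rng = np.random.default_rng(6)
        for _ in range(25):
            k = int(rng.integers(3, 12))
            dense = rng.random((k, k)) * (rng.random((k, k)) < 0.4)
            np.fill_diagonal(dense, 0.0)
            tau = rng.random(k) + 0.05
            tau /= tau.sum()

            def solve(mat):
                rowsum = mat.sum(axis=1)
                dang = rowsum == 0
                H = np.where(dang[:, None], 0.0, mat / np.where(rowsum == 0, 1, rowsum)[:, None])
                ts = TransitionSystem(sp.csr_matrix(H), dang.astype(float), tau, 0.85)
                return dense_solve(ts)

            target = int(rng.integers(k))
            candidates = [i for i in range(k) if i != target and dense[i, target] == 0]
            if not candidates:
                continue
            src = candidates[0]
            before = solve(dense)[target]
            dense2 = dense.copy()
            dense2[src, target] = rng.random() + 0.1
            after = solve(dense2)[target]
            assert after >= before - 1e-12


class TestGlobalDNRS:
    def test_uniform_scores_give_exactly_one(self):
        for k in (1, 5, 18, 100):
            pr, q, _ = global_dnrs(np.full(k, 1.0 / k))
            assert pr == pytest.approx(1.0, abs=1e-12)
            assert q == max(1, math.ceil(0.05 * k))

    def test_worked_example_k20(self):
        s = np.array([0.5] + [0.5 / 19] * 19)
        pr, q, top = global_dnrs(s, 0.05, [f"g{i:02d}" for i in range(20)])
        assert q == 1
        assert pr == pytest.approx(10.0, abs=1e-12)
        assert top == ["g00"]

    def test_always_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = rng.random(int(rng.integers(1, 40)))
            s /= s.sum()
            pr, _, _ = global_dnrs(s)
            assert pr >= 1.0 - 1e-12

    def test_tie_break_lexicographic(self):
        s = np.array([0.25, 0.25, 0.25, 0.25])
        _, q, top = global_dnrs(s, 0.25, ["zz", "aa", "mm", "bb"])
        assert q == 1
        assert top == ["aa"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_dnrs(np.array([]))


class TestStageRank:
    def test_identical_stages_collapse_to_teleport_vector(self):
        """With zero edges every node is dangling and the fixed point is tau."""
        rng = np.random.default_rng(1)
        vals = rng.random((5, 8))
        genes = list("ABCDE")
        series = StageSeries(
            [ExpressionMatrix(genes, vals, "t0"), ExpressionMatrix(genes, vals.copy(), "t1")]
        )
        ppi = PPINetwork.from_pairs([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        rr = stage_rank(series, ppi, 1)
        tau = np.std(vals, axis=1)
        tau /= tau.sum()
        np.testing.assert_allclose(rr.s_star, tau, atol=1e-9)
        assert rr.n_edges == 0

    def test_gene_order_invariance(self, single_trial_sweep):
        series, ppi, truth = single_trial_sweep
        t = truth.bifurcation_index
        rr = stage_rank(series, ppi, t)
        perm = np.random.default_rng(2).permutation(len(series.gene_ids))
        genes_p = [series.gene_ids[i] for i in perm]
        series_p = StageSeries(
            [
                ExpressionMatrix(genes_p, m.values[perm], m.stage_label)
                for m in series.stages
            ]
        )
        rr_p = stage_rank(series_p, ppi, t)
        assert rr_p.pr == pytest.approx(rr.pr, rel=1e-9)
        assert sorted(rr_p.signaling_genes) == sorted(rr.signaling_genes)

    def test_deterministic(self, single_trial_sweep):
        series, ppi, truth = single_trial_sweep
        a = stage_rank(series, ppi, 3)
        b = stage_rank(series, ppi, 3)
        np.testing.assert_array_equal(a.s_star, b.s_star)
        assert a.pr == b.pr
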