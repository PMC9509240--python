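"""Simulated-annealing subpathway search vs independent brute-force oracles."""

import dataclasses
import itertools

import networkx as nx
import numpy as np
import pytest

from pathdrp import (
    PathwayGraph,
    SAConfig,
    WeightStats,
    anneal_subpathway,
    permutation_pvalue,
    screen_subpathways,
    subpathway_score,
)

# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of connected subsets (bitmask)
# ---------------------------------------------------------------------------


def connected_subsets(graph: nx.Graph):
    """Yield every non-empty connected induced node subset (n <= ~15)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    adj = [0] * n
    for a, b in graph.edges:
        adj[idx[a]] |= 1 << idx[b]
        adj[idx[b]] |= 1 << idx[a]
    for mask in range(1, 1 << n):
        # BFS over the bitmask
        start = mask & (-mask)
        seen = start
        frontier = start
        while frontier:
            nxt = 0
            m = frontier
            while m:
                bit = m & (-m)
                m ^= bit
                nxt |= adj[bit.bit_length() - 1] & mask
            frontier = nxt & ~seen
            seen |= frontier
        if seen == mask:
            yield {nodes[i] for i in range(n) if mask >> i & 1}


def brute_force_best(graph: PathwayGraph, stats: WeightStats):
    best, best_z = None, -np.inf
    for genes in connected_subsets(graph.graph):
        z = subpathway_score(genes, graph, stats)
        if z > best_z:
            best, best_z = genes, z
    return best, best_z


def _weighted_graph(rng, n, p=0.35) -> PathwayGraph:
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    pw = PathwayGraph("t", nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
    w = np.abs(rng.standard_normal(n)) * 2
    pw.set_weights({f"n{i}": w[i] for i in range(n)})
    return pw


# ---------------------------------------------------------------------------
# scoring closed forms
# ---------------------------------------------------------------------------


class TestModuleScore:
    def _graph(self, weights):
        g = nx.path_graph(len(weights))
        pw = PathwayGraph("p", nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        pw.set_weights({f"n{i}": w for i, w in enumerate(weights)})
        return pw

    def test_all_weights_at_mean_score_zero(self):
        pw = self._graph([2.0, 2.0, 2.0, 2.0])
        stats = WeightStats(2.0, 1.0)
        for genes in (["n0"], ["n1", "n2"], ["n0", "n1", "n2", "n3"]):
            assert subpathway_score(genes, pw, stats) == pytest.approx(0.0)

    def test_single_gene_one_sd_above_mean(self):
        pw = self._graph([3.0, 1.0, 1.0])
        assert subpathway_score(["n0"], pw, WeightStats(2.0, 1.0)) == pytest.approx(1.0)

    def test_four_genes_each_one_sd_above_mean(self):
        pw = self._graph([3.0] * 4)
        # Z = 4*sigma / (sigma*sqrt(4)) = 2
        assert subpathway_score(pw.nodes, pw, WeightStats(2.0, 1.0)) == pytest.approx(2.0)

    def test_empty_set_raises(self):
        pw = self._graph([1.0, 2.0])
        with pytest.raises(ValueError, match="empty"):
            subpathway_score([], pw, WeightStats(1.0, 1.0))

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            WeightStats(1.0, 0.0)


# ---------------------------------------------------------------------------
# annealing behaviour
# ---------------------------------------------------------------------------


class TestAnneal:
    def test_planted_segment_on_path_graph_found_exactly(self):
        """6-node path with a heavy 3-node segment: SA must return exactly
        the exhaustive optimum (21 connected subsets on a 6-path)."""
        g = nx.path_graph(6)
        pw = PathwayGraph("p", nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        w = {f"n{i}": (5.0 if i in (2, 3, 4) else 0.5) for i in range(6)}
        pw.set_weights(w)
        stats = WeightStats(np.mean(list(w.values())), np.std(list(w.values())))
        oracle_genes, oracle_z = brute_force_best(pw, stats)
        genes, z = anneal_subpathway(pw, SAConfig(seed=0), stats)
        assert genes == oracle_genes == {"n2", "n3", "n4"}
        assert z == pytest.approx(oracle_z)

    def test_equal_weights_score_near_zero(self):
        g = nx.path_graph(8)
        pw = PathwayGraph("p", nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        pw.set_weights({n: 1.0 for n in pw.nodes})
        stats = WeightStats(1.0, 1.0)  # weights all at the global mean
        _, z = anneal_subpathway(pw, SAConfig(iterations=500, seed=1), stats)
        assert abs(z) < 1e-9

    def test_same_seed_identical_output(self, rng):
        pw = _weighted_graph(rng, 15)
        cfg = SAConfig(iterations=1500, seed=9)
        out1 = anneal_subpathway(pw, cfg)
        out2 = anneal_subpathway(pw, dataclasses.replace(cfg))
        assert out1 == out2

    def test_matches_exhaustive_on_small_graphs(self):
        """SA finds the global optimum on nearly all small random graphs."""
        rng = np.random.default_rng(123)
        cfg = SAConfig(iterations=3000, restarts=2)
        hits = 0
        runs = 30
        for r in range(runs):
            pw = _weighted_graph(rng, int(rng.integers(6, 11)))
            stats = WeightStats(pw.weight_array().mean(), pw.weight_array().std())
            _, oracle_z = brute_force_best(pw, stats)
            _, z = anneal_subpathway(pw, dataclasses.replace(cfg, seed=r), stats)
            assert z <= oracle_z + 1e-9  # SA can never beat the optimum
            hits += abs(z - oracle_z) < 1e-9
        assert hits >= 0.9 * runs

    def test_budget_monotonicity(self, rng):
        """Mean best Z over seeds is non-decreasing in the iteration count."""
        graphs = [_weighted_graph(rng, 18) for _ in range(5)]
        means = []
        for iters in (100, 10_000):
            zs = []
            for s, pw in enumerate(graphs):
                cfg = SAConfig(iterations=iters, restarts=1, seed=s)
                zs.append(anneal_subpathway(pw, cfg)[1])
            means.append(np.mean(zs))
        assert means[1] >= means[0] - 1e-12


class TestPermutationPvalue:
    def _setup(self, rng):
        pw = _weighted_graph(rng, 12)
        stats = WeightStats(pw.weight_array().mean(), pw.weight_array().std())
        return pw, stats

    def test_floor_when_observed_beats_all(self, rng):
        pw, stats = self._setup(rng)
        cfg = SAConfig(iterations=300, restarts=1, permutations=50, seed=3)
        p = permutation_pvalue(pw, 1e9, cfg, stats)
        assert p == pytest.approx(1 / 51)

    def test_one_when_observed_below_all(self, rng):
        pw, stats = self._setup(rng)
        cfg = SAConfig(iterations=300, restarts=1, permutations=50, seed=3)
        p = permutation_pvalue(pw, -1e9, cfg, stats)
        assert p == 1.0

    def test_null_pvalues_valid_at_matched_budget(self):
        """i.i.d. weights with the null re-annealed at the observed budget:
        p-values are stochastically >= uniform (the permutation test is
        exact when observed and permuted statistics are optimized equally
        hard; the reduced-budget default trades this for speed)."""
        rng = np.random.default_rng(77)
        cfg = SAConfig(iterations=400, restarts=1, permutations=60,
                       perm_budget_divisor=1)
        ps = []
        for r in range(20):
            pw = _weighted_graph(rng, 12)
            stats = WeightStats(pw.weight_array().mean(), pw.weight_array().std())
            genes, z = anneal_subpathway(pw, dataclasses.replace(cfg, seed=r), stats)
            ps.append(permutation_pvalue(pw, z, dataclasses.replace(cfg, seed=r), stats))
        assert np.mean(np.array(ps) <= 0.05) <= 0.15
        assert np.mean(ps) > 0.3


class TestScreening:
    def test_recovers_planted_modules(self, small_data, fast_sa):
        from pathdrp import score_all_genes

        ds, pathways, truth = small_data
        scores = score_all_genes(ds)
        subs = screen_subpathways(pathways, scores, fast_sa)
        assert 1 <= len(subs) <= fast_sa.max_subpathways
        by_id = {p.pathway_id: p for p in pathways}
        for s in subs:
            assert s.k >= fast_sa.min_genes
            assert s.p_value <= fast_sa.p_threshold
            assert nx.is_connected(by_id[s.pathway_id].graph.subgraph(s.genes))
        recovered = sum(
            len(truth.planted.get(s.pathway_id, set()) & s.genes)
            / len(truth.planted.get(s.pathway_id, s.genes) | s.genes) >= 0.5
            for s in subs if s.pathway_id in truth.planted
        )
        assert recovered >= 2

    def test_truncation_keeps_largest_z(self, small_data):
        from pathdrp import score_all_genes

        ds, pathways, _ = small_data
        scores = score_all_genes(ds)
        cfg = SAConfig(iterations=600, restarts=1, permutations=49,
                       p_threshold=1.0, max_subpathways=2, seed=4)
        all_cfg = dataclasses.replace(cfg, max_subpathways=100)
        subs_all = screen_subpathways(pathways, scores, all_cfg)
        subs_top = screen_subpathways(pathways, scores, cfg)
        assert len(subs_top) == 2
        expect = sorted((s.score for s in subs_all), reverse=True)[:2]
        assert [s.score for s in subs_top] == pytest.approx(expect)
        assert [s.rank for s in subs_top] == [0, 1]

    def test_zero_survivors_is_instructive_error(self, small_data):
        from pathdrp import score_all_genes

        ds, pathways, _ = small_data
        scores = score_all_genes(ds)
        cfg = SAConfig(iterations=200, restarts=1, permutations=10,
                       p_threshold=1e-9, seed=4)
        with pytest.raises(RuntimeError, match="relax"):
            screen_subpathways(pathways, scores, cfg)

    def test_small_best_module_filtered_by_min_genes(self):
        """A pathway whose optimum has 2 genes is excluded by the size filter."""
        # star with one hot pair far from everything else
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        pw = PathwayGraph("tiny", g)
        scores = {"a": 10.0, "b": 10.0, "c": 0.0, "d": 0.0, "e": 0.0}
        # second pathway that passes, so screening does not error out
        g2 = nx.path_graph(4)
        pw2 = PathwayGraph("ok", nx.relabel_nodes(g2, {i: f"m{i}" for i in g2.nodes}))
        scores.update({f"m{i}": 10.0 for i in range(4)})
        cfg = SAConfig(iterations=800, restarts=2, permutations=20,
                       p_threshold=1.0, seed=1)
        subs = screen_subpathways([pw, pw2], scores, cfg)
        ids = {s.pathway_id for s in subs}
        assert "ok" in ids
        # the hot 2-gene module in "tiny" is the optimum there, so the
        # pathway is dropped entirely by the size filter
        assert "tiny" not in ids
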