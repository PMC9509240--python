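"""Subpathway discovery on node-weighted pathway graphs by simulated annealing.

A subpathway is a connected set of genes within one pathway whose composite
drug-association scores are jointly higher than chance.  The module score is
the standardized sum used for active-subnetwork search,

    Z(M) = (sum_{g in M} w_g - k * mu_w) / (sigma_w * sqrt(k)),   k = |M|,

where ``mu_w``/``sigma_w`` are the global mean/sd of all composite gene
scores.  The sqrt(k) normalization keeps the score size-neutral so the
search does not trivially grow modules.

The search is Metropolis simulated annealing over connected node subsets:
a move either adds a node adjacent to the current set or removes a node
whose removal keeps the set connected, chosen uniformly over all legal
moves; worsening moves are accepted with probability exp(dZ / T) under a
geometric cooling schedule.  Significance is a permutation p-value: node
weights are shuffled within the pathway and the search re-run (at a reduced
iteration budget, which biases the null conservatively upward).

The inner loops are numba-compiled; articulation points of the induced
subgraph are tracked with an iterative lowlink pass so removal legality is
O(k + edges) per sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

from .datasets import PathwayGraph


@dataclass
class SAConfig:
    """Simulated-annealing and screening parameters."""

    iterations: int = 10_000
    t0: float = 1.0              # initial temperature
    cooling: float = 0.995       # geometric ratio, T_t = t0 * cooling**t
    restarts: int = 3
    seed: int = 0
    permutations: int = 1000     # B
    min_genes: int = 3
    p_threshold: float = 0.05
    max_subpathways: int = 17    # K retained
    perm_budget_divisor: int = 10

    def validate(self) -> None:
        if not 0 < self.cooling < 1:
            raise ValueError("cooling ratio must be in (0, 1)")
        if self.min_genes < 1 or self.permutations < 1:
            raise ValueError("min_genes and permutations must be >= 1")
        if self.iterations < 1 or self.restarts < 1:
            raise ValueError("iterations and restarts must be >= 1")


@dataclass
class Subpathway:
    """A retained connected module with its score and significance."""

    pathway_id: str
    genes: frozenset[str]
    score: float
    p_value: float
    rank: int = -1

    @property
    def k(self) -> int:
        return len(self.genes)


@dataclass
class WeightStats:
    """Global mean/sd of composite scores, the null reference for Z."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError("weight sd must be positive")

    @classmethod
    def from_scores(cls, scores) -> "WeightStats":
        vals = np.asarray(
            scores["score"] if isinstance(scores, pd.DataFrame) else list(scores.values()),
            float,
        )
        return cls(float(vals.mean()), float(vals.std()))


def subpathway_score(
    genes, graph: PathwayGraph, stats: WeightStats
) -> float:
    """Standardized-sum score Z of a gene set within a weighted pathway."""
    genes = set(genes)
    if not genes:
        raise ValueError("empty gene set")
    missing = genes - set(graph.graph.nodes)
    if missing:
        raise ValueError(f"genes not in pathway {graph.pathway_id}: {sorted(missing)}")
    k = len(genes)
    wsum = sum(graph.node_weight(g) for g in genes)
    return (wsum - k * stats.mu) / (stats.sigma * np.sqrt(k))


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed_stream(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _mark_articulation(indptr, indices, in_set, root, disc, low, parent, ptr,
                       stack, is_art):
    """Flag articulation points of the subgraph induced by ``in_set``."""
    n = len(in_set)
    for v in range(n):
        if in_set[v]:
            disc[v] = -1
            is_art[v] = False
    t = 0
    root_children = 0
    parent[root] = -1
    disc[root] = 0
    low[root] = 0
    ptr[root] = indptr[root]
    t = 1
    stack[0] = root
    sp = 1
    while sp > 0:
        v = stack[sp - 1]
        if ptr[v] < indptr[v + 1]:
            u = indices[ptr[v]]
            ptr[v] += 1
            if not in_set[u]:
                continue
            if disc[u] == -1:
                parent[u] = v
                disc[u] = t
                low[u] = t
                t += 1
                ptr[u] = indptr[u]
                stack[sp] = u
                sp += 1
                if v == root:
                    root_children += 1
            elif u != parent[v]:
                if disc[u] < low[v]:
                    low[v] = disc[u]
        else:
            sp -= 1
            p = parent[v]
            if p != -1:
                if low[v] < low[p]:
                    low[p] = low[v]
                if p != root and low[v] >= disc[p]:
                    is_art[p] = True
    if root_children > 1:
        is_art[root] = True


@njit(cache=True)
def _sa_single(indptr, indices, w, mu, sigma, n_iter, t0, cooling, start,
               in_set, best_set, add_cand, rem_cand, disc, low, parent, ptr,
               stack, is_art):
    """One annealing run from ``start``; returns best-ever Z, best_set filled."""
    n = len(w)
    for v in range(n):
        in_set[v] = False
    in_set[start] = True
    k = 1
    wsum = w[start]
    cur_z = (wsum - mu) / sigma
    best_z = cur_z
    for v in range(n):
        best_set[v] = in_set[v]
    root = start
    temp = t0
    for _ in range(n_iter):
        # legal additions: non-members adjacent to the set
        na = 0
        for v in range(n):
            if not in_set[v]:
                for e in range(indptr[v], indptr[v + 1]):
                    if in_set[indices[e]]:
                        add_cand[na] = v
                        na += 1
                        break
        # legal removals: non-articulation members (never empty the set)
        nr = 0
        if k > 1:
            _mark_articulation(indptr, indices, in_set, root, disc, low,
                               parent, ptr, stack, is_art)
            for v in range(n):
                if in_set[v] and not is_art[v]:
                    rem_cand[nr] = v
                    nr += 1
        total = na + nr
        if total == 0:
            temp *= cooling
            continue
        j = np.random.randint(0, total)
        if j < na:
            v = add_cand[j]
            new_k = k + 1
            new_sum = wsum + w[v]
            adding = True
        else:
            v = rem_cand[j - na]
            new_k = k - 1
            new_sum = wsum - w[v]
            adding = False
        new_z = (new_sum - new_k * mu) / (sigma * np.sqrt(new_k))
        dz = new_z - cur_z
        accept = dz > 0
        if not accept:
            arg = dz / temp
            if arg > -50.0 and np.random.random() < np.exp(arg):
                accept = True
        if accept:
            in_set[v] = adding
            k = new_k
            wsum = new_sum
            cur_z = new_z
            if not adding and v == root:
                for u in range(n):
                    if in_set[u]:
                        root = u
                        break
            if cur_z > best_z:
                best_z = cur_z
                for u in range(n):
                    best_set[u] = in_set[u]
        temp *= cooling
    return best_z


@njit(cache=True)
def _anneal(indptr, indices, w, mu, sigma, n_iter, t0, cooling, restarts):
    """Best-ever module over restarts (restart 0 starts at the heaviest node)."""
    n = len(w)
    in_set = np.zeros(n, np.bool_)
    best_set = np.zeros(n, np.bool_)
    overall = np.zeros(n, np.bool_)
    add_cand = np.empty(n, np.int64)
    rem_cand = np.empty(n, np.int64)
    disc = np.empty(n, np.int64)
    low = np.empty(n, np.int64)
    parent = np.empty(n, np.int64)
    ptr = np.empty(n, np.int64)
    stack = np.empty(n, np.int64)
    is_art = np.zeros(n, np.bool_)
    best_z = -1e300
    for r in range(restarts):
        if r == 0:
            start = int(np.argmax(w))
        else:
            start = np.random.randint(0, n)
        z = _sa_single(indptr, indices, w, mu, sigma, n_iter, t0, cooling,
                       start, in_set, best_set, add_cand, rem_cand, disc, low,
                       parent, ptr, stack, is_art)
        if z > best_z:
            best_z = z
            for v in range(n):
                overall[v] = best_set[v]
    return best_z, overall


@njit(cache=True)
def _perm_null(indptr, indices, w, mu, sigma, n_iter, t0, cooling, B):
    """Best Z after re-annealing B weight permutations (restarts=1)."""
    out = np.empty(B)
    wp = w.copy()
    for b in range(B):
        for i in range(len(wp) - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = wp[i]
            wp[i] = wp[j]
            wp[j] = tmp
        z, _ = _anneal(indptr, indices, wp, mu, sigma, n_iter, t0, cooling, 1)
        out[b] = z
    return out


# ---------------------------------------------------------------------------
# Python surface
# ---------------------------------------------------------------------------


def _graph_to_csr(graph: PathwayGraph):
    nodes = list(graph.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = [[] for _ in range(n)]
    for a, b in graph.graph.edges:
        adj[index[a]].append(index[b])
        adj[index[b]].append(index[a])
    indptr = np.zeros(n + 1, np.int64)
    for i in range(n):
        indptr[i + 1] = indptr[i] + len(adj[i])
    indices = np.empty(indptr[-1], np.int64)
    for i in range(n):
        indices[indptr[i]:indptr[i + 1]] = adj[i]
    w = graph.weight_array(nodes)
    return nodes, indptr, indices, w


def _derive_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0])


def anneal_subpathway(
    graph: PathwayGraph,
    config: SAConfig,
    stats: WeightStats | None = None,
    seed: int | None = None,
) -> tuple[set[str], float]:
    """Best-scoring connected module of one pathway; deterministic given seed."""
    config.validate()
    nodes, indptr, indices, w = _graph_to_csr(graph)
    if len(nodes) < config.min_genes:
        raise ValueError(
            f"pathway {graph.pathway_id} has fewer than min_genes nodes"
        )
    if stats is None:
        stats = WeightStats(float(w.mean()), float(w.std()))
    _seed_stream(_derive_seed(config.seed if seed is None else seed, 11))
    z, mask = _anneal(indptr, indices, w, stats.mu, stats.sigma,
                      config.iterations, config.t0, config.cooling,
                      config.restarts)
    genes = {nodes[i] for i in range(len(nodes)) if mask[i]}
    return genes, float(z)


def permutation_pvalue(
    graph: PathwayGraph,
    observed_z: float,
    config: SAConfig,
    stats: WeightStats,
    seed: int | None = None,
) -> float:
    """p = (1 + #{Z_perm >= Z_obs}) / (B + 1) under within-pathway shuffles."""
    config.validate()
    _, indptr, indices, w = _graph_to_csr(graph)
    budget = max(1, config.iterations // config.perm_budget_divisor)
    _seed_stream(_derive_seed(config.seed if seed is None else seed, 13))
    null = _perm_null(indptr, indices, w, stats.mu, stats.sigma, budget,
                      config.t0, config.cooling, config.permutations)
    b = int(np.sum(null >= observed_z))
    return (1 + b) / (config.permutations + 1)


def screen_subpathways(
    pathways: list[PathwayGraph],
    composite_scores,
    config: SAConfig,
) -> list[Subpathway]:
    """Full screening pass: anneal each pathway, test, filter, rank, truncate.

    ``composite_scores`` is a gene→score mapping or the score_all_genes
    DataFrame.  Filters follow the screening rule: keep modules with at least
    ``min_genes`` genes and permutation p <= ``p_threshold``; survivors are
    ranked by Z descending and truncated to the top ``max_subpathways``.
    """
    config.validate()
    if isinstance(composite_scores, pd.DataFrame):
        weights = composite_scores["score"].to_dict()
    else:
        weights = dict(composite_scores)
    stats = WeightStats.from_scores(
        composite_scores if isinstance(composite_scores, pd.DataFrame)
        else weights
    )
    survivors: list[Subpathway] = []
    for i, pw in enumerate(pathways):
        pw.set_weights(weights)
        if pw.graph.number_of_nodes() < config.min_genes:
            continue
        seed = _derive_seed(config.seed, 17, i)
        genes, z = anneal_subpathway(pw, config, stats, seed=seed)
        if len(genes) < config.min_genes:
            continue
        p = permutation_pvalue(pw, z, config, stats, seed=seed)
        if p > config.p_threshold:
            continue
        sub = Subpathway(pw.pathway_id, frozenset(genes), z, p)
        assert nx.is_connected(pw.graph.subgraph(sub.genes)), (
            f"module from {pw.pathway_id} is not connected"
        )
        survivors.append(sub)
    if not survivors:
        raise RuntimeError(
            "no subpathway passed the filters (min_genes >= "
            f"{config.min_genes}, p <= {config.p_threshold}); relax "
            "p_threshold or increase permutations/iterations"
        )
    survivors.sort(key=lambda s: (-s.score, s.pathway_id))
    retained = survivors[: config.max_subpathways]
    for rank, sub in enumerate(retained):
        sub.rank = rank
    return retained


def subpathways_to_frame(subs: list[Subpathway]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway_id": [s.pathway_id for s in subs],
            "genes": [",".join(sorted(s.genes)) for s in subs],
            "k": [s.k for s in subs],
            "Z": [s.score for s in subs],
            "p": [s.p_value for s in subs],
            "rank": [s.rank for s in subs],
        }
    )


def write_subpathways(subs: list[Subpathway], path) -> None:
    subpathways_to_frame(subs).to_csv(path, sep="\t", index=False)
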