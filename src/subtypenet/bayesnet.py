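"""Gaussian Bayesian network learning seeded with CCR trend edges.

Per gene group, a directed acyclic graph over the group's genes and their
trend-linked miRNAs is learned from (standardized) expression by greedy
hill climbing on the Gaussian BIC score with random restarts.  Each node's
conditional density is a linear regression on its parents; the network
score decomposes over node families::

    score = sum_i [ loglik_i(parents_i) - (penalty/2) * log(n) * k_i ]

with ``k_i`` = number of parents + intercept + variance.  The CCR-derived
miRNA -> target edges form the initial structure (they remain deletable
during the search); restarts perturb the incumbent by random legal edge
toggles and re-climb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import ConfigurationError, DataConsistencyError, logger


@dataclass
class SearchConfig:
    n_restarts: int = 20
    max_parents: int = 4
    perturb_edges: int = 5
    seed: int = 0
    score_type: str = "bic"
    penalty: float = 1.0
    #: pin the seed structure's edges: the search may not delete or
    #: reverse them (off by default; seed edges are an initial guess only)
    pin_seed_edges: bool = False

    def validate(self) -> None:
        if self.n_restarts < 1:
            raise ConfigurationError("n_restarts must be >= 1")
        if self.max_parents < 1:
            raise ConfigurationError("max_parents must be >= 1")
        if self.score_type != "bic":
            raise ConfigurationError("score_type must be 'bic'")


@dataclass
class RegulatoryNetwork:
    """Learned DAG over gene/miRNA nodes with its fit score."""

    graph: nx.DiGraph  # nodes carry node_type in {gene, miRNA}
    score: float
    group: str = ""
    restart_scores: List[float] = field(default_factory=list)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise DataConsistencyError("network contains a cycle")


def seed_from_ccr(group_genes: Iterable[str],
                  edges: pd.DataFrame, group: str = "") -> RegulatoryNetwork:
    """Initial bipartite DAG: trend miRNAs -> their targets in the group.

    Only edges whose target gene belongs to the group are used; the node
    set is the group genes plus the miRNAs regulating them.  Being
    bipartite and one-directional, the seed is acyclic by construction.
    """
    genes = list(dict.fromkeys(group_genes))
    if not genes:
        raise DataConsistencyError("empty gene group")
    g = nx.DiGraph()
    g.add_nodes_from(genes, node_type="gene")
    for row in edges.itertuples(index=False):
        if row.gene in g and g.nodes[row.gene]["node_type"] == "gene":
            if row.mirna not in g:
                g.add_node(row.mirna, node_type="miRNA")
            g.add_edge(row.mirna, row.gene)
    return RegulatoryNetwork(graph=g, score=float("nan"), group=group)


class GaussianBICScorer:
    """Decomposable Gaussian BIC over node families, with caching.

    ``data`` is features x samples; rows are standardized (zero mean, unit
    variance) before scoring.  Collinear parent sets fall back to a small
    ridge with a logged warning.
    """

    def __init__(self, data: pd.DataFrame, penalty: float = 1.0):
        X = data.to_numpy(float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        self._X = (X - mu) / sd
        self._index = {name: i for i, name in enumerate(data.index)}
        self.n = X.shape[1]
        self.penalty = penalty
        self._cache: Dict[Tuple[int, FrozenSet[int]], float] = {}

    def family_score(self, node: str, parents: Iterable[str]) -> float:
        i = self._index[node]
        pset = frozenset(self._index[p] for p in parents)
        key = (i, pset)
        if key in self._cache:
            return self._cache[key]
        y = self._X[i]
        n = self.n
        if pset:
            P = self._X[sorted(pset)].T
            A = np.column_stack([np.ones(n), P])
            coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
            if rank < A.shape[1]:
                logger.warning("collinear parents for %s; ridge fallback",
                               node)
                coef = np.linalg.solve(A.T @ A + 1e-8 * np.eye(A.shape[1]),
                                       A.T @ y)
            resid = y - A @ coef
            rss = float(resid @ resid)
        else:
            rss = float(((y - y.mean()) ** 2).sum())
        sigma2 = max(rss / n, 1e-12)
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
        k = len(pset) + 2  # coefficients + intercept + variance
        score = loglik - 0.5 * self.penalty * np.log(n) * k
        self._cache[key] = score
        return score

    def score_dag(self, dag: nx.DiGraph) -> float:
        return sum(self.family_score(v, dag.predecessors(v)) for v in dag)


def score_dag(data: pd.DataFrame, dag: nx.DiGraph,
              penalty: float = 1.0) -> float:
    """Gaussian BIC of ``dag`` given features-x-samples ``data``."""
    missing = [v for v in dag if v not in data.index]
    if missing:
        raise DataConsistencyError(f"no expression for nodes {missing}")
    if data.shape[1] <= max((dag.in_degree(v) for v in dag), default=0) + 2:
        raise DataConsistencyError("too few samples for the largest family")
    return GaussianBICScorer(data, penalty).score_dag(dag)


def _legal_moves(dag: nx.DiGraph, max_parents: int, pinned=frozenset()):
    """All single-edge additions, deletions and reversals preserving
    acyclicity, the parent cap and pinned edges, in deterministic order."""
    nodes = sorted(dag.nodes)
    moves = []
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if dag.has_edge(u, v):
                if (u, v) in pinned:
                    continue
                moves.append(("delete", u, v))
                if dag.in_degree(u) < max_parents \
                        and not _creates_cycle_reversed(dag, u, v):
                    moves.append(("reverse", u, v))
            elif dag.in_degree(v) < max_parents \
                    and not nx.has_path(dag, v, u):
                moves.append(("add", u, v))
    return moves


def _creates_cycle_reversed(dag: nx.DiGraph, u: str, v: str) -> bool:
    dag.remove_edge(u, v)
    bad = nx.has_path(dag, u, v)
    dag.add_edge(u, v)
    return bad


def _apply(dag: nx.DiGraph, move) -> None:
    op, u, v = move
    if op == "add":
        dag.add_edge(u, v)
    elif op == "delete":
        dag.remove_edge(u, v)
    else:
        dag.remove_edge(u, v)
        dag.add_edge(v, u)


def hill_climb(data: pd.DataFrame, start: nx.DiGraph,
               config: SearchConfig,
               pinned=frozenset()) -> Tuple[nx.DiGraph, float]:
    """Greedy best-first single-edge search from ``start`` to a local optimum.

    Deterministic: the best strictly-improving move is applied, ties broken
    lexicographically by (operation, source, target).  ``pinned`` edges may
    not be deleted or reversed.
    """
    config.validate()
    scorer = GaussianBICScorer(data, config.penalty)
    dag = start.copy()
    score = scorer.score_dag(dag)
    improved = True
    while improved:
        improved = False
        best: Optional[tuple] = None
        best_gain = 1e-9
        for move in _legal_moves(dag, config.max_parents, pinned):
            op, u, v = move
            gain = 0.0
            if op == "add":
                gain = scorer.family_score(
                    v, list(dag.predecessors(v)) + [u]) \
                    - scorer.family_score(v, dag.predecessors(v))
            elif op == "delete":
                ps = [p for p in dag.predecessors(v) if p != u]
                gain = scorer.family_score(v, ps) \
                    - scorer.family_score(v, dag.predecessors(v))
            else:  # reverse u->v
                ps_v = [p for p in dag.predecessors(v) if p != u]
                ps_u = list(dag.predecessors(u)) + [v]
                gain = (scorer.family_score(v, ps_v)
                        - scorer.family_score(v, dag.predecessors(v))
                        + scorer.family_score(u, ps_u)
                        - scorer.family_score(u, dag.predecessors(u)))
            if gain > best_gain or (best is not None
                                    and gain == best_gain and move < best):
                best, best_gain = move, gain
        if best is not None:
            _apply(dag, best)
            score += best_gain
            improved = True
    return dag, scorer.score_dag(dag)


def _perturb(dag: nx.DiGraph, n_toggles: int, max_parents: int,
             rng: np.random.Generator,
             pinned=frozenset()) -> nx.DiGraph:
    """Random legal edge toggles: add a missing edge, or delete / reverse
    an existing one (reversals help escape misoriented basins)."""
    out = dag.copy()
    nodes = sorted(out.nodes)
    if len(nodes) < 2:
        return out
    done = 0
    attempts = 0
    while done < n_toggles and attempts < 50 * n_toggles:
        attempts += 1
        u, v = rng.choice(nodes, size=2, replace=False)
        if (u, v) in pinned:
            continue
        if out.has_edge(u, v):
            out.remove_edge(u, v)
            if rng.random() < 0.5 and out.in_degree(u) < max_parents \
                    and not nx.has_path(out, u, v):
                out.add_edge(v, u)
            done += 1
        elif out.in_degree(v) < max_parents and not nx.has_path(out, v, u):
            out.add_edge(u, v)
            done += 1
    return out


def _random_dag(nodes: List[str], n_edges: int, max_parents: int,
                rng: np.random.Generator) -> nx.DiGraph:
    """Random DAG via a random topological order (restart diversification)."""
    order = list(rng.permutation(nodes))
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    pairs = [(order[i], order[j]) for i in range(len(order))
             for j in range(i + 1, len(order))]
    rng.shuffle(pairs)
    for u, v in pairs:
        if g.number_of_edges() >= n_edges:
            break
        if g.in_degree(v) < max_parents:
            g.add_edge(u, v)
    return g


def _reversal_polish(data: pd.DataFrame, dag: nx.DiGraph, score: float,
                     config: SearchConfig):
    """Re-climb from single-edge reversals of the incumbent.

    Greedy single-edge search often locks in a misoriented edge whose
    basin hides part of the true structure; restarting from each reversal
    is a cheap targeted escape.
    """
    improved = True
    while improved:
        improved = False
        for u, v in sorted(dag.edges()):
            cand = dag.copy()
            cand.remove_edge(u, v)
            if cand.in_degree(u) < config.max_parents \
                    and not nx.has_path(cand, u, v):
                cand.add_edge(v, u)
                d2, s2 = hill_climb(data, cand, config)
                if s2 > score + 1e-9:
                    dag, score = d2, s2
                    improved = True
                    break
    return dag, score


def learn_with_restarts(data: pd.DataFrame, seed_net: RegulatoryNetwork,
                        config: SearchConfig) -> RegulatoryNetwork:
    """Hill climbing with random restarts from the CCR-seeded structure.

    Restart 0 climbs from the seed DAG.  Later restarts alternate between
    perturbing the incumbent best by ``perturb_edges`` random legal edge
    toggles and fresh random-DAG starts (random topological order), and the
    final incumbent is polished by re-climbing from single-edge reversals.
    The highest-scoring network is returned with per-restart scores logged.
    """
    config.validate()
    seed_net.validate()
    rng = np.random.default_rng(config.seed)
    pinned = frozenset(seed_net.graph.edges()) if config.pin_seed_edges \
        else frozenset()
    best_dag, best_score = hill_climb(data, seed_net.graph, config, pinned)
    scores = [best_score]
    nodes = sorted(seed_net.graph.nodes)
    for k in range(1, config.n_restarts):
        if k % 2 or pinned:
            start = _perturb(best_dag, config.perturb_edges,
                             config.max_parents, rng, pinned)
        else:
            start = _random_dag(nodes,
                                int(rng.integers(len(nodes) // 2,
                                                 2 * len(nodes) + 1)),
                                config.max_parents, rng)
        dag, score = hill_climb(data, start, config, pinned)
        scores.append(score)
        if score > best_score:
            best_dag, best_score = dag, score
    if config.n_restarts > 1 and not pinned:
        best_dag, best_score = _reversal_polish(data, best_dag, best_score,
                                                config)
    net = RegulatoryNetwork(graph=best_dag, score=float(best_score),
                            group=seed_net.group, restart_scores=scores)
    # preserve node types from the seed (perturbed/learned graphs keep nodes)
    for v in net.graph:
        net.graph.nodes[v]["node_type"] = \
            seed_net.graph.nodes[v].get("node_type", "gene")
    net.validate()
    return net
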