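"""Topology metrics, 3-node motif discovery and motif-edge correlations.

Learned regulatory networks are reduced to an undirected *typed skeleton*
(nodes typed gene / miRNA; edges classed gene-gene, miRNA-gene or
miRNA-miRNA by their endpoints).  Motifs are connected 3-node induced
subgraphs counted per canonical typed pattern and compared against a null
ensemble of degree-preserving, edge-class-preserving double-edge-swap
randomizations; patterns enriched by z >= z_min with enough instances are
reported with their node tuples.  Edge-level Pearson correlations annotate
motif instances with expression support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ConfigurationError, DataConsistencyError


@dataclass
class NetworkMetrics:
    avg_degree: float
    avg_betweenness: float
    avg_clustering: float
    avg_closeness: float
    avg_neighbors: float
    density: float
    centralization: float
    char_path_length: float
    diameter: float
    top_degree_node: str

    def as_dict(self) -> Dict[str, object]:
        return dict(self.__dict__)


@dataclass
class MotifStats:
    pattern: str
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p_emp: float
    significant: bool
    instances: List[Tuple[str, ...]] = field(default_factory=list)


def skeletonize(graph: nx.DiGraph) -> nx.Graph:
    """Undirected typed skeleton of a directed regulatory network.

    Antiparallel edge pairs collapse to one undirected edge; every edge is
    classed by its endpoint types (gene-gene, miRNA-gene, miRNA-miRNA).
    """
    g = nx.Graph()
    for v, d in graph.nodes(data=True):
        g.add_node(v, node_type=d.get("node_type", "gene"))
    for u, v in graph.edges():
        if u == v:
            continue
        g.add_edge(u, v, edge_class=_edge_class(g, u, v))
    return g


def _edge_class(g: nx.Graph, u: str, v: str) -> str:
    t = sorted((g.nodes[u].get("node_type", "gene"),
                g.nodes[v].get("node_type", "gene")))
    return f"{t[0]}-{t[1]}"


def network_metrics(graph: nx.Graph) -> NetworkMetrics:
    """Average topology metrics of an undirected network.

    Betweenness is unnormalized; closeness is computed within each
    connected component; characteristic path length averages shortest paths
    over all connected pairs; the diameter is that of the largest
    component; centralization is Freeman degree centralization.
    """
    if graph.number_of_nodes() == 0:
        raise DataConsistencyError("empty graph has no metrics")
    n = graph.number_of_nodes()
    degrees = dict(graph.degree())
    avg_degree = float(np.mean(list(degrees.values())))
    btw = nx.betweenness_centrality(graph, normalized=False)
    avg_betweenness = float(np.mean(list(btw.values())))
    avg_clustering = float(nx.average_clustering(graph)) if n > 0 else 0.0

    closeness, path_lengths = [], []
    diameter = 0.0
    largest = 0
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        m = sub.number_of_nodes()
        sp = dict(nx.all_pairs_shortest_path_length(sub))
        for v in sub:
            total = sum(sp[v].values())
            closeness.append((m - 1) / total if total > 0 else 0.0)
            path_lengths.extend(d for u, d in sp[v].items() if u != v)
        if m > largest:
            largest = m
            diameter = float(max((max(d.values()) for d in sp.values()),
                                 default=0))
    avg_closeness = float(np.mean(closeness))
    char_path_length = float(np.mean(path_lengths)) if path_lengths else 0.0

    density = float(nx.density(graph))
    max_deg = max(degrees.values())
    if n > 2:
        centralization = float(
            sum(max_deg - d for d in degrees.values())
            / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0
    top = max(sorted(degrees), key=degrees.get)
    return NetworkMetrics(
        avg_degree=avg_degree, avg_betweenness=avg_betweenness,
        avg_clustering=avg_clustering, avg_closeness=avg_closeness,
        avg_neighbors=avg_degree, density=density,
        centralization=centralization, char_path_length=char_path_length,
        diameter=diameter, top_degree_node=top)


# ---------------------------------------------------------------------------
# motifs

def _canonical_pattern(types: Tuple[str, ...],
                       adj: Tuple[Tuple[int, int], ...]) -> str:
    """Canonical key of a typed 3-node graph: minimum over node orderings."""
    best = None
    for perm in permutations(range(len(types))):
        t = tuple(types[p] for p in perm)
        inv = {p: i for i, p in enumerate(perm)}
        edges = tuple(sorted(tuple(sorted((inv[a], inv[b]))) for a, b in adj))
        key = (t, edges)
        if best is None or key < best:
            best = key
    t, edges = best
    edge_txt = ";".join(f"{a}-{b}" for a, b in edges)
    return f"types={','.join(t)}|edges={edge_txt}"


def enumerate_motifs(graph: nx.Graph, k: int = 3):
    """Counts and instances of connected induced k-node subgraphs (k=3).

    Each vertex set is counted once under a canonical typed key.
    """
    if k != 3:
        raise ConfigurationError("only 3-node motifs are supported")
    counts: Dict[str, int] = {}
    instances: Dict[str, List[Tuple[str, ...]]] = {}
    adj = {v: set(graph.neighbors(v)) for v in graph}
    seen = set()
    for u, v in graph.edges():
        for w in (adj[u] | adj[v]) - {u, v}:
            trip = tuple(sorted((u, v, w)))
            if trip in seen:
                continue
            seen.add(trip)
            types = tuple(graph.nodes[x].get("node_type", "gene")
                          for x in trip)
            e = tuple((i, j) for i, j in combinations(range(3), 2)
                      if trip[j] in adj[trip[i]])
            key = _canonical_pattern(types, e)
            counts[key] = counts.get(key, 0) + 1
            instances.setdefault(key, []).append(trip)
    return counts, instances


def randomize_network(graph: nx.Graph, n_swaps: Optional[int] = None,
                      seed: Optional[int] = None) -> nx.Graph:
    """Degree- and edge-class-preserving double-edge-swap randomization.

    A swap (u,v),(x,y) -> (u,x),(v,y) is accepted only if it introduces no
    self-loop or multi-edge and the multiset of the two edge classes is
    unchanged, so per-node degrees are preserved exactly and edge-class
    totals exactly as well.  Graphs admitting no legal swap are returned
    unchanged.
    """
    if graph.number_of_edges() < 2:
        return graph.copy()
    rng = np.random.default_rng(seed)
    g = graph.copy()
    if n_swaps is None:
        n_swaps = 10 * g.number_of_edges()
    edges = [tuple(e) for e in g.edges()]
    done = 0
    attempts = 0
    max_attempts = 100 * n_swaps
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        # propose (u,x),(v,y)
        if len({u, v, x, y}) < 4:
            continue
        if g.has_edge(u, x) or g.has_edge(v, y):
            continue
        old = sorted((_edge_class(g, u, v), _edge_class(g, x, y)))
        new = sorted((_edge_class(g, u, x), _edge_class(g, v, y)))
        if old != new:
            continue
        g.remove_edge(u, v)
        g.remove_edge(x, y)
        g.add_edge(u, x, edge_class=_edge_class(g, u, x))
        g.add_edge(v, y, edge_class=_edge_class(g, v, y))
        edges[i] = (u, x)
        edges[j] = (v, y)
        done += 1
    return g


def motif_significance(graph: nx.Graph, n_random: int = 100,
                       seed: Optional[int] = None, z_min: float = 2.0,
                       min_count: int = 5) -> List[MotifStats]:
    """Motif enrichment against a degree-preserving null ensemble.

    A pattern is significant when z >= ``z_min``, it has at least
    ``min_count`` instances, and its instances span at least two distinct
    nodes (biomarkers).
    """
    if n_random < 100:
        raise ConfigurationError("n_random must be >= 100")
    counts, instances = enumerate_motifs(graph)
    rng = np.random.default_rng(seed)
    patterns = sorted(counts)
    null_counts: Dict[str, List[int]] = {p: [] for p in patterns}
    for _ in range(n_random):
        rand = randomize_network(graph, seed=int(rng.integers(2**31)))
        rc, _ = enumerate_motifs(rand)
        for p in patterns:
            null_counts[p].append(rc.get(p, 0))
    out = []
    for p in patterns:
        obs = counts[p]
        null = np.array(null_counts[p], dtype=float)
        mean, sd = float(null.mean()), float(null.std(ddof=1))
        z = (obs - mean) / sd if sd > 0 else (np.inf if obs > mean else 0.0)
        p_emp = float((1 + (null >= obs).sum()) / (n_random + 1))
        span = set()
        for inst in instances[p]:
            span.update(inst)
        significant = bool(z >= z_min and obs >= min_count and len(span) >= 2)
        out.append(MotifStats(pattern=p, observed=obs, null_mean=mean,
                              null_sd=sd, z=float(z), p_emp=p_emp,
                              significant=significant,
                              instances=instances[p]))
    out.sort(key=lambda m: (-m.z, m.pattern))
    return out


def edge_correlations(motifs: List[MotifStats], graph: nx.Graph,
                      expression: pd.DataFrame, labels: pd.Series,
                      subset: Optional[List[str]] = None) -> pd.DataFrame:
    """Pearson r and P for every edge inside significant-motif instances.

    ``expression`` stacks miRNA and mRNA features (features x samples); the
    correlation is computed over ``subset`` samples (default: all labeled
    samples).  Edges with P >= 0.05 are flagged.
    """
    samples = list(subset) if subset is not None else list(labels.index)
    samples = [s for s in samples if s in expression.columns]
    if len(samples) < 3:
        raise DataConsistencyError("need >= 3 samples for edge correlations")
    edges = set()
    for m in motifs:
        for inst in m.instances:
            for a, b in combinations(inst, 2):
                if graph.has_edge(a, b):
                    edges.add(tuple(sorted((a, b))))
    rows = []
    for a, b in sorted(edges):
        for feat in (a, b):
            if feat not in expression.index:
                raise DataConsistencyError(f"no expression for {feat!r}")
        r, p = stats.pearsonr(expression.loc[a, samples],
                              expression.loc[b, samples])
        rows.append((a, b, float(r), float(p), bool(p >= 0.05)))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "p",
                                       "not_significant"])


def mean_abs_edge_correlation(edge_table: pd.DataFrame) -> float:
    """Group-level average |r| over motif edges."""
    if edge_table.empty:
        return float("nan")
    return float(edge_table["r"].abs().mean())
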