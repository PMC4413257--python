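"""Synthetic-truth evaluation suite.

Each function generates data with known ground truth under the study's
conditions, runs the corresponding pipeline stage, and returns measured
quality numbers (recall, precision, calibration rates, enrichment scores).
The pytest acceptance suite asserts thresholds on these quantities and the
``scripts/acceptance.py`` entry point reports them.
"""

from __future__ import annotations

import dataclasses
import itertools
import tempfile
from typing import Dict, List, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._utils import BASAL, LUMINAL, derive_seed
from .bayesnet import (
    GaussianBICScorer,
    RegulatoryNetwork,
    SearchConfig,
    learn_with_restarts,
)
from .ccr import screen_pairs
from .groups import chi_square_subtype, sam_statistics
from .netstats import enumerate_motifs, motif_significance, \
    network_metrics, randomize_network
from .pipeline import PipelineConfig, run_pipeline
from .segmentation import DEFAULT_T, backward_eliminate, estimate_fdr, fit_sbl
from .simulate import GroundTruth, SimulationConfig, simulate_dataset, \
    simulate_mirna_pairs


# ---------------------------------------------------------------------------
# segmentation

def _profile_with_breakpoints(rng, n_probes: int, n_bps: int, height: float,
                              noise: float):
    while True:
        bps = np.sort(rng.choice(np.arange(50, n_probes - 50), size=n_bps,
                                 replace=False))
        if np.diff(bps).min() >= 60:
            break
    y = np.zeros(n_probes)
    level = 0.0
    for i, b in enumerate(bps):
        level = height if i % 2 == 0 else 0.0
        y[b:] = level
    return y + rng.normal(0, noise, n_probes), bps


def breakpoint_recovery(n_profiles: int = 50, n_probes: int = 1000,
                        n_bps: int = 5, height: float = 0.6,
                        noise: float = 0.2, tol: int = 2,
                        T: float = DEFAULT_T, seed: int = 0) -> Dict:
    """Breakpoint recall/precision (+-tol probes) on simulated profiles."""
    rng = np.random.default_rng(seed)
    tp = fn = fp = 0
    for _ in range(n_profiles):
        y, truth = _profile_with_breakpoints(rng, n_probes, n_bps, height,
                                             noise)
        fit = fit_sbl(y)
        called, _ = backward_eliminate(fit, y, T)
        for t in truth:
            if called.size and np.abs(called - t).min() <= tol:
                tp += 1
            else:
                fn += 1
        for c in called:
            if np.abs(truth - c).min() > tol:
                fp += 1
    recall = tp / max(tp + fn, 1)
    precision = tp / max(tp + fp, 1)
    return {"recall": recall, "precision": precision, "n": n_profiles}


def be_nestedness(n_profiles: int = 100, n_probes: int = 400,
                  thresholds: Sequence[float] = (2.0, 3.0, 4.5, 6.0, 9.0),
                  seed: int = 0) -> Dict:
    """Count nestedness violations of BE survivor sets across thresholds."""
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_profiles):
        y = rng.normal(0, 0.25, n_probes)
        for m in rng.choice(np.arange(30, n_probes - 30),
                            size=int(rng.integers(0, 4)), replace=False):
            y[m:] += rng.choice([-1, 1]) * rng.uniform(0.3, 1.0)
        fit = fit_sbl(y)
        prev = None
        for T in sorted(thresholds):
            cur = set(backward_eliminate(fit, y, T)[0].tolist())
            if prev is not None and not cur <= prev:
                violations += 1
            prev = cur
    return {"violations": violations, "n": n_profiles}


def fdr_monotonicity(n_null: int = 30, n_probes: int = 600,
                     thresholds: Sequence[float] = (2.0, 3.0, 4.0, 5.0, 6.0),
                     noise: float = 0.2, seed: int = 0) -> Dict:
    """Null false-call rates across a threshold grid (shared SBL fits)."""
    rng = np.random.default_rng(seed)
    nulls = [rng.normal(0, noise, n_probes) for _ in range(n_null)]
    fits = [fit_sbl(y) for y in nulls]
    rates = [estimate_fdr(T, nulls, fits=fits) for T in sorted(thresholds)]
    monotone = all(a >= b for a, b in zip(rates, rates[1:]))
    rate_default = estimate_fdr(DEFAULT_T, nulls, fits=fits)
    return {"rates": rates, "monotone": monotone,
            "rate_at_default_T": rate_default, "n": n_null}


# ---------------------------------------------------------------------------
# chi-square

def chi2_exactness(n_tables: int = 1000, seed: int = 0) -> Dict:
    """Max |statistic - textbook formula| over random 2x3 tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    checked = 0
    for _ in range(n_tables):
        tab = rng.integers(0, 40, size=(2, 3))
        tab[:, 1] += 1
        chi2, _, _, degenerate = chi_square_subtype(tab)
        if degenerate:
            continue
        t = np.asarray(tab, float)
        t = t[:, t.sum(axis=0) > 0]
        e = np.outer(t.sum(1), t.sum(0)) / t.sum()
        worst = max(worst, abs(chi2 - ((t - e) ** 2 / e).sum()))
        checked += 1
    return {"max_abs_error": worst, "n": checked}


def chi2_vs_permutation(n_tables: int = 20, n_draws: int = 100_000,
                        seed: int = 0) -> Dict:
    """Max |asymptotic P - exact label-permutation P| on small tables.

    The label-permutation null with fixed margins is sampled exactly via
    the multivariate hypergeometric distribution.  Tables are restricted to
    the chi-square approximation's textbook validity range (all expected
    counts >= 5); outside it the asymptotic and exact P legitimately
    diverge by more than sampling error.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_tables:
        tab = np.array([rng.multinomial(52, rng.dirichlet([3, 8, 3])),
                        rng.multinomial(40, rng.dirichlet([3, 8, 3]))])
        chi2, p_asym, _, degenerate = chi_square_subtype(tab)
        if degenerate:
            continue
        expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        if expected.min() < 5:
            continue
        colors = tab.sum(axis=0)
        n = tab.sum()
        draws = rng.multivariate_hypergeometric(colors, 52, size=n_draws)
        e_l = colors * 52 / n
        e_b = colors * 40 / n
        rest = colors[None, :] - draws
        with np.errstate(divide="ignore", invalid="ignore"):
            null = np.where(e_l > 0, (draws - e_l) ** 2 / e_l, 0).sum(1) \
                + np.where(e_b > 0, (rest - e_b) ** 2 / e_b, 0).sum(1)
        # mid-p (half weight on ties) is the continuity-matched comparator
        # for a discrete exact null vs a continuous approximation
        p_ge = float((null >= chi2 - 1e-9).mean())
        p_gt = float((null > chi2 + 1e-9).mean())
        p_perm = 0.5 * (p_ge + p_gt)
        worst = max(worst, abs(p_asym - p_perm))
        done += 1
    return {"max_abs_gap": worst, "n": n_tables}


# ---------------------------------------------------------------------------
# SAM

def _null_expr(rng, n_features, n_l, n_b):
    labels = pd.Series([LUMINAL] * n_l + [BASAL] * n_b,
                       index=[f"s{i}" for i in range(n_l + n_b)])
    X = pd.DataFrame(rng.standard_normal((n_features, n_l + n_b)),
                     index=[f"f{i}" for i in range(n_features)],
                     columns=labels.index)
    return X, labels


def sam_calibration(n_features: int = 1000, n_per_group: int = 20,
                    n_perm: int = 200, seed: int = 0) -> Dict:
    """Empirical type-I rate of the SAM permutation P under a full null."""
    rng = np.random.default_rng(seed)
    X, labels = _null_expr(rng, n_features, n_per_group, n_per_group)
    res = sam_statistics(X, labels, n_perm=n_perm,
                         seed=derive_seed(seed, "sam-cal"))
    return {"type1_rate": float((res["p_perm"] < 0.05).mean()),
            "n": n_features}


def sam_power(n_features: int = 1000, n_shifted: int = 50,
              shift_sd: float = 2.0, n_per_group: int = 20,
              n_perm: int = 200, seed: int = 0) -> Dict:
    """Detection rate of planted shift_sd-sigma shifts at P<0.05 & FDR<0.1."""
    rng = np.random.default_rng(seed)
    X, labels = _null_expr(rng, n_features, n_per_group, n_per_group)
    shifted = X.index[:n_shifted]
    X.loc[shifted, labels == LUMINAL] += shift_sd
    res = sam_statistics(X, labels, n_perm=n_perm,
                         seed=derive_seed(seed, "sam-pow"))
    hit = ((res.loc[shifted, "p_perm"] < 0.05)
           & (res.loc[shifted, "q"] < 0.1)).mean()
    return {"power": float(hit), "n": n_shifted}


# ---------------------------------------------------------------------------
# CCR

def ccr_power(n_luminal: int = 41, n_basal: int = 15, n_true: int = 40,
              n_null: int = 300, rho: float = 0.7, n_perm: int = 1000,
              seed: int = 0) -> Dict:
    """Luminal-trend power and null call rate at the dual-profiling sizes.

    True pairs have within-luminal correlation ``rho`` and zero basal
    correlation; null (decoy) pairs are uncorrelated in both subtypes.
    """
    cfg = SimulationConfig(n_luminal=n_luminal, n_basal=n_basal,
                           rho_luminal=rho, rho_basal=0.0,
                           n_true_pairs=n_true, n_decoy_pairs=n_null,
                           seed=seed)
    rng = np.random.default_rng(derive_seed(seed, "ccr-bench"))
    genes = [f"g{i}" for i in range(max(n_true, 20))]
    samples = [f"LumA_{i+1:02d}" for i in range(n_luminal)] + \
        [f"Basal_{i+1:02d}" for i in range(n_basal)]
    mrna = pd.DataFrame(rng.standard_normal((len(genes), len(samples))),
                        index=genes, columns=samples)
    truth = GroundTruth(true_pairs={
        (f"miR-{i+1:03d}", genes[i % len(genes)], "luminal")
        for i in range(n_true)})
    mirna, tmap = simulate_mirna_pairs(truth, mrna, cfg)
    labels = pd.Series([LUMINAL] * n_luminal + [BASAL] * n_basal,
                       index=samples)
    critical, table = screen_pairs(mirna, mrna, tmap, labels,
                                   n_perm=n_perm,
                                   seed=derive_seed(seed, "ccr-perm"))
    is_true = table["mirna"].str.startswith("miR-")
    power = float((table.loc[is_true, "trend"] == "luminal").mean())
    null_rate = float(table.loc[~is_true, "significant"].mean())
    return {"power": power, "null_call_rate": null_rate,
            "critical": float(critical), "n": int(is_true.sum()),
            "n_null": int((~is_true).sum())}


def ccr_calibration(n_pairs: int = 300, rho_both: float = 0.5,
                    n_luminal: int = 41, n_basal: int = 15,
                    n_perm: int = 400, seed: int = 0) -> Dict:
    """Fraction of pairs called significant when rho_L = rho_B (no signal)."""
    cfg = SimulationConfig(n_luminal=n_luminal, n_basal=n_basal,
                           rho_luminal=rho_both, rho_basal=rho_both,
                           n_true_pairs=n_pairs, n_decoy_pairs=1, seed=seed)
    rng = np.random.default_rng(derive_seed(seed, "ccr-cal"))
    genes = [f"g{i}" for i in range(n_pairs)]
    samples = [f"LumA_{i+1:02d}" for i in range(n_luminal)] + \
        [f"Basal_{i+1:02d}" for i in range(n_basal)]
    mrna = pd.DataFrame(rng.standard_normal((n_pairs, len(samples))),
                        index=genes, columns=samples)
    truth = GroundTruth(true_pairs={
        (f"miR-{i+1:03d}", genes[i], "both") for i in range(n_pairs)})
    mirna, tmap = simulate_mirna_pairs(truth, mrna, cfg)
    labels = pd.Series([LUMINAL] * n_luminal + [BASAL] * n_basal,
                       index=samples)
    _, table = screen_pairs(mirna, mrna, tmap, labels, n_perm=n_perm,
                            seed=derive_seed(seed, "ccr-cal-perm"))
    mask = table["mirna"].str.startswith("miR-")
    return {"significant_rate": float(table.loc[mask, "significant"].mean()),
            "n": int(mask.sum())}


# ---------------------------------------------------------------------------
# Bayesian networks

def _all_dags(nodes: List[str]):
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(p for p, b in zip(pairs, bits) if b)
        if nx.is_directed_acyclic_graph(g):
            yield g


def _random_sem(rng, nodes: List[str], n: int, p_edge: float = 0.4,
                beta=(0.5, 1.5), noise: float = 0.3) -> pd.DataFrame:
    order = list(rng.permutation(nodes))
    g = nx.DiGraph()
    g.add_nodes_from(order)
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            if rng.random() < p_edge:
                g.add_edge(u, v)
    data = {}
    for v in nx.topological_sort(g):
        x = rng.normal(0, noise if g.in_degree(v) else 1.0, n)
        for p in g.predecessors(v):
            x = x + rng.uniform(*beta) * rng.choice([-1, 1]) * data[p]
        data[v] = x
    return pd.DataFrame(data).T.loc[nodes], g


def bn_exhaustive_optimum(n_datasets: int = 100, n_nodes: int = 4,
                          n_samples: int = 100, n_restarts: int = 10,
                          seed: int = 0) -> Dict:
    """Fraction of datasets where restarts reach the enumeration optimum."""
    rng = np.random.default_rng(seed)
    nodes = [f"x{i}" for i in range(n_nodes)]
    hits = 0
    for k in range(n_datasets):
        data, _ = _random_sem(rng, nodes, n_samples)
        scorer = GaussianBICScorer(data)
        best = max(scorer.score_dag(g) for g in _all_dags(nodes))
        empty = nx.DiGraph()
        empty.add_nodes_from(nodes, node_type="gene")
        seed_net = RegulatoryNetwork(graph=empty, score=float("nan"))
        cfg = SearchConfig(n_restarts=n_restarts, max_parents=n_nodes - 1,
                           seed=derive_seed(seed, f"bn-{k}"))
        net = learn_with_restarts(data, seed_net, cfg)
        if net.score >= best - 1e-6:
            hits += 1
    return {"fraction_optimal": hits / n_datasets, "n": n_datasets}


def bn_skeleton_recovery(n_nodes: int = 10, n_edges: int = 12,
                         n_samples: int = 200, n_restarts: int = 20,
                         n_reps: int = 8, seed: int = 0) -> Dict:
    """Mean skeleton recall/precision over replicate linear-Gaussian SEMs.

    Each replicate draws a fresh random 10-node DAG with 12 edges
    (beta in [0.5, 1], noise 0.2, n=200), learns a network with restarts
    and scores the undirected skeleton against the truth.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"x{i}" for i in range(n_nodes)]
    recalls, precisions = [], []
    for rep in range(n_reps):
        order = list(rng.permutation(nodes))
        possible = [(order[i], order[j]) for i in range(n_nodes)
                    for j in range(i + 1, n_nodes)]
        idx = rng.choice(len(possible), size=n_edges, replace=False)
        edges = [possible[i] for i in idx]
        g = nx.DiGraph()
        g.add_nodes_from(order)
        g.add_edges_from(edges)
        data = {}
        for v in nx.topological_sort(g):
            x = rng.normal(0, 0.2 if g.in_degree(v) else 1.0, n_samples)
            for p in g.predecessors(v):
                x = x + rng.uniform(0.5, 1.0) * rng.choice([-1, 1]) * data[p]
            data[v] = x
        df = pd.DataFrame(data).T.loc[nodes]
        empty = nx.DiGraph()
        empty.add_nodes_from(nodes, node_type="gene")
        seed_net = RegulatoryNetwork(graph=empty, score=float("nan"))
        cfg = SearchConfig(n_restarts=n_restarts, max_parents=4,
                           seed=derive_seed(seed, f"bn-skel-{rep}"))
        net = learn_with_restarts(df, seed_net, cfg)
        true_skel = {frozenset(e) for e in edges}
        found_skel = {frozenset(e) for e in net.graph.edges()}
        tp = len(true_skel & found_skel)
        recalls.append(tp / len(true_skel))
        precisions.append(tp / max(len(found_skel), 1))
    return {"recall": float(np.mean(recalls)),
            "precision": float(np.mean(precisions)), "n": n_reps}


# ---------------------------------------------------------------------------
# motifs and metrics

def motif_count_agreement(n_graphs: int = 20, n_nodes: int = 25,
                          p_edge: float = 0.15, seed: int = 0) -> Dict:
    """Motif totals vs exhaustive triple iteration; degree preservation."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    degree_violations = 0
    for k in range(n_graphs):
        g = nx.gnp_random_graph(int(rng.integers(12, n_nodes + 1)), p_edge,
                                seed=int(rng.integers(100_000)))
        for i, v in enumerate(g.nodes):
            g.nodes[v]["node_type"] = "miRNA" if i % 3 == 0 else "gene"
        counts, _ = enumerate_motifs(g)
        brute = 0
        for trip in itertools.combinations(g.nodes, 3):
            sub = g.subgraph(trip)
            if sub.number_of_edges() >= 2 and nx.is_connected(sub):
                brute += 1
        if sum(counts.values()) != brute:
            mismatches += 1
        rand = randomize_network(g, seed=int(rng.integers(100_000)))
        if dict(g.degree()) != dict(rand.degree()):
            degree_violations += 1
    return {"count_mismatches": mismatches,
            "degree_violations": degree_violations, "n": n_graphs}


def planted_clique_enrichment(n_background: int = 30, p_edge: float = 0.06,
                              clique: int = 5, n_random: int = 100,
                              seed: int = 0) -> Dict:
    """z-score of the triangle pattern with a planted gene clique."""
    g = nx.gnp_random_graph(n_background, p_edge, seed=seed)
    extra = list(range(n_background, n_background + clique))
    g.add_edges_from(itertools.combinations(extra, 2))
    nx.set_node_attributes(g, "gene", "node_type")
    out = motif_significance(g, n_random=n_random, seed=seed + 1)
    tri = [m for m in out if "edges=0-1;0-2;1-2" in m.pattern]
    z = tri[0].z if tri else 0.0
    flagged = bool(tri and tri[0].significant)
    return {"triangle_z": float(z), "flagged": flagged,
            "n": g.number_of_nodes()}


def graph_metric_agreement(n_graphs: int = 20, n_nodes: int = 15,
                           p_edge: float = 0.25, seed: int = 0) -> Dict:
    """Metrics vs brute-force path counting on random graphs."""
    rng = np.random.default_rng(seed)
    worst_btw = worst_clust = worst_close = 0.0
    for _ in range(n_graphs):
        g = nx.gnp_random_graph(n_nodes, p_edge,
                                seed=int(rng.integers(100_000)))
        nx.set_node_attributes(g, "gene", "node_type")
        m = network_metrics(g)
        # brute betweenness
        btw = dict.fromkeys(g, 0.0)
        nodes = list(g)
        for s, t in itertools.combinations(nodes, 2):
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in nodes:
                if v not in (s, t):
                    btw[v] += sum(v in p for p in paths) / len(paths)
        worst_btw = max(worst_btw,
                        abs(m.avg_betweenness - np.mean(list(btw.values()))))
        # brute clustering
        cl = []
        for v in nodes:
            nb = list(g.neighbors(v))
            if len(nb) < 2:
                cl.append(0.0)
                continue
            links = sum(g.has_edge(a, b)
                        for a, b in itertools.combinations(nb, 2))
            cl.append(2 * links / (len(nb) * (len(nb) - 1)))
        worst_clust = max(worst_clust, abs(m.avg_clustering - np.mean(cl)))
        # brute closeness (within components)
        close = []
        for v in nodes:
            dists = nx.single_source_shortest_path_length(g, v)
            total = sum(dists.values())
            close.append((len(dists) - 1) / total if total else 0.0)
        worst_close = max(worst_close, abs(m.avg_closeness - np.mean(close)))
    return {"max_betweenness_err": worst_btw,
            "max_clustering_err": worst_clust,
            "max_closeness_err": worst_close, "n": n_graphs}


# ---------------------------------------------------------------------------
# end-to-end

def end_to_end_recovery(seed: int = 0, outdir: str | None = None,
                        check_determinism: bool = True) -> Dict:
    """Group precision/recall and network biomarker recall on the default
    synthetic scenario (52 luminal-A + 40 basal-like), plus a determinism
    check (identical report on rerun with the same seed)."""
    import json

    def one_run(d):
        cfg = PipelineConfig(simulate=SimulationConfig(), outdir=d,
                             seed=seed)
        return run_pipeline(cfg)

    with tempfile.TemporaryDirectory() as tmp:
        base = outdir or f"{tmp}/run_a"
        report = one_run(base)
        sim = dataclasses.replace(SimulationConfig(),
                                  seed=derive_seed(seed, "simulate"))
        truth = simulate_dataset(sim).truth
        planted = truth.subtype_specific_genes
        groups = pd.read_csv(f"{base}/gene_groups.tsv", sep="\t",
                             index_col=0)
        tp = sum(1 for g, grp in planted.items()
                 if g in groups.index and groups.loc[g, "group"] == grp)
        recall = tp / len(planted)
        precision = tp / max(len(groups), 1)
        in_net = sum(
            1 for g, grp in planted.items()
            if g in report["networks"].get(grp, {"nodes": []})["nodes"])
        net_recall = in_net / len(planted)
        deterministic = True
        if check_determinism:
            report2 = one_run(f"{tmp}/run_b")
            a = json.loads(json.dumps(report, default=str))
            b = json.loads(json.dumps(report2, default=str))
            a["config"].pop("outdir")
            b["config"].pop("outdir")
            deterministic = a == b
    return {"group_recall": recall, "group_precision": precision,
            "network_biomarker_recall": net_recall,
            "deterministic": deterministic, "n": len(planted)}
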