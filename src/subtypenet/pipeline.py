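"""End-to-end orchestration: segmentation -> groups -> CCR -> networks -> motifs.

A single :class:`PipelineConfig` drives the full analysis, either on a
simulated cohort or on files on disk.  One top-level seed fans out to
stage-specific seeds (stable hash of the stage name) so each stage is
independently reproducible; the run report echoes the configuration and
every derived seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io
from ._utils import GROUPS, ConfigurationError, derive_seed
from .bayesnet import RegulatoryNetwork, SearchConfig, learn_with_restarts, \
    seed_from_ccr
from .ccr import classify_trends_fixed, screen_pairs, trend_edges
from .groups import build_indicator_matrix, partition_groups, sam_statistics, \
    subtype_cna_tests
from .netstats import edge_correlations, mean_abs_edge_correlation, \
    motif_significance, network_metrics, skeletonize
from .segmentation import DEFAULT_T, genes_from_segments, segment_profile
from .simulate import SimulationConfig, simulate_dataset


@dataclass
class PipelineConfig:
    """All thresholds and stage parameters of one run."""

    simulate: Optional[SimulationConfig] = None
    input_paths: Optional[Dict[str, str]] = None
    outdir: str = "subtypenet_run"
    seed: int = 0
    # subtype-group thresholds
    alpha_chi2: float = 0.05
    sam_p: float = 0.05
    sam_fdr: float = 0.1
    sam_n_perm: int = 1000
    # CCR screen
    ccr_alpha: float = 0.05
    ccr_n_perm: int = 1000
    ccr_critical_override: Optional[float] = None  # e.g. the published 6.17
    # segmentation
    seg_T: float = DEFAULT_T
    seg_prune_alpha: float = 1e8
    seg_k_mad: float = 2.0
    # structure search
    search: SearchConfig = field(default_factory=SearchConfig)
    # motifs
    motif_n_random: int = 100
    motif_z_min: float = 2.0
    motif_min_count: int = 5

    def validate(self) -> None:
        for name in ("alpha_chi2", "sam_p", "sam_fdr", "ccr_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigurationError(f"{name} must lie in (0, 1]")
        if self.simulate is None and self.input_paths is None:
            raise ConfigurationError(
                "either 'simulate' or 'input_paths' must be given")
        if self.input_paths is not None:
            missing = [k for k, p in self.input_paths.items()
                       if not Path(p).exists()]
            if missing:
                raise ConfigurationError(f"missing input files: {missing}")


class StageError(RuntimeError):
    """An error in one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as err:  # noqa: BLE001 - tag and re-raise
                raise StageError(name, err) from err
        return wrapper
    return deco


@_stage("inputs")
def _acquire_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate,
                                  seed=derive_seed(config.seed, "simulate"))
        ds = simulate_dataset(sim)
        return {"profiles": ds.profiles, "annotation": ds.gene_annotation,
                "mrna": ds.mrna, "mirna": ds.mirna, "labels": ds.labels,
                "target_map": ds.target_map, "truth": ds.truth}
    data = io.read_dataset_inputs(config.input_paths)
    data["truth"] = None
    return data


@_stage("segmentation")
def _run_segmentation(config: PipelineConfig, data):
    results = []
    states = {}
    for profile in data["profiles"]:
        res = segment_profile(profile, T=config.seg_T,
                              prune_alpha=config.seg_prune_alpha,
                              k_mad=config.seg_k_mad)
        results.append(res)
        states[profile.sample_id] = genes_from_segments(
            res, data["annotation"])
    return results, states


@_stage("groups")
def _run_groups(config: PipelineConfig, data, states):
    gsm = build_indicator_matrix(states, data["labels"])
    cna = subtype_cna_tests(gsm)
    de = sam_statistics(data["mrna"], data["labels"],
                        n_perm=config.sam_n_perm,
                        seed=derive_seed(config.seed, "sam"))
    groups = partition_groups(cna, de, alpha=config.alpha_chi2,
                              sam_p=config.sam_p, fdr=config.sam_fdr)
    return gsm, cna, de, groups


@_stage("ccr")
def _run_ccr(config: PipelineConfig, data):
    critical, table = screen_pairs(
        data["mirna"], data["mrna"], data["target_map"], data["labels"],
        n_perm=config.ccr_n_perm, seed=derive_seed(config.seed, "ccr"),
        alpha=config.ccr_alpha)
    if config.ccr_critical_override is not None:
        table = classify_trends_fixed(table,
                                      critical=config.ccr_critical_override)
        critical = config.ccr_critical_override
    return critical, table


@_stage("networks")
def _run_networks(config: PipelineConfig, data, groups, ccr_table):
    networks: Dict[str, RegulatoryNetwork] = {}
    for group in GROUPS:
        genes = groups.index[groups["group"] == group].tolist()
        if not genes:
            continue
        trend = "luminal" if group.startswith("luminalA") else "basal"
        edges = trend_edges(ccr_table, trend)
        seed_net = seed_from_ccr(genes, edges, group=group)
        nodes = list(seed_net.graph.nodes)
        rows = []
        for v in nodes:
            src = data["mrna"] if v in data["mrna"].index else data["mirna"]
            rows.append(src.loc[v])
        expr = pd.DataFrame(rows, index=nodes)
        if len(nodes) < 2 or expr.shape[1] <= config.search.max_parents + 2:
            networks[group] = RegulatoryNetwork(graph=seed_net.graph,
                                                score=float("nan"),
                                                group=group)
            continue
        cfg = dataclasses.replace(
            config.search, seed=derive_seed(config.seed, f"bn:{group}"))
        networks[group] = learn_with_restarts(expr, seed_net, cfg)
    return networks


@_stage("motifs")
def _run_motifs(config: PipelineConfig, data, networks):
    motif_out = {}
    metrics_out = {}
    edge_corr = {}
    expr_all = pd.concat([data["mrna"], data["mirna"]])
    for group, net in networks.items():
        skel = skeletonize(net.graph)
        if skel.number_of_nodes() == 0:
            continue
        metrics_out[group] = network_metrics(skel).as_dict()
        if skel.number_of_edges() < 2:
            motif_out[group] = []
            continue
        motifs = motif_significance(
            skel, n_random=config.motif_n_random,
            seed=derive_seed(config.seed, f"motif:{group}"),
            z_min=config.motif_z_min, min_count=config.motif_min_count)
        motif_out[group] = motifs
        sig = [m for m in motifs if m.significant] or motifs[:1]
        edge_corr[group] = edge_correlations(sig, skel, expr_all,
                                             data["labels"])
    return motif_out, metrics_out, edge_corr


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages; write artifacts under ``config.outdir``.

    Returns the run report (also written as ``report.json``).  Any stage
    failure halts the run with a stage-tagged error; partial outputs are
    kept next to a ``FAILED`` marker file.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        report = _run_all_stages(config, outdir)
    except StageError as err:
        (outdir / "FAILED").write_text(str(err) + "\n")
        raise
    return report


def _run_all_stages(config: PipelineConfig, outdir: Path) -> Dict:
    from . import __version__

    data = _acquire_inputs(config)
    seg_results, states = _run_segmentation(config, data)
    gsm, cna, de, groups = _run_groups(config, data, states)
    critical, ccr_table = _run_ccr(config, data)
    networks = _run_networks(config, data, groups, ccr_table)
    motifs, metrics, edge_corr = _run_motifs(config, data, networks)

    # ---- artifacts
    io.write_seg(seg_results, outdir / "segments.seg")
    io.write_states(gsm.states, outdir / "gene_states.tsv")
    cna.to_csv(outdir / "cna_tests.tsv", sep="\t")
    de.to_csv(outdir / "sam_de.tsv", sep="\t")
    groups.to_csv(outdir / "gene_groups.tsv", sep="\t")
    ccr_table.to_csv(outdir / "ccr_pairs.tsv", sep="\t", index=False)
    io.write_sif(_trend_graph(ccr_table), outdir / "trend_edges.sif")
    for group, net in networks.items():
        io.write_graphml(net.graph, outdir / f"network_{group}.graphml")
        io.write_sif(net.graph, outdir / f"network_{group}.sif")
    for group, motif_list in motifs.items():
        pd.DataFrame([{
            "pattern": m.pattern, "observed": m.observed,
            "null_mean": m.null_mean, "null_sd": m.null_sd, "z": m.z,
            "p_emp": m.p_emp, "significant": m.significant,
        } for m in motif_list]).to_csv(
            outdir / f"motifs_{group}.tsv", sep="\t", index=False)

    trend_counts = ccr_table["trend"].value_counts().to_dict()
    report = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s)
                        for s in ("simulate", "sam", "ccr")},
        "config": dataclasses.asdict(config),
        "counts": {
            "samples": int(len(data["labels"])),
            "genes_annotated": int(len(data["annotation"])),
            "genes_with_states": int(len(gsm.states)),
            "subtype_specific": int((cna["p"] < config.alpha_chi2).sum()),
            "de_significant": int(((de["p_perm"] < config.sam_p)
                                   & (de["q"] < config.sam_fdr)).sum()),
            "concordant": int(len(groups)),
            "pairs_screened": int(len(ccr_table)),
        },
        "group_sizes": {g: int((groups["group"] == g).sum()) for g in GROUPS},
        "pair_trends": {k: int(trend_counts.get(k, 0))
                        for k in ("luminal", "basal", "none")},
        "ccr_critical": float(critical),
        "networks": {
            g: {"nodes": sorted(net.graph.nodes),
                "n_edges": int(net.graph.number_of_edges()),
                "score": None if np.isnan(net.score) else float(net.score)}
            for g, net in networks.items()},
        "metrics": metrics,
        "motifs": {g: [{"pattern": m.pattern, "observed": m.observed,
                        "z": m.z, "significant": m.significant}
                       for m in ms] for g, ms in motifs.items()},
        "edge_correlation_mean": {
            g: (None if np.isnan(m) else float(m))
            for g, t in edge_corr.items()
            for m in [mean_abs_edge_correlation(t)]},
    }
    write_reports(report, outdir)
    return report


def _trend_graph(ccr_table: pd.DataFrame):
    import networkx as nx

    g = nx.DiGraph()
    for row in ccr_table[ccr_table["trend"] != "none"].itertuples(index=False):
        g.add_edge(row.mirna, row.gene)
    return g


def write_reports(report: Dict, outdir) -> None:
    """Machine-readable JSON plus a human-readable text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_json(report, outdir / "report.json")
    lines = [
        f"subtypenet {report['version']} run (seed {report['seed']})",
        "",
        "stage counts:",
    ]
    for k, v in report["counts"].items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("gene groups:")
    for g in GROUPS:
        lines.append(f"  {g}: {report['group_sizes'].get(g, 0)} genes")
    lines.append("")
    lines.append("miRNA-target trends (CCR critical value "
                 f"{report['ccr_critical']:.3f}):")
    for k, v in report["pair_trends"].items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    for g, net in report.get("networks", {}).items():
        score = net["score"]
        score_txt = "n/a" if score is None else f"{score:.2f}"
        lines.append(f"network {g}: {len(net['nodes'])} nodes, "
                     f"{net['n_edges']} edges, score {score_txt}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
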