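"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats only: wide probe TSV (chrom, pos, one column per
sample), BED gene annotation (0-based half-open), expression / label /
target-map TSVs, IGV-compatible SEG files, per-gene state TSV, SIF edge
lists, GraphML networks and JSON reports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import DataConsistencyError
from .segmentation import CopyNumberProfile, SegmentationResult


# ---------------------------------------------------------------------------
# probe tracks

def write_probe_tsv(profiles: List[CopyNumberProfile], path) -> None:
    """Wide TSV: chrom, pos, then one log-ratio column per sample."""
    if not profiles:
        raise DataConsistencyError("no profiles to write")
    base = profiles[0].probes[["chrom", "pos"]].reset_index(drop=True)
    out = base.copy()
    for p in profiles:
        probes = p.probes.reset_index(drop=True)
        if not probes[["chrom", "pos"]].equals(base):
            raise DataConsistencyError(
                f"{p.sample_id}: probe grid differs; wide TSV requires a "
                "shared grid")
        out[p.sample_id] = probes["log_ratio"].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_probe_tsv(path, labels: pd.Series) -> List[CopyNumberProfile]:
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c not in ("chrom", "pos")]
    profiles = []
    for s in samples:
        profiles.append(CopyNumberProfile(
            sample_id=s,
            subtype=str(labels.get(s, "")),
            probes=df[["chrom", "pos", s]].rename(
                columns={s: "log_ratio"})))
    return profiles


# ---------------------------------------------------------------------------
# annotation / matrices / labels / target map

def write_bed(annotation: pd.DataFrame, path) -> None:
    annotation[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "gene"])


def write_matrix(matrix: pd.DataFrame, path, index_name: str = "feature") -> None:
    matrix.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("subtype").rename_axis("sample").to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("subtype")


def write_target_map(target_map: pd.DataFrame, path) -> None:
    target_map[["mirna", "gene"]].to_csv(path, sep="\t", index=False)


def read_target_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# segmentation outputs

def write_seg(results: List[SegmentationResult], path) -> None:
    """IGV SEG format: sample, chrom, start, end, num_probes, seg.mean."""
    rows = []
    for res in results:
        for seg in res.segments:
            pos = res.probe_pos[seg.chrom]
            start = int(pos[seg.start_probe])
            last = int(pos[seg.end_probe - 1])
            rows.append((res.sample_id, seg.chrom, start, last + 1,
                         seg.end_probe - seg.start_probe, round(seg.mean, 6)))
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                "num_probes", "seg.mean"]
                 ).to_csv(path, sep="\t", index=False)


def write_states(states: pd.DataFrame, path) -> None:
    states.rename_axis("gene").to_csv(path, sep="\t")


def read_states(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# networks

def write_sif(graph, path, relation: str = "regulates") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")


def write_graphml(graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> "nx.Graph":
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# ground truth / reports

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(data: Dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def read_json(path) -> Dict:
    return json.loads(Path(path).read_text())


def write_truth(truth, path) -> None:
    write_json({
        "true_breakpoints": truth.true_breakpoints,
        "true_states": {g: truth.true_states.loc[g].to_dict()
                        for g in truth.true_states.index},
        "subtype_specific_genes": truth.subtype_specific_genes,
        "true_pairs": [list(p) for p in sorted(truth.true_pairs)],
        "true_edges": [list(e) for e in sorted(truth.true_edges)],
    }, path)


def write_dataset(ds, outdir) -> Dict[str, str]:
    """Write a SyntheticDataset bundle; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": outdir / "probes.tsv",
        "annotation": outdir / "genes.bed",
        "mrna": outdir / "mrna.tsv",
        "mirna": outdir / "mirna.tsv",
        "labels": outdir / "labels.tsv",
        "target_map": outdir / "target_map.tsv",
        "truth": outdir / "truth.json",
    }
    write_probe_tsv(ds.profiles, paths["probes"])
    write_bed(ds.gene_annotation, paths["annotation"])
    write_matrix(ds.mrna, paths["mrna"], "gene")
    write_matrix(ds.mirna, paths["mirna"], "mirna")
    write_labels(ds.labels, paths["labels"])
    write_target_map(ds.target_map, paths["target_map"])
    write_truth(ds.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_dataset_inputs(paths: Dict[str, str]):
    """Read back the pipeline inputs (not the ground truth)."""
    labels = read_labels(paths["labels"])
    return {
        "profiles": read_probe_tsv(paths["probes"], labels),
        "annotation": read_bed(paths["annotation"]),
        "mrna": read_matrix(paths["mrna"]),
        "mirna": read_matrix(paths["mirna"]),
        "labels": labels,
        "target_map": read_target_map(paths["target_map"]),
    }
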