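"""Synthetic multi-omic cohorts with planted ground truth.

Generates subtype-labeled data shaped like the study inputs the pipeline
consumes: piecewise-constant SNP-array log-ratio profiles with planted
copy-number aberrations (CNAs), mRNA expression with copy-number dosage and
subtype differential-expression effects, and miRNA expression with
subtype-specific miRNA-target correlation structure.  Every planted quantity
(breakpoints, per-gene copy states, group labels, dysregulated pairs,
regulatory edges) is recorded in a :class:`GroundTruth` bundle so downstream
stages can be scored against a known answer.

Defaults mirror the original study's cohort shape: 52 luminal-A and 40
basal-like samples.  CNA gain/loss segment means default to log2(3/2) and
log2(1/2), i.e. single-copy gain/loss on a diploid background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from ._utils import (
    BASAL,
    GROUPS,
    LUMINAL,
    ConfigurationError,
    DataConsistencyError,
    derive_seed,
    logger,
)
from .segmentation import CopyNumberProfile

#: carrier rate of a planted CNA in the non-dominant subtype
BACKGROUND_CNA_RATE = 0.05
#: genes are contiguous probe windows of this many probes
PROBES_PER_GENE = 20
#: genomic spacing between adjacent probes (bp)
PROBE_SPACING = 100
#: width of each planted CNA region, in genes
REGION_WIDTH_GENES = 3
#: planted regions per gene group
REGIONS_PER_GROUP = 2


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Counts must be positive, correlations in (-1, 1), noise SDs positive and
    ``segment_mean_gain > 0 > segment_mean_loss``.
    """

    n_luminal: int = 52
    n_basal: int = 40
    n_probes_per_chrom: int = 600
    n_chroms: int = 3
    noise_sd_cn: float = 0.2
    segment_mean_gain: float = 0.585  # log2(3/2)
    segment_mean_loss: float = -1.0  # log2(1/2)
    cna_penetrance: float = 0.8
    dosage_beta: float = 0.5
    de_effect: float = 1.0
    expr_noise_sd: float = 0.5
    rho_luminal: float = 0.7
    rho_basal: float = 0.7
    n_true_pairs: int = 24
    n_decoy_pairs: int = 24
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_luminal", "n_basal", "n_probes_per_chrom", "n_chroms",
                     "n_true_pairs", "n_decoy_pairs"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in ("noise_sd_cn", "expr_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("rho_luminal", "rho_basal"):
            if abs(getattr(self, name)) >= 1:
                raise ConfigurationError(f"{name} must lie strictly in (-1, 1)")
        if not (self.segment_mean_gain > 0 > self.segment_mean_loss):
            raise ConfigurationError(
                "segment_mean_gain must be > 0 and segment_mean_loss < 0")
        if not (0 <= self.cna_penetrance <= 1):
            raise ConfigurationError("cna_penetrance must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted answers for one synthetic cohort."""

    #: sample -> chrom -> sorted probe indices where a new segment starts
    true_breakpoints: Dict[str, Dict[str, List[int]]] = field(default_factory=dict)
    #: gene x sample copy states in {-1, 0, +1}
    true_states: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: gene -> group label for planted subtype-specific genes
    subtype_specific_genes: Dict[str, str] = field(default_factory=dict)
    #: (mirna, gene, trend) with trend in {"luminal", "basal", "both"}
    true_pairs: Set[Tuple[str, str, str]] = field(default_factory=set)
    #: directed regulatory edges (parent, child)
    true_edges: Set[Tuple[str, str]] = field(default_factory=set)


@dataclass
class SyntheticDataset:
    """Full simulated input bundle plus its ground truth."""

    profiles: List[CopyNumberProfile]
    gene_annotation: pd.DataFrame  # columns: chrom, start, end, gene
    mrna: pd.DataFrame  # genes x samples
    mirna: pd.DataFrame  # miRNAs x samples
    labels: pd.Series  # sample -> subtype
    target_map: pd.DataFrame  # columns: mirna, gene
    truth: GroundTruth

    def validate(self) -> None:
        samples = [p.sample_id for p in self.profiles]
        if sorted(samples) != sorted(self.labels.index):
            raise DataConsistencyError("profile samples != label samples")
        if list(self.mrna.columns) != list(self.mirna.columns):
            raise DataConsistencyError("mRNA/miRNA sample columns differ")
        if set(self.mrna.columns) != set(self.labels.index):
            raise DataConsistencyError("expression samples != label samples")
        if self.mrna.isna().any().any() or self.mirna.isna().any().any():
            raise DataConsistencyError("expression matrices contain NaN")


# ---------------------------------------------------------------------------
# layout helpers (deterministic in the config, independent of the seed)

def _sample_names(config: SimulationConfig) -> Tuple[List[str], pd.Series]:
    lum = [f"LumA_{i+1:02d}" for i in range(config.n_luminal)]
    bas = [f"Basal_{i+1:02d}" for i in range(config.n_basal)]
    samples = lum + bas
    labels = pd.Series(
        [LUMINAL] * len(lum) + [BASAL] * len(bas), index=samples, name="subtype")
    return samples, labels


def _gene_layout(config: SimulationConfig) -> pd.DataFrame:
    """Tile each chromosome with contiguous PROBES_PER_GENE-probe genes."""
    genes_per_chrom = config.n_probes_per_chrom // PROBES_PER_GENE
    if genes_per_chrom < 1:
        raise ConfigurationError(
            "n_probes_per_chrom must be >= one gene window "
            f"({PROBES_PER_GENE} probes)")
    rows = []
    gid = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c+1}"
        for g in range(genes_per_chrom):
            start = g * PROBES_PER_GENE * PROBE_SPACING
            end = (g + 1) * PROBES_PER_GENE * PROBE_SPACING
            rows.append((chrom, start, end, f"gene{gid:04d}"))
            gid += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def _region_layout(config: SimulationConfig,
                   annotation: pd.DataFrame) -> List[dict]:
    """Deterministically place planted CNA regions, non-overlapping.

    Each of the four groups gets REGIONS_PER_GROUP regions of
    REGION_WIDTH_GENES consecutive genes; slots rotate over chromosomes.
    """
    genes_per_chrom = config.n_probes_per_chrom // PROBES_PER_GENE
    gap = 2
    slots = []
    for c in range(config.n_chroms):
        g = 1
        while g + REGION_WIDTH_GENES <= genes_per_chrom - 1:
            slots.append((c, g))
            g += REGION_WIDTH_GENES + gap
    needed = len(GROUPS) * REGIONS_PER_GROUP
    if len(slots) < needed:
        raise ConfigurationError(
            f"n_probes_per_chrom/n_chroms too small to place {needed} CNA "
            f"regions (only {len(slots)} slots)")
    # interleave groups across slots so every chromosome mixes groups
    regions = []
    for k, group in enumerate(GROUPS * REGIONS_PER_GROUP):
        c, g = slots[k]
        chrom = f"chr{c+1}"
        genes_chrom = annotation[annotation["chrom"] == chrom]["gene"].tolist()
        genes = genes_chrom[g:g + REGION_WIDTH_GENES]
        subtype = LUMINAL if group.startswith("luminalA") else BASAL
        state = 1 if group.endswith("gain") else -1
        regions.append({
            "chrom": chrom,
            "probe_lo": g * PROBES_PER_GENE,
            "probe_hi": (g + REGION_WIDTH_GENES) * PROBES_PER_GENE,
            "genes": genes,
            "group": group,
            "subtype": subtype,
            "state": state,
        })
    return regions


# ---------------------------------------------------------------------------
# generators

def simulate_cna_cohort(config: SimulationConfig):
    """Simulate per-sample probe log-ratio profiles with planted CNAs.

    Returns ``(profiles, gene_annotation, truth)`` where ``truth`` has
    breakpoints, per-gene states and group labels filled in.  Carriers of
    each region are a random ``cna_penetrance`` fraction of the dominant
    subtype; the other subtype carries it at ``BACKGROUND_CNA_RATE``.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "cna"))
    samples, labels = _sample_names(config)
    annotation = _gene_layout(config)
    regions = _region_layout(config, annotation)

    # carrier draw per region
    for reg in regions:
        dom = labels.index[labels == reg["subtype"]]
        oth = labels.index[labels != reg["subtype"]]
        n_carr = int(round(config.cna_penetrance * len(dom)))
        carriers = set(rng.choice(dom, size=n_carr, replace=False))
        bg = set(np.asarray(oth)[rng.random(len(oth)) < BACKGROUND_CNA_RATE])
        reg["carriers"] = carriers | bg

    genes = annotation["gene"].tolist()
    states = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for reg in regions:
        for s in reg["carriers"]:
            states.loc[reg["genes"], s] = reg["state"]

    truth = GroundTruth(
        true_states=states,
        subtype_specific_genes={g: reg["group"]
                                for reg in regions for g in reg["genes"]},
    )

    mean_of = {1: config.segment_mean_gain, -1: config.segment_mean_loss}
    profiles = []
    npc = config.n_probes_per_chrom
    pos = np.arange(npc) * PROBE_SPACING
    for s in samples:
        frames = []
        bps: Dict[str, List[int]] = {}
        for c in range(config.n_chroms):
            chrom = f"chr{c+1}"
            mu = np.zeros(npc)
            cuts = set()
            for reg in regions:
                if reg["chrom"] == chrom and s in reg["carriers"]:
                    mu[reg["probe_lo"]:reg["probe_hi"]] = mean_of[reg["state"]]
                    cuts.add(reg["probe_lo"])
                    if reg["probe_hi"] < npc:
                        cuts.add(reg["probe_hi"])
            y = mu + rng.normal(0.0, config.noise_sd_cn, npc) \
                if config.noise_sd_cn > 0 else mu.copy()
            bps[chrom] = sorted(cuts)
            frames.append(pd.DataFrame(
                {"chrom": chrom, "pos": pos, "log_ratio": y}))
        truth.true_breakpoints[s] = bps
        profiles.append(CopyNumberProfile(
            sample_id=s, subtype=labels[s],
            probes=pd.concat(frames, ignore_index=True)))
    return profiles, annotation, truth


def simulate_expression(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """mRNA matrix: baseline + dosage x copy state + subtype DE shift + noise.

    The subtype shift's sign follows the planted group label: gain groups are
    overexpressed and loss groups underexpressed in their dominant subtype.
    """
    config.validate()
    if truth.true_states.empty:
        raise DataConsistencyError("truth has no copy states; run "
                                   "simulate_cna_cohort first")
    rng = np.random.default_rng(derive_seed(config.seed, "mrna"))
    states = truth.true_states
    genes, samples = states.index, states.columns
    _, labels = _sample_names(config)
    if list(samples) != list(labels.index):
        raise DataConsistencyError("truth samples do not match config cohort")

    baseline = rng.normal(5.0, 1.0, size=len(genes))
    expr = baseline[:, None] + config.dosage_beta * states.to_numpy(float)

    is_lum = (labels == LUMINAL).to_numpy()
    for gene, group in truth.subtype_specific_genes.items():
        sign = 1.0 if group.endswith("gain") else -1.0
        target = is_lum if group.startswith("luminalA") else ~is_lum
        i = genes.get_loc(gene)
        expr[i, target] += sign * config.de_effect
    if config.expr_noise_sd > 0:
        expr = expr + rng.normal(0.0, config.expr_noise_sd, expr.shape)
    return pd.DataFrame(expr, index=genes, columns=samples)


def _coupled_mirna(target: np.ndarray, is_lum: np.ndarray, rho_l: float,
                   rho_b: float, rng: np.random.Generator) -> np.ndarray:
    """miRNA = rho * z(target) + sqrt(1-rho^2) * noise, per subtype.

    ``z`` standardizes the target within the subtype, so the population
    correlation with the target equals rho exactly.
    """
    out = np.empty_like(target, dtype=float)
    for mask, rho in ((is_lum, rho_l), (~is_lum, rho_b)):
        t = target[mask]
        sd = t.std()
        z = (t - t.mean()) / sd if sd > 0 else np.zeros_like(t)
        out[mask] = rho * z + np.sqrt(1.0 - rho * rho) * \
            rng.standard_normal(mask.sum())
    return out


def simulate_mirna_pairs(truth: GroundTruth, mrna: pd.DataFrame,
                         config: SimulationConfig):
    """miRNA matrix + target map realizing the planted pair correlations.

    Per true pair the within-subtype correlation targets are set by the
    pair's trend label: ``luminal`` -> (rho_luminal, 0), ``basal`` ->
    (0, rho_basal), ``both`` -> (rho_luminal, rho_basal).  Decoy pairs are
    uncorrelated noise in both subtypes.
    """
    config.validate()
    for mir, gene, trend in truth.true_pairs:
        if gene not in mrna.index:
            raise DataConsistencyError(
                f"true pair targets unknown gene {gene!r}")
    rng = np.random.default_rng(derive_seed(config.seed, "mirna"))
    _, labels = _sample_names(config)
    is_lum = (labels == LUMINAL).to_numpy()

    rho_for = {
        "luminal": (config.rho_luminal, 0.0),
        "basal": (0.0, config.rho_basal),
        "both": (config.rho_luminal, config.rho_basal),
    }
    rows, names, map_rows = [], [], []
    for mir, gene, trend in sorted(truth.true_pairs):
        rho_l, rho_b = rho_for[trend]
        rows.append(_coupled_mirna(mrna.loc[gene].to_numpy(float), is_lum,
                                   rho_l, rho_b, rng))
        names.append(mir)
        map_rows.append((mir, gene))

    decoy_genes = rng.choice(mrna.index.to_numpy(), size=config.n_decoy_pairs)
    for k, gene in enumerate(decoy_genes):
        mir = f"decoy-miR-{k+1:03d}"
        rows.append(rng.standard_normal(mrna.shape[1]))
        names.append(mir)
        map_rows.append((mir, gene))

    mirna = pd.DataFrame(np.asarray(rows), index=names, columns=mrna.columns)
    target_map = pd.DataFrame(map_rows, columns=["mirna", "gene"])
    return mirna, target_map


def _assign_true_pairs(truth: GroundTruth, config: SimulationConfig) -> None:
    """Attach miRNA partners to planted group genes, trend matching the group."""
    group_genes = sorted(truth.subtype_specific_genes)
    if not group_genes:
        raise DataConsistencyError("no planted group genes to pair")
    for k in range(config.n_true_pairs):
        gene = group_genes[k % len(group_genes)]
        group = truth.subtype_specific_genes[gene]
        trend = "luminal" if group.startswith("luminalA") else "basal"
        mir = f"miR-{k+1:03d}"
        truth.true_pairs.add((mir, gene, trend))
        truth.true_edges.add((mir, gene))


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full mutually consistent input bundle."""
    config = config or SimulationConfig()
    config.validate()
    profiles, annotation, truth = simulate_cna_cohort(config)
    mrna = simulate_expression(truth, config)
    _assign_true_pairs(truth, config)
    mirna, target_map = simulate_mirna_pairs(truth, mrna, config)
    _, labels = _sample_names(config)
    ds = SyntheticDataset(profiles=profiles, gene_annotation=annotation,
                          mrna=mrna, mirna=mirna, labels=labels,
                          target_map=target_map, truth=truth)
    ds.validate()
    logger.info("simulated cohort: %d samples, %d genes, %d miRNAs",
                len(labels), len(mrna), len(mirna))
    return ds


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different RNG seed."""
    return replace(config, seed=seed)
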