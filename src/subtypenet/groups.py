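"""Subtype-specific CNA genes, SAM differential expression, four-group partition.

Gene-level copy states from all samples are assembled into an indicator
matrix over {-1, 0, +1}.  For each gene a Pearson chi-square test contrasts
the state counts between the two subtypes (no multiple-testing correction,
matching the original analysis, which deliberately kept all P < 0.05 genes).
Differential expression uses the SAM moderated statistic
``d = (mean_L - mean_B) / (s + s0)`` with a pooled permutation null.
Genes that are both subtype-specific in copy number and concordantly
differentially expressed are partitioned into the four groups
luminal-A gain / luminal-A loss / basal gain / basal loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import (
    BASAL,
    LUMINAL,
    ConfigurationError,
    DataConsistencyError,
    logger,
)

STATES = (-1, 0, 1)


@dataclass
class GeneStateMatrix:
    """Gene x sample copy states plus subtype labels."""

    states: pd.DataFrame  # genes x samples, values in {-1, 0, +1}
    labels: pd.Series  # sample -> subtype

    def validate(self) -> None:
        vals = set(np.unique(self.states.to_numpy()))
        if not vals <= set(STATES):
            raise DataConsistencyError(f"states outside {{-1,0,1}}: {vals}")
        missing = set(self.states.columns) - set(self.labels.index)
        if missing:
            raise DataConsistencyError(f"samples without labels: {missing}")


def build_indicator_matrix(per_sample_states: Dict[str, pd.Series],
                           labels: pd.Series) -> GeneStateMatrix:
    """Assemble per-sample gene-state vectors into one indicator matrix.

    Samples are sorted canonically so the result is independent of input
    order.  Genes missing (NaN) in any sample are dropped with a logged
    count.
    """
    if not per_sample_states:
        raise DataConsistencyError("no samples given")
    samples = sorted(per_sample_states)
    mat = pd.DataFrame({s: per_sample_states[s] for s in samples})
    complete = mat.dropna()
    n_dropped = len(mat) - len(complete)
    if n_dropped:
        logger.info("dropped %d genes missing in at least one sample",
                    n_dropped)
    if complete.empty:
        raise DataConsistencyError("no genes observed in every sample")
    gsm = GeneStateMatrix(states=complete.astype(int),
                          labels=labels.loc[samples])
    gsm.validate()
    return gsm


def contingency_table(states_row: pd.Series, labels: pd.Series) -> np.ndarray:
    """2x3 counts (rows luminal-A, basal-like; columns -1, 0, +1)."""
    tab = np.zeros((2, 3), dtype=int)
    for i, subtype in enumerate((LUMINAL, BASAL)):
        vals = states_row[labels.index[labels == subtype]]
        for j, st in enumerate(STATES):
            tab[i, j] = int((vals == st).sum())
    return tab


def chi_square_subtype(table: np.ndarray) -> Tuple[float, float, int, bool]:
    """Pearson chi-square on a 2x3 subtype-by-state table.

    All-zero state columns are dropped before computing df = (2-1)(c-1);
    no continuity correction and no multiple-testing adjustment.  Tables
    with fewer than two occupied state columns are degenerate and return
    ``(0.0, 1.0, 0, True)``.
    """
    table = np.asarray(table)
    if (table.sum(axis=1) == 0).any():
        raise DataConsistencyError("empty subtype row in contingency table")
    keep = table.sum(axis=0) > 0
    t = table[:, keep]
    if t.shape[1] < 2:
        return 0.0, 1.0, 0, True
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p), int(dof), False


def assign_direction(table: np.ndarray) -> Tuple[str, int]:
    """Dominant (subtype, state) of a subtype-specific gene.

    Picks the aberrant cell (state -1 or +1) with the largest standardized
    Pearson residual; ties break toward the larger within-subtype
    proportion, then toward gain.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(expected * (1 - row / n) * (1 - col / n))
        resid = np.where(denom > 0, (table - expected) / denom, -np.inf)
    subtypes = (LUMINAL, BASAL)
    cells = [(resid[i, j], table[i, j] / row[i, 0], 1 if j == 2 else 0,
              subtypes[i], STATES[j])
             for i in range(2) for j in (0, 2)]
    cells.sort(key=lambda c: (c[0], c[1], c[2]), reverse=True)
    _, _, _, subtype, state = cells[0]
    return subtype, int(state)


def subtype_cna_tests(gsm: GeneStateMatrix) -> pd.DataFrame:
    """Chi-square subtype-specificity test for every gene."""
    gsm.validate()
    rows = []
    for gene in gsm.states.index:
        tab = contingency_table(gsm.states.loc[gene], gsm.labels)
        chi2, p, dof, degenerate = chi_square_subtype(tab)
        if degenerate:
            dom_subtype, dom_state = LUMINAL, 1
        else:
            dom_subtype, dom_state = assign_direction(tab)
        rows.append((gene, chi2, p, dof, degenerate, dom_subtype, dom_state))
    return pd.DataFrame(rows, columns=["gene", "chi2", "p", "df", "degenerate",
                                       "dominant_subtype", "dominant_state"]
                        ).set_index("gene")


# ---------------------------------------------------------------------------
# SAM

def sam_statistics(expr: pd.DataFrame, labels: pd.Series,
                   s0_policy: str = "median", n_perm: int = 1000,
                   seed: Optional[int] = None) -> pd.DataFrame:
    """SAM moderated two-sample statistics with a pooled permutation null.

    ``d_i = (mean_L - mean_B) / (s_i + s0)`` where ``s_i`` is the pooled
    two-sample standard error and the fudge factor ``s0`` is the median of
    all ``s_i`` (``s0_policy='median'``, the package default) or a
    percentile like ``'p25'``.  The per-feature permutation P is the
    fraction of the pooled null |d| (all features x all permutations) at or
    above the observed |d|; q is the SAM-style FDR estimate: median null
    exceedance count over observed exceedance count.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    for subtype in (LUMINAL, BASAL):
        if (labels == subtype).sum() < 2:
            raise DataConsistencyError(f"need >= 2 {subtype} samples")
    samples = labels.index.intersection(expr.columns)
    labels = labels.loc[samples]
    X = expr[samples].to_numpy(float)
    is_lum = (labels == LUMINAL).to_numpy()
    rng = np.random.default_rng(seed)

    def d_stats(masks: np.ndarray):
        """Mean difference and pooled SE per mask column (samples x B)."""
        m = masks.astype(float)
        n1 = m.sum(axis=0)
        n2 = m.shape[0] - n1
        s1 = X @ m
        s2 = X.sum(axis=1, keepdims=True) - s1
        q1 = (X**2) @ m
        q2 = (X**2).sum(axis=1, keepdims=True) - q1
        mean1 = s1 / n1
        mean2 = s2 / n2
        ss = (q1 - s1**2 / n1) + (q2 - s2**2 / n2)
        pooled = ss / (m.shape[0] - 2)
        se = np.sqrt(np.maximum(pooled, 0.0) * (1.0 / n1 + 1.0 / n2))
        return mean1 - mean2, se

    diff, s = d_stats(is_lum[:, None])
    diff, s = diff[:, 0], s[:, 0]
    if s0_policy == "median":
        s0 = float(np.median(s))
    elif s0_policy.startswith("p"):
        s0 = float(np.percentile(s, float(s0_policy[1:])))
    else:
        raise ConfigurationError(f"unknown s0_policy {s0_policy!r}")
    d = diff / (s + s0)

    perm_masks = np.empty((X.shape[1], n_perm), dtype=bool)
    for b in range(n_perm):
        perm_masks[:, b] = rng.permutation(is_lum)
    pdiff, ps = d_stats(perm_masks)
    null_d = pdiff / (ps + s0)

    abs_d = np.abs(d)
    null_abs = np.sort(np.abs(null_d).ravel())
    exceed_null = null_abs.size - np.searchsorted(null_abs, abs_d, side="left")
    p_perm = exceed_null / null_abs.size

    # q: per-permutation count of null |d| >= |d_i|, median over
    # permutations, divided by the observed count at the same cut
    m_feat = X.shape[0]
    counts = np.empty((n_perm, m_feat))
    for b in range(n_perm):
        col = np.sort(np.abs(null_d[:, b]))
        counts[b] = m_feat - np.searchsorted(col, abs_d, side="left")
    med_null = np.median(counts, axis=0)
    obs_sorted = np.sort(abs_d)
    obs_count = m_feat - np.searchsorted(obs_sorted, abs_d, side="left")
    q = np.clip(med_null / np.maximum(obs_count, 1), 0.0, 1.0)

    return pd.DataFrame({
        "d": d, "s": s, "p_perm": p_perm, "q": q,
        "direction": np.sign(diff).astype(int),
    }, index=expr.index)


def partition_groups(cna: pd.DataFrame, de: pd.DataFrame,
                     alpha: float = 0.05, sam_p: float = 0.05,
                     fdr: float = 0.1) -> pd.DataFrame:
    """Assign concordant genes to the four gain/loss x subtype groups.

    A gene joins a group iff its chi-square P < ``alpha``, its SAM P and
    FDR pass (< ``sam_p``, < ``fdr``), and direction is concordant: a
    dominant gain must be overexpressed in the dominant subtype, a
    dominant loss underexpressed.  Discordant genes are excluded (logged).
    """
    shared = cna.index.intersection(de.index)
    rows = []
    n_discordant = 0
    for gene in shared:
        c = cna.loc[gene]
        e = de.loc[gene]
        if c["p"] >= alpha or c["degenerate"]:
            continue
        if e["p_perm"] >= sam_p or e["q"] >= fdr:
            continue
        over_lum = e["direction"] > 0  # overexpressed in luminal-A
        over_dom = over_lum if c["dominant_subtype"] == LUMINAL else not over_lum
        gain = c["dominant_state"] == 1
        if gain != over_dom:
            n_discordant += 1
            continue
        prefix = "luminalA" if c["dominant_subtype"] == LUMINAL else "basal"
        rows.append((gene, f"{prefix}_{'gain' if gain else 'loss'}"))
    if n_discordant:
        logger.info("excluded %d discordant genes (CNA/DE direction "
                    "mismatch)", n_discordant)
    return pd.DataFrame(rows, columns=["gene", "group"]).set_index("gene")
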