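"""Correlation-coefficient-ratio (CCR) screen for miRNA-target dysregulation.

For each candidate miRNA-target pair the Pearson correlation is computed
separately within luminal-A samples (``r_L``) and basal-like samples
(``r_B``).  The CCR contrasts the coupling strength between subtypes::

    CCR = r_L / (sign(r_B) * max(|r_B|, epsilon))

A large |CCR| means the pair is coupled in luminal-A but not basal-like
(luminal-dominant); a small |CCR| means the reverse.  Significance is
calibrated by permuting subtype labels and pooling |CCR| across pairs and
permutations into one empirical null; a pair's two-sided permutation P is
``2 * min(upper tail, lower tail)`` so that, under exchangeability, about
alpha of null pairs are called at level alpha.  The (1 - alpha) quantile of
the pooled null is reported as the screen's critical value — the quantity
whose published counterpart on the original breast-cancer cohort is 6.17.

A significant pair is labeled *luminal trend* when it sits in the
luminal-dominant (upper) tail and its luminal-A correlation is itself
significant (p_L < 0.05), and *basal trend* in the symmetric case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import (
    LUMINAL,
    ConfigurationError,
    DataConsistencyError,
    logger,
)

#: critical value published for the original cohort; used only as a
#: fallback cut-off when no permutation calibration is run
DEFAULT_CCR_CRITICAL = 6.17

#: denominator guard for near-zero basal correlations
DEFAULT_EPSILON = 0.01

_MIN_VAR = 1e-12


def _pair_r(x: np.ndarray, y: np.ndarray, mask: np.ndarray):
    """Row-wise Pearson r between matched rows of x and y over mask columns."""
    a = x[:, mask]
    b = y[:, mask]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    va = (a * a).sum(axis=1)
    vb = (b * b).sum(axis=1)
    denom = np.sqrt(va * vb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a * b).sum(axis=1) / denom, np.nan)
    return np.clip(r, -1.0, 1.0), va, vb


def _r_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t-test P for a Pearson correlation with n observations."""
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def pair_correlations(mirna: pd.DataFrame, mrna: pd.DataFrame,
                      target_map: pd.DataFrame,
                      labels: pd.Series) -> pd.DataFrame:
    """Per-subtype Pearson r and P for every miRNA-target pair.

    Pairs whose miRNA or target has (near-)zero variance within either
    subtype are dropped with a logged count.
    """
    samples = mirna.columns.intersection(mrna.columns).intersection(
        labels.index)
    if len(samples) == 0:
        raise DataConsistencyError(
            "no shared samples across miRNA, mRNA and labels")
    pairs = target_map[
        target_map["mirna"].isin(mirna.index)
        & target_map["gene"].isin(mrna.index)]
    if pairs.empty:
        raise DataConsistencyError("target map shares no features with the "
                                   "expression matrices")
    labels = labels.loc[samples]
    X = mirna.loc[pairs["mirna"], samples].to_numpy(float)
    Y = mrna.loc[pairs["gene"], samples].to_numpy(float)
    is_lum = (labels == LUMINAL).to_numpy()
    n_l, n_b = int(is_lum.sum()), int((~is_lum).sum())
    if min(n_l, n_b) < 3:
        raise DataConsistencyError("need >= 3 samples per subtype")

    r_l, va_l, vb_l = _pair_r(X, Y, is_lum)
    r_b, va_b, vb_b = _pair_r(X, Y, ~is_lum)
    ok = (va_l > _MIN_VAR) & (vb_l > _MIN_VAR) & \
         (va_b > _MIN_VAR) & (vb_b > _MIN_VAR)
    if (~ok).any():
        logger.info("dropped %d near-constant pairs", int((~ok).sum()))
    out = pd.DataFrame({
        "mirna": pairs["mirna"].to_numpy(),
        "gene": pairs["gene"].to_numpy(),
        "r_L": r_l, "p_L": _r_pvalue(r_l, n_l),
        "r_B": r_b, "p_B": _r_pvalue(r_b, n_b),
        "n_L": n_l, "n_B": n_b,
    })[ok]
    return out.reset_index(drop=True)


def ccr_statistic(r_l: np.ndarray, r_b: np.ndarray,
                  epsilon: float = DEFAULT_EPSILON):
    """Guarded correlation ratio; also returns the guard flag."""
    r_l = np.asarray(r_l, float)
    r_b = np.asarray(r_b, float)
    sign = np.where(r_b >= 0, 1.0, -1.0)
    guarded = np.abs(r_b) < epsilon
    denom = sign * np.maximum(np.abs(r_b), epsilon)
    return r_l / denom, guarded


def permutation_null_ccr(mirna: pd.DataFrame, mrna: pd.DataFrame,
                         target_map: pd.DataFrame, labels: pd.Series,
                         n_perm: int = 1000, seed: Optional[int] = None,
                         alpha: float = 0.05,
                         epsilon: float = DEFAULT_EPSILON
                         ) -> Tuple[float, pd.DataFrame]:
    """Pooled permutation null for |CCR|.

    Subtype labels are permuted ``n_perm`` times (group sizes preserved);
    |CCR| is recomputed for every pair in every permutation and pooled into
    one empirical null distribution.  Returns the critical value (the
    (1-alpha) null quantile) and a table with, per pair, the observed CCR,
    both empirical tail fractions and the two-sided ``p_null``.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    if not (0 < alpha <= 1):
        raise ConfigurationError("alpha must lie in (0, 1]")
    base = pair_correlations(mirna, mrna, target_map, labels)
    samples = mirna.columns.intersection(mrna.columns).intersection(
        labels.index)
    lab = labels.loc[samples]
    X = mirna.loc[base["mirna"], samples].to_numpy(float)
    Y = mrna.loc[base["gene"], samples].to_numpy(float)
    is_lum = (lab == LUMINAL).to_numpy()
    rng = np.random.default_rng(seed)

    obs_ccr, guarded = ccr_statistic(base["r_L"].to_numpy(),
                                     base["r_B"].to_numpy(), epsilon)
    abs_obs = np.abs(obs_ccr)

    null = np.empty((n_perm, len(base)))
    for b in range(n_perm):
        perm = rng.permutation(is_lum)
        r_l, _, _ = _pair_r(X, Y, perm)
        r_b, _, _ = _pair_r(X, Y, ~perm)
        c, _ = ccr_statistic(r_l, r_b, epsilon)
        null[b] = np.abs(c)
    pooled = np.sort(null.ravel())
    n_null = pooled.size
    critical = float(np.quantile(pooled, 1.0 - alpha))

    upper = (n_null - np.searchsorted(pooled, abs_obs, side="left")) / n_null
    lower = np.searchsorted(pooled, abs_obs, side="right") / n_null
    p_null = np.minimum(2.0 * np.minimum(upper, lower), 1.0)

    table = base.copy()
    table["ccr"] = obs_ccr
    table["abs_ccr"] = abs_obs
    table["guarded"] = guarded
    table["tail_upper"] = upper
    table["tail_lower"] = lower
    table["p_null"] = p_null
    return critical, table


def classify_trends(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label each screened pair luminal / basal trend or none.

    luminal: two-sided |CCR| significant, in the luminal-dominant (upper)
    tail, and p_L < 0.05.  basal: significant, basal-dominant (lower) tail,
    and p_B < 0.05.  Everything else: none.
    """
    sig = table["p_null"].to_numpy() <= alpha
    upper_side = table["tail_upper"].to_numpy() <= table["tail_lower"].to_numpy()
    trend = np.where(
        sig & upper_side & (table["p_L"].to_numpy() < 0.05), "luminal",
        np.where(sig & ~upper_side & (table["p_B"].to_numpy() < 0.05),
                 "basal", "none"))
    out = table.copy()
    out["significant"] = sig
    out["trend"] = trend
    return out


def classify_trends_fixed(table: pd.DataFrame,
                          critical: float = DEFAULT_CCR_CRITICAL
                          ) -> pd.DataFrame:
    """Trend labels from a fixed |CCR| critical value (no permutation null).

    luminal: |CCR| >= critical and p_L < 0.05; basal: |CCR| <= 1/critical
    and p_B < 0.05.  Used when a published cut-off (6.17 on the original
    cohort) is imposed instead of a fresh permutation calibration.
    """
    if critical <= 1:
        raise ConfigurationError("critical value must exceed 1")
    abs_ccr = table["abs_ccr"].to_numpy() if "abs_ccr" in table else \
        np.abs(ccr_statistic(table["r_L"].to_numpy(),
                             table["r_B"].to_numpy())[0])
    hi = abs_ccr >= critical
    lo = abs_ccr <= 1.0 / critical
    trend = np.where(hi & (table["p_L"].to_numpy() < 0.05), "luminal",
                     np.where(lo & (table["p_B"].to_numpy() < 0.05),
                              "basal", "none"))
    out = table.copy()
    out["abs_ccr"] = abs_ccr
    out["significant"] = hi | lo
    out["trend"] = trend
    return out


def screen_pairs(mirna: pd.DataFrame, mrna: pd.DataFrame,
                 target_map: pd.DataFrame, labels: pd.Series,
                 n_perm: int = 1000, seed: Optional[int] = None,
                 alpha: float = 0.05,
                 epsilon: float = DEFAULT_EPSILON
                 ) -> Tuple[float, pd.DataFrame]:
    """Full screen: correlations -> CCR -> permutation null -> trends."""
    critical, table = permutation_null_ccr(
        mirna, mrna, target_map, labels, n_perm=n_perm, seed=seed,
        alpha=alpha, epsilon=epsilon)
    return critical, classify_trends(table, alpha=alpha)


def trend_edges(table: pd.DataFrame, trend: str) -> pd.DataFrame:
    """miRNA -> gene edges of one trend ('luminal' or 'basal')."""
    if trend not in ("luminal", "basal"):
        raise ConfigurationError("trend must be 'luminal' or 'basal'")
    sub = table[table["trend"] == trend]
    return sub[["mirna", "gene"]].reset_index(drop=True)
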