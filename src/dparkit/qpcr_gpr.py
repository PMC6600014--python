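"""qPCR panel scoring: modified Global Pattern Recognition plus geNorm.

Global Pattern Recognition (GPR) scores each assay by how often its
delta-Cp against every other assay of the panel differs significantly
between conditions (t test, p < 0.05): hits / number of candidate
normalizers.  Normalizer stability uses the geNorm M value — the mean,
over all partner assays, of the standard deviation across samples of the
pairwise Cp difference.  Fold changes are reported against a universal
normalizer, the per-sample mean Cp of the 10 lowest-M assays (an assay
never normalizes itself).

Cp is a log2-scale quantity (one cycle = one doubling), so differences of
Cp values are log-expression ratios throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "preprocess_cp",
    "genorm_m_values",
    "gpr_scores",
    "fold_change_universal",
]

logger = logging.getLogger(__name__)

CP_CUTOFF = 35.0
HIT_ALPHA = 0.05
N_NORMALIZERS = 10


def _pivot(cp: pd.DataFrame) -> pd.DataFrame:
    """Assay x sample Cp matrix; sample = condition:replicate."""
    d = cp.copy()
    d["sample"] = d["condition"].astype(str) + ":" + d["replicate"].astype(str)
    return d.pivot_table(index="assay", columns="sample", values="Cp", aggfunc="mean")


def preprocess_cp(raw: pd.DataFrame, cutoff: float = CP_CUTOFF) -> pd.DataFrame:
    """Censor Cp above the detection cutoff and drop unusable assays.

    Cp values > ``cutoff`` become missing; assays left with fewer than 2
    usable replicates in either condition are dropped with a log entry.
    """
    d = raw.copy()
    d.loc[d["Cp"] > cutoff, "Cp"] = np.nan
    keep = []
    for assay, sub in d.groupby("assay"):
        usable = sub.dropna(subset=["Cp"]).groupby("condition").size()
        conds = d["condition"].unique()
        if all(usable.get(c, 0) >= 2 for c in conds):
            keep.append(assay)
        else:
            logger.info("dropping assay %s: < 2 usable replicates in a condition", assay)
    return d[d["assay"].isin(keep)].reset_index(drop=True)


def genorm_m_values(cp: pd.DataFrame) -> pd.Series:
    """geNorm stability M per assay (lower = more stable).

    M_j = mean over partners k != j of SD across samples of (Cp_j - Cp_k),
    pairwise-complete over missing values.
    """
    mat = _pivot(cp)
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 assays")
    assays = mat.index
    M = {}
    vals = mat.values
    for j, a in enumerate(assays):
        sds = []
        for k in range(len(assays)):
            if k == j:
                continue
            diff = vals[j] - vals[k]
            diff = diff[~np.isnan(diff)]
            sds.append(np.std(diff, ddof=1) if diff.size >= 2 else np.nan)
        M[a] = float(np.nanmean(sds))
    return pd.Series(M, name="M")


def gpr_scores(cp: pd.DataFrame, alpha: float = HIT_ALPHA) -> pd.DataFrame:
    """Modified Global Pattern Recognition: hits, score, aggregate p.

    For each target assay, delta-Cp against every other assay is compared
    between the two conditions by a two-sample t test; ``hits`` counts
    normalizers with p < ``alpha``, ``score`` = hits / candidates, and the
    aggregate p is the median of the normalizer p-values.  Zero-variance
    delta-Cp comparisons are skipped.
    """
    mat = _pivot(cp)
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 assays post-filter")
    cols = mat.columns
    cond = np.array([c.split(":")[0] for c in cols])
    conditions = pd.unique(cond)
    if len(conditions) != 2:
        raise ValueError("GPR needs exactly 2 conditions")
    a_mask, b_mask = cond == conditions[0], cond == conditions[1]

    vals = mat.values
    rows = []
    for j, assay in enumerate(mat.index):
        pvals = []
        n_cand = 0
        for k in range(len(mat.index)):
            if k == j:
                continue
            d = vals[j] - vals[k]
            da, db = d[a_mask], d[b_mask]
            da, db = da[~np.isnan(da)], db[~np.isnan(db)]
            if da.size < 2 or db.size < 2:
                continue
            if np.var(da) == 0 and np.var(db) == 0:
                if np.isclose(da.mean(), db.mean()):
                    # identical constant pattern: clearly no change
                    n_cand += 1
                    pvals.append(1.0)
                continue
            t, p = stats.ttest_ind(da, db)
            n_cand += 1
            pvals.append(float(p))
        hits = int(sum(p < alpha for p in pvals))
        rows.append(
            {
                "assay": assay,
                "hits": hits,
                "candidates": n_cand,
                "score": hits / n_cand if n_cand else np.nan,
                "aggregate_p": float(np.median(pvals)) if pvals else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("assay")


def fold_change_universal(
    cp: pd.DataFrame,
    m_values: pd.Series | None = None,
    n_norm: int = N_NORMALIZERS,
) -> pd.Series:
    """Linear fold change vs the universal normalizer (condition 2 / 1).

    The universal normalizer for an assay is the per-sample mean Cp of the
    ``n_norm`` lowest-M assays, excluding the assay itself; fold =
    2 ** -(mean dCp_cond2 - mean dCp_cond1).
    """
    mat = _pivot(cp)
    if mat.shape[0] < n_norm + 1:
        raise ValueError(f"need at least {n_norm + 1} assays")
    if m_values is None:
        m_values = genorm_m_values(cp)
    ranked = m_values.sort_values().index
    cols = mat.columns
    cond = np.array([c.split(":")[0] for c in cols])
    conditions = pd.unique(cond)
    if len(conditions) != 2:
        raise ValueError("need exactly 2 conditions")
    a_mask, b_mask = cond == conditions[0], cond == conditions[1]

    folds = {}
    for assay in mat.index:
        norm_assays = [a for a in ranked if a != assay][:n_norm]
        universal = mat.loc[norm_assays].mean(axis=0)
        dcp = mat.loc[assay] - universal
        ddcp = np.nanmean(dcp[cols[b_mask]]) - np.nanmean(dcp[cols[a_mask]])
        folds[assay] = float(2.0 ** (-ddcp))
    return pd.Series(folds, name="fold_change")
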