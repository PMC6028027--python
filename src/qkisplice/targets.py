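"""miRNA target discovery by multi-evidence consistency ranking.

The pipeline merges, per candidate gene: Pearson anti-correlation between
miRNA and gene expression in several clinical cohorts (significant at BH
q <= α with r < 0), directional fold-change filters from EMT and miRNA
transfection experiments (up > 1.5-fold in MDCK EMT, up > 1.3-fold in
HMLE EMT, down > 1.5-fold upon miR-200 transfection), and presence of a
predicted seed site and an Ago-CLIP peak.  Genes are ranked by the number
of satisfied evidence sources ("consistency"); ties are broken by the most
negative mean clinical correlation.

``recurrence_score`` is a transparent cross-cancer surrogate for
recurrence-style scores (labelled REC-surrogate in outputs): the fraction
of cohorts in which the gene-miRNA correlation is significantly negative.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import DataError
from .stats import bh_fdr

__all__ = [
    "mirna_gene_correlations",
    "apply_experimental_filters",
    "consistency_rank",
    "recurrence_score",
    "DEFAULT_FOLD_THRESHOLDS",
]

# (direction, linear fold threshold) per experimental dataset
DEFAULT_FOLD_THRESHOLDS: dict[str, tuple[str, float]] = {
    "mdck_emt": ("up", 1.5),
    "hmle_emt": ("up", 1.3),
    "mir200_transfection": ("down", 1.5),
}

_FLAG_NAMES = {
    "mdck_emt": "mdck_emt_up",
    "hmle_emt": "hmle_emt_up",
    "mir200_transfection": "mir200_transfection_down",
}


def mirna_gene_correlations(expression: pd.DataFrame, mirna: pd.Series,
                            dataset: str = "") -> tuple[pd.DataFrame, list[str]]:
    """Per-gene Pearson correlation with a miRNA across shared samples.

    Returns ``(results, skipped)`` where results has gene, r, p_value,
    q_value (BH across genes in the dataset) and n, and ``skipped`` lists
    zero-variance genes excluded from testing.  The p-value is the exact
    two-sided t-based Pearson p (identical to scipy.stats.pearsonr).
    """
    if len(expression.columns) < 3:
        raise DataError("need at least 3 paired samples")
    if set(expression.columns) != set(mirna.index):
        raise DataError("expression and miRNA sample sets differ")
    m = mirna.reindex(expression.columns).to_numpy(dtype=float)
    x = expression.to_numpy(dtype=float)
    n = x.shape[1]

    xc = x - x.mean(axis=1, keepdims=True)
    mc = m - m.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sm = np.sqrt((mc**2).sum())
    variable = sx > 0
    skipped = expression.index[~variable].tolist()

    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ mc) / (sx * sm)
    r = np.clip(r, -1.0, 1.0)
    rv = r[variable]
    # two-sided p from the t transform; |r| = 1 -> p = 0
    with np.errstate(divide="ignore"):
        t = rv * np.sqrt((n - 2) / np.maximum(1.0 - rv**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rv), 1.0)] = 0.0
    out = pd.DataFrame(
        {"gene": expression.index[variable], "dataset": dataset,
         "r": rv, "p_value": p, "q_value": bh_fdr(p), "n": n}
    ).reset_index(drop=True)
    return out, skipped


def apply_experimental_filters(
    de_tables: Mapping[str, pd.Series],
    thresholds: Mapping[str, tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Directional fold-change flags per gene.

    ``de_tables`` maps dataset name to a Series of *linear* fold changes
    (condition/control ratios, > 0).  "up" datasets flag genes with fold >
    threshold; "down" datasets flag fold < 1/threshold.
    """
    thresholds = dict(DEFAULT_FOLD_THRESHOLDS if thresholds is None else thresholds)
    flags = {}
    for name, folds in de_tables.items():
        direction, cut = thresholds[name]
        f = folds.astype(float)
        if (f <= 0).any():
            bad = f.index[f <= 0].tolist()
            raise DataError(f"non-positive fold changes in {name}: {bad[:5]}")
        flags[_FLAG_NAMES.get(name, f"{name}_{direction}")] = (
            f > cut if direction == "up" else f < 1.0 / cut
        )
    return pd.DataFrame(flags)


def consistency_rank(
    evidence: pd.DataFrame,
    clinical: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank genes by number of satisfied evidence sources.

    ``evidence`` holds boolean experimental/sequence flags (genes in the
    index); ``clinical`` maps dataset name to a correlation result frame
    from :func:`mirna_gene_correlations`.  A clinical dataset counts as
    evidence when q <= alpha and r < 0.  Output is ordered by consistency
    score (descending), then mean clinical r (ascending, most negative
    first), then gene id, with one column per evidence source.
    """
    table = evidence.copy().astype(bool)
    r_cols = {}
    for name, res in clinical.items():
        by_gene = res.set_index("gene")
        r = by_gene["r"].reindex(table.index)
        q = by_gene["q_value"].reindex(table.index)
        table[f"neg_corr_{name}"] = ((q <= alpha) & (r < 0)).fillna(False)
        r_cols[name] = r
    score = table.sum(axis=1).astype(int)
    mean_r = pd.DataFrame(r_cols).mean(axis=1)
    out = table.copy()
    out["consistency_score"] = score
    out["mean_clinical_r"] = mean_r
    out = out.reset_index(names="gene").sort_values(
        ["consistency_score", "mean_clinical_r", "gene"],
        ascending=[False, True, True], kind="stable",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def recurrence_score(per_cancer: Mapping[str, pd.Series | dict],
                     alpha: float = 0.05) -> tuple[float, pd.DataFrame]:
    """REC-surrogate: fraction of cohorts with a significant negative correlation.

    ``per_cancer`` maps cohort name to one gene-miRNA correlation record
    with fields ``r`` and ``q_value``.  Returns the score in [0, 1] and a
    per-cohort detail table.  Invariant to cohort order and monotone in
    the number of significant cohorts.
    """
    if len(per_cancer) < 2:
        raise DataError("need at least two cohorts for a recurrence score")
    rows = []
    for cancer in sorted(per_cancer):
        rec = per_cancer[cancer]
        r = float(rec["r"])
        q = float(rec["q_value"])
        rows.append((cancer, r, q, bool(q <= alpha and r < 0)))
    detail = pd.DataFrame(rows, columns=["cancer", "r", "q_value", "significant_negative"])
    return float(detail["significant_negative"].mean()), detail
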