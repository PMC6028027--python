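"""Regulator-responsive splicing from expression-decile PSI contrasts.

De novo identification of events whose inclusion tracks a regulator's
expression across a cohort: samples are split into the top and bottom
expression deciles, ΔPSI = mean PSI(high) - mean PSI(low) is computed per
event with a rank-based significance test and BH q-values, the most
significant event per gene is selected, per-cancer contrasts are assembled
into a cross-cancer ΔPSI matrix (keeping events measured in every cancer
with max |ΔPSI| >= 35% in at least one), and the matrix is ordered by
unsupervised hierarchical clustering.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import mannwhitneyu

from .stats import bh_fdr

__all__ = [
    "decile_split",
    "delta_psi_contrast",
    "per_gene_best_event",
    "build_cross_cancer_matrix",
    "cluster_delta_psi",
]

CONTRAST_COLUMNS = [
    "event_id", "mean_psi_high", "mean_psi_low", "delta_psi",
    "p_value", "q_value", "n_high", "n_low",
]


class SizeError(ValueError):
    """Too little data for the requested operation."""


def decile_split(expression: pd.Series, fraction: float = 0.10
                 ) -> tuple[list[str], list[str]]:
    """Top and bottom expression deciles of a cohort.

    Returns ``(high, low)`` sample-id lists, each of size
    ``floor(fraction * n)``.  Ties in expression are broken by stable
    sample-identifier order, so the split is deterministic and the two
    sets are always disjoint.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError(f"fraction={fraction} outside (0, 0.5]")
    n = len(expression)
    k = math.floor(fraction * n)
    if k < 2:
        raise SizeError(f"{n} samples give decile size {k} < 2")
    order = expression.to_frame("x").reset_index(names="sample")
    order = order.sort_values(["x", "sample"], kind="stable")
    low = order["sample"].iloc[:k].tolist()
    high = order["sample"].iloc[-k:].tolist()
    return high, low


def _rank_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value; degenerate all-tied input -> p=1."""
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)


def delta_psi_contrast(psi_matrix, high: list[str], low: list[str],
                       min_group_n: int = 10) -> pd.DataFrame:
    """Per-event ΔPSI between two sample groups with significance.

    ``psi_matrix`` is a :class:`~qkisplice.psi.PsiMatrix` (or a bare PSI
    DataFrame).  Per event the group means use non-missing PSI only; the
    p-value is a two-sided Mann-Whitney U on per-sample PSI, and q-values
    are BH across all tested events.  Events with fewer than
    ``min_group_n`` non-missing samples in either group are skipped.
    """
    psi = psi_matrix.psi if hasattr(psi_matrix, "psi") else psi_matrix
    high, low = list(high), list(low)
    if not high or not low:
        raise ValueError("both sample groups must be nonempty")
    if set(high) & set(low):
        raise ValueError("high and low groups overlap")
    rows = []
    for ev, row in psi.iterrows():
        a = row[high].dropna().to_numpy(dtype=float)
        b = row[low].dropna().to_numpy(dtype=float)
        if len(a) < min_group_n or len(b) < min_group_n:
            continue
        rows.append(
            (ev, a.mean(), b.mean(), a.mean() - b.mean(),
             _rank_test(a, b), len(a), len(b))
        )
    out = pd.DataFrame(
        rows,
        columns=["event_id", "mean_psi_high", "mean_psi_low", "delta_psi",
                 "p_value", "n_high", "n_low"],
    )
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out[CONTRAST_COLUMNS]


def per_gene_best_event(contrasts: pd.DataFrame,
                        event_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Most significant event per gene (smallest p; ties by larger |ΔPSI|,
    then event_id)."""
    df = contrasts.copy()
    df["gene"] = df["event_id"].map(dict(event_to_gene))
    if df["gene"].isna().any():
        missing = df.loc[df["gene"].isna(), "event_id"].tolist()
        raise KeyError(f"events without gene mapping: {missing[:5]}")
    df["_absd"] = -df["delta_psi"].abs()
    df = df.sort_values(["p_value", "_absd", "event_id"], kind="stable")
    best = df.groupby("gene", sort=True).head(1).drop(columns="_absd")
    return best.reset_index(drop=True)


def build_cross_cancer_matrix(
    contrasts: Mapping[str, pd.DataFrame],
    samples_per_cancer: Mapping[str, int],
    min_samples_per_cancer: int = 450,
    min_max_abs_delta: float = 0.35,
    measured_fraction: pd.DataFrame | None = None,
    constitutive_fraction: float = 0.80,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-cancer ΔPSI contrasts into a filtered events x cancers matrix.

    Cancers with fewer than ``min_samples_per_cancer`` samples are
    excluded.  A row (event) is retained only if it has a ΔPSI value in
    every retained cancer — the operationalization of "constitutively
    expressed in all cancers", optionally tightened by
    ``measured_fraction`` (events x cancers fraction of samples with
    non-missing PSI, required >= ``constitutive_fraction`` everywhere) —
    and |ΔPSI| >= ``min_max_abs_delta`` in at least one cancer.

    Returns ``(matrix, flags)``; ``flags`` records the per-row filter
    outcome for auditability.
    """
    kept_cancers = sorted(
        c for c in contrasts if samples_per_cancer[c] >= min_samples_per_cancer
    )
    if not kept_cancers:
        raise SizeError("no cancer cohort meets the minimum sample count")
    if len(contrasts) < 2:
        raise SizeError("need at least two cancer cohorts")
    cols = {
        c: contrasts[c].set_index("event_id")["delta_psi"] for c in kept_cancers
    }
    matrix = pd.DataFrame(cols).sort_index()
    measured_all = matrix.notna().all(axis=1)
    if measured_fraction is not None:
        mf = measured_fraction.reindex(index=matrix.index, columns=kept_cancers)
        measured_all &= (mf >= constitutive_fraction).all(axis=1)
    big = (matrix.abs() >= min_max_abs_delta).any(axis=1)
    flags = pd.DataFrame(
        {"constitutive": measured_all, "max_delta_ok": big,
         "retained": measured_all & big}
    )
    return matrix.loc[flags["retained"]], flags


def cluster_delta_psi(matrix: pd.DataFrame, method: str = "average",
                      metric: str = "euclidean"
                      ) -> tuple[list, list, np.ndarray, np.ndarray]:
    """Unsupervised hierarchical clustering of the ΔPSI matrix.

    Agglomerative clustering (Euclidean distance, average linkage by
    default) on rows and columns; returns ``(row_order, col_order,
    row_linkage, col_linkage)`` with orders as index/column labels.
    Deterministic for a fixed input up to row/column label order (rows are
    pre-sorted by label so permuting the input changes nothing).
    """
    if matrix.shape[0] < 2:
        raise SizeError("need at least two rows to cluster")
    m = matrix.sort_index(axis=0).sort_index(axis=1)
    if m.isna().any().any():
        raise ValueError("matrix must be complete (filter before clustering)")
    row_link = linkage(m.to_numpy(), method=method, metric=metric)
    row_order = [m.index[i] for i in leaves_list(row_link)]
    if m.shape[1] >= 2:
        col_link = linkage(m.to_numpy().T, method=method, metric=metric)
        col_order = [m.columns[i] for i in leaves_list(col_link)]
    else:
        col_link = np.empty((0, 4))
        col_order = list(m.columns)
    return row_order, col_order, row_link, col_link
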