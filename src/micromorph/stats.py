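"""Association and comparison statistics for the clustered cells.

Chi-square independence test on the cluster x group contingency table with
standardized residuals to localize the association; z-scored feature
heatmaps per cluster or per group; Mann-Whitney U tests for per-image
counts/frequencies between conditions.  Noise cells (cluster -1) are
excluded from every statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pipeline_ml import feature_columns

logger = logging.getLogger(__name__)


def contingency(labels: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Cluster x group cross-tabulation of non-noise cells.

    ``labels`` and ``groups`` are aligned per-cell series.  Raises
    ``ValueError`` when fewer than two clusters or two groups remain after
    excluding noise (the independence test is undefined).
    """
    labels = pd.Series(labels).reset_index(drop=True)
    groups = pd.Series(groups).reset_index(drop=True)
    if len(labels) != len(groups):
        raise ValueError("labels and groups must align per cell")
    keep = labels >= 0
    labels, groups = labels[keep], groups[keep]
    if labels.nunique() < 2 or groups.nunique() < 2:
        raise ValueError(
            "contingency table needs >= 2 clusters and >= 2 groups "
            "after excluding noise"
        )
    table = pd.crosstab(labels, groups)
    table.index.name = "cluster"
    table.columns.name = "group"
    return table


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: pd.DataFrame
    std_residuals: pd.DataFrame       # Pearson: (O-E)/sqrt(E)
    adjusted_residuals: pd.DataFrame  # (O-E)/sqrt(E(1-row/N)(1-col/N))


def chi_square(table: pd.DataFrame, yates: bool = False) -> ChiSquareResult:
    """Chi-square test of independence with standardized residuals.

    The statistic is the classic sum (O-E)^2/E with expected counts from
    the product of marginals.  Both Pearson residuals (O-E)/sqrt(E) and
    marginal-adjusted residuals are reported.  ``yates`` applies the
    continuity correction (2x2 tables only).
    """
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any():
        raise ValueError("negative counts in contingency table")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if (row_sums == 0).any():
        bad = table.index[row_sums == 0].tolist()
        raise ValueError(f"empty contingency row(s): {bad}")
    if (col_sums == 0).any():
        bad = table.columns[col_sums == 0].tolist()
        raise ValueError(f"empty contingency column(s): {bad}")
    correction = yates and obs.shape == (2, 2)
    stat, p, dof, expected = sps.chi2_contingency(obs, correction=correction)
    n = obs.sum()
    pearson = (obs - expected) / np.sqrt(expected)
    adj_den = np.sqrt(
        expected
        * (1.0 - row_sums[:, None] / n)
        * (1.0 - col_sums[None, :] / n)
    )
    adjusted = (obs - expected) / adj_den
    as_df = lambda a: pd.DataFrame(a, index=table.index, columns=table.columns)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(dof),
        p_value=float(p),
        expected=as_df(expected),
        std_residuals=as_df(pearson),
        adjusted_residuals=as_df(adjusted),
    )


def cluster_heatmap(
    table: pd.DataFrame, keys: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-level mean of z-scored features, plus between-level variance.

    Each feature column is z-scored over all cells (constant features map
    to 0, with a warning), then averaged within each level of ``keys``
    (cluster ids or group labels).  Returns ``(heatmap, between_var)``
    where ``between_var`` is the variance of the level means per feature —
    large values mean the keys separate that feature well.
    """
    feats = feature_columns(table)
    X = table[feats].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning("constant feature(s) z-scored to 0: %s",
                       [f for f, c in zip(feats, constant) if c])
        sd = np.where(constant, 1.0, sd)
    Z = (X - mu) / sd
    zdf = pd.DataFrame(Z, columns=feats, index=table.index)
    keys = pd.Series(np.asarray(keys), index=table.index, name="key")
    heatmap = zdf.groupby(keys).mean()
    if heatmap.shape[0] < 1:
        raise ValueError("need >= 1 cells per key level")
    between_var = heatmap.var(axis=0, ddof=0)
    return heatmap, between_var


def rank_test(x, y, exact_max: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for two small per-image samples.

    Exact null distribution when both sides have at most ``exact_max``
    observations and no ties straddle the samples (the study compares 4
    slices per condition); normal approximation otherwise.  Completely tied
    input (every value identical) returns p=1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank_test: both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("rank_test: all observations tied; p set to 1")
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(x) <= exact_max and len(y) <= exact_max
    method = "exact" if (small and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rank_tests_by_unit(
    counts: pd.DataFrame,
    group_a: str,
    group_b: str,
    value: str = "count",
) -> pd.DataFrame:
    """Mann-Whitney comparisons of per-image counts for every (unit, cluster).

    ``counts`` is the spatial-counts table (one row per image x unit x
    cluster).  For each anatomical unit and cluster, the per-image values of
    ``value`` in ``group_a`` are compared against ``group_b``.  Pairs where
    either side is empty are skipped.
    """
    rows = []
    for (unit, k), sub in counts.groupby(["unit_name", "cluster"]):
        xa = sub.loc[sub["group"] == group_a, value].dropna().to_numpy()
        xb = sub.loc[sub["group"] == group_b, value].dropna().to_numpy()
        if len(xa) == 0 or len(xb) == 0:
            continue
        u, p = rank_test(xa, xb)
        rows.append({
            "unit_name": unit,
            "cluster": k,
            "value": value,
            "n_a": len(xa),
            "n_b": len(xb),
            "U": u,
            "p_value": p,
        })
    return pd.DataFrame(
        rows, columns=["unit_name", "cluster", "value", "n_a", "n_b", "U",
                       "p_value"])
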