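"""Correlation of per-cell nTA with feature tables and grouped motif ranking.

Per-feature association uses Spearman's rank correlation (Pearson available
via flag) with two-sided p-values; Benjamini-Hochberg adjusted q-values are
reported alongside the raw p-values. For the grouped analysis, correlations
are computed separately within each cell group (cell type x batch), keeping
only groups with more than ``min_cells`` cells to reduce noise, and features
are ranked either by the mean correlation across groups or by the
mean/variance ratio — the latter de-emphasizes features whose correlation is
large but unstable across groups (e.g. GC-driven artifacts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN for a constant vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman requires at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return math.nan
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def _corr_with_p(x: np.ndarray, y: np.ndarray, method: str) -> Tuple[float, float]:
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return math.nan, math.nan
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(rho), float(p)


def correlate_features(
    nta: pd.Series,
    features: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate per-cell nTA against every feature column.

    Both inputs are indexed by cell id; only overlapping cells are used.
    Returns a DataFrame (feature, rho, pvalue, qvalue, n_cells) sorted by
    |rho| descending; constant features get NaN and rank last.
    """
    common = nta.index.intersection(features.index)
    if len(common) == 0:
        raise ValueError("no overlapping cell identifiers between nTA and features")
    x = nta.loc[common].to_numpy(dtype=float)
    rows = []
    for feature in features.columns:
        y = features.loc[common, feature].to_numpy(dtype=float)
        rho, p = _corr_with_p(x, y, method)
        rows.append({"feature": feature, "rho": rho, "pvalue": p, "n_cells": len(common)})
    df = pd.DataFrame(rows)
    finite = df["pvalue"].notna()
    df["qvalue"] = np.nan
    if finite.any():
        df.loc[finite, "qvalue"] = multipletests(df.loc[finite, "pvalue"], method="fdr_bh")[1]
    df["_abs"] = df["rho"].abs()
    df = df.sort_values("_abs", ascending=False, na_position="last").drop(columns="_abs")
    return df.reset_index(drop=True)


@dataclass
class GroupedCorrelationResult:
    """Per-feature grouped correlation statistics.

    ``per_feature`` columns: mean, variance, mean_over_variance plus one
    rho column per retained group. Zero variance across groups yields a
    signed-infinity mean/variance sentinel, which orders above every finite
    ratio of the same sign.
    """

    per_feature: pd.DataFrame
    groups_retained: List[Tuple[str, int]]
    groups_excluded: List[Tuple[str, int]]
    min_cells: int

    def ranked(self, by: str = "mean_over_variance") -> pd.DataFrame:
        if by not in ("mean", "mean_over_variance"):
            raise ValueError("rank by 'mean' or 'mean_over_variance'")
        return self.per_feature.sort_values(by, ascending=False, na_position="last")


def grouped_motif_ranking(
    nta: pd.Series,
    features: pd.DataFrame,
    groups: pd.Series,
    min_cells: int = 1000,
    method: str = "spearman",
) -> GroupedCorrelationResult:
    """Group-wise feature-nTA correlations with mean/variance aggregation.

    Only groups with strictly more than ``min_cells`` cells contribute; fewer
    than two retained groups is an error (the variance would be undefined).
    """
    common = nta.index.intersection(features.index).intersection(groups.index)
    if len(common) == 0:
        raise ValueError("no overlapping cell identifiers")
    nta = nta.loc[common]
    features = features.loc[common]
    groups = groups.loc[common]

    retained: List[Tuple[str, int]] = []
    excluded: List[Tuple[str, int]] = []
    group_cells: Dict[str, pd.Index] = {}
    for label, idx in groups.groupby(groups).groups.items():
        n = len(idx)
        if n > min_cells:
            retained.append((str(label), n))
            group_cells[str(label)] = idx
        else:
            excluded.append((str(label), n))
    if len(retained) < 2:
        raise ValueError(
            f"fewer than 2 groups exceed the min_cells={min_cells} filter "
            f"({len(retained)} retained); variance across groups is undefined"
        )

    rho_cols = {}
    for label, _ in retained:
        idx = group_cells[label]
        x = nta.loc[idx].to_numpy(dtype=float)
        rhos = []
        for feature in features.columns:
            y = features.loc[idx, feature].to_numpy(dtype=float)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                rhos.append(math.nan)
                continue
            if method == "spearman":
                rho, _ = sps.spearmanr(x, y)
            else:
                rho, _ = sps.pearsonr(x, y)
            rhos.append(float(rho))
        rho_cols[f"rho:{label}"] = rhos

    df = pd.DataFrame(rho_cols, index=features.columns)
    rho_mat = df.to_numpy()
    mean = np.nanmean(rho_mat, axis=1)
    var = np.nanvar(rho_mat, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(var == 0.0, np.sign(mean) * np.inf, mean / var)
    ratio = np.where((var == 0.0) & (mean == 0.0), np.nan, ratio)
    df.insert(0, "mean", mean)
    df.insert(1, "variance", var)
    df.insert(2, "mean_over_variance", ratio)
    df.index.name = "feature"
    return GroupedCorrelationResult(
        per_feature=df,
        groups_retained=sorted(retained),
        groups_excluded=sorted(excluded),
        min_cells=min_cells,
    )
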