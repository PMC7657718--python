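"""Missing-data handling: profiling, threshold deletion, imputation.

Features are deleted when their fraction of missing values strictly exceeds
a tolerance threshold (the study grid is 5/10/15/20%), except protected
theory-driven features, which are exempt from deletion but still imputed.
Remaining gaps are filled either by column median/mode or by a mixed-type
k-nearest-neighbour imputer (default k=5) using a Gower-style distance:
z-scored absolute differences on numeric dimensions, 0/1 mismatch on
categorical dimensions, averaged over the dimensions observed in both rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .touchpoints import CATEGORICAL, UserFeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MissingnessPolicy:
    """Threshold-deletion and imputation settings.

    ``threshold`` is the maximum tolerated missing fraction tau in [0, 1];
    a feature is dropped when its missing fraction is *strictly greater*
    than tau.  ``imputation`` is ``"median_mode"`` or ``"knn"``;
    ``knn_k`` defaults to 5.
    """

    threshold: float = 0.15
    imputation: str = "knn"
    knn_k: int = 5
    protected: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.imputation not in ("median_mode", "knn"):
            raise ValueError(f"unknown imputation {self.imputation!r}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def missingness_fraction(table: UserFeatureTable | pd.DataFrame) -> pd.Series:
    """Per-feature fraction of rows with a missing value, in [0, 1]."""
    df = table.data if isinstance(table, UserFeatureTable) else table
    if len(df) == 0:
        return pd.Series(0.0, index=df.columns)
    return df.isna().mean()


def delete_by_missingness(
    table: UserFeatureTable, policy: MissingnessPolicy
) -> tuple[UserFeatureTable, pd.DataFrame]:
    """Drop columns whose missing fraction strictly exceeds the threshold.

    Protected columns (policy-level plus the table's own protected set) are
    never dropped.  Returns the reduced table and a report frame with one
    row per feature: its missing fraction and the action taken.
    """
    frac = missingness_fraction(table)
    protected = set(policy.protected) | set(table.protected)
    report = pd.DataFrame({"feature": frac.index, "fraction": frac.to_numpy()})
    drop = [
        c for c in table.data.columns
        if frac[c] > policy.threshold and c not in protected
    ]
    report["action"] = np.where(
        report["feature"].isin(drop), "deleted",
        np.where(report["feature"].isin(protected) & (report["fraction"] > policy.threshold),
                 "kept_protected", "kept"),
    )
    if drop:
        logger.info("deleted %d feature(s) above missingness threshold %.2f",
                    len(drop), policy.threshold)
    out = UserFeatureTable(
        table.data.drop(columns=drop),
        {k: v for k, v in table.value_types.items() if k not in drop},
        y=table.y,
        core_cutoff=table.core_cutoff,
        protected=set(table.protected) - set(drop),
    )
    return out, report


def _column_mode(s: pd.Series):
    """Most frequent level; ties broken by earliest observation order."""
    counts: dict = {}
    for v in s:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        counts[v] = counts.get(v, 0) + 1
    if not counts:
        return np.nan
    return max(counts, key=counts.get)


def impute_simple(table: UserFeatureTable) -> UserFeatureTable:
    """Column median for numeric features, column mode for categoricals.

    Observed cells are never altered; an all-missing column is an error
    naming it.  Idempotent.
    """
    df = table.data.copy()
    for c in df.columns:
        col = df[c]
        if not col.isna().any():
            continue
        if col.isna().all():
            raise ValueError(f"cannot impute all-missing column {c!r}")
        if table.value_types.get(c) == CATEGORICAL:
            fill = _column_mode(col)
        else:
            fill = pd.to_numeric(col).median()
        df[c] = col.fillna(fill)
    return UserFeatureTable(df, dict(table.value_types), table.y, table.core_cutoff,
                            set(table.protected))


def _gower_distances(df: pd.DataFrame, categorical: Sequence[str]) -> np.ndarray:
    """Pairwise mixed-type distances.

    Numeric dimensions: |z_i - z_j| on z-scored values (zero-variance
    columns contribute 0); categorical dimensions: 0/1 mismatch.  The
    distance is the mean over dimensions observed in both rows; rows with
    no shared observed dimension are maximally distant (inf).
    """
    n = len(df)
    cat = set(categorical)
    num_cols = [c for c in df.columns if c not in cat]
    cat_cols = [c for c in df.columns if c in cat]

    total = np.zeros((n, n))
    count = np.zeros((n, n))
    if num_cols:
        x = df[num_cols].to_numpy(dtype=float)
        mu = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0)
        sd[~np.isfinite(sd)] = 0.0
        z = (x - mu) / np.where(sd > 0, sd, 1.0)
        z[:, sd == 0] = 0.0
        obs = ~np.isnan(z)
        z0 = np.nan_to_num(z)
        for j in range(z.shape[1]):
            both = np.outer(obs[:, j], obs[:, j])
            total += np.abs(z0[:, j, None] - z0[None, :, j]) * both
            count += both
    for c in cat_cols:
        col = df[c]
        obs = col.notna().to_numpy()
        codes = pd.factorize(col, use_na_sentinel=True)[0]
        both = np.outer(obs, obs)
        mismatch = (codes[:, None] != codes[None, :]).astype(float)
        total += mismatch * both
        count += both
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = total / count
    dist[count == 0] = np.inf
    np.fill_diagonal(dist, np.inf)  # a row is never its own neighbour
    return dist


def impute_knn(table: UserFeatureTable, k: int = 5) -> UserFeatureTable:
    """Mixed-type k-nearest-neighbour imputation (default k=5).

    For each missing cell the k nearest rows (Gower-style distance, ties by
    row order) among those with the cell observed supply the fill:
    unweighted mean for numeric, mode for categorical.  If no candidate
    neighbour observes the cell, the column median/mode is used for that
    cell, logged.  Observed cells are never altered.
    """
    df = table.data
    n = len(df)
    if n < k + 1:
        raise ValueError(f"knn imputation needs at least k+1={k + 1} rows, have {n}")
    cat_cols = [c for c in df.columns if table.value_types.get(c) == CATEGORICAL]
    dist = _gower_distances(df, cat_cols)
    order = np.argsort(dist, axis=1, kind="stable")  # row-order tie-break

    out = df.copy()
    n_fallback = 0
    for c in df.columns:
        col = df[c]
        miss_idx = np.flatnonzero(col.isna().to_numpy())
        if miss_idx.size == 0:
            continue
        observed = col.notna().to_numpy()
        is_cat = c in cat_cols
        fallback = _column_mode(col) if is_cat else pd.to_numeric(col).median()
        vals = col.to_numpy()
        filled = []
        for i in miss_idx:
            cand = [j for j in order[i] if observed[j] and np.isfinite(dist[i, j])]
            neigh = cand[:k]
            if not neigh:
                n_fallback += 1
                filled.append(fallback)
            elif is_cat:
                filled.append(_column_mode(pd.Series(vals[neigh])))
            else:
                filled.append(float(np.mean(vals[neigh].astype(float))))
        out.iloc[miss_idx, out.columns.get_loc(c)] = filled
    if n_fallback:
        logger.info("knn imputation fell back to median/mode for %d cell(s)", n_fallback)
    return UserFeatureTable(out, dict(table.value_types), table.y, table.core_cutoff,
                            set(table.protected))


def impute(table: UserFeatureTable, policy: MissingnessPolicy) -> UserFeatureTable:
    """Dispatch to the policy's imputation method."""
    if policy.imputation == "knn":
        return impute_knn(table, policy.knn_k)
    return impute_simple(table)
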