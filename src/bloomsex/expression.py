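"""Count-matrix conditioning: filtering, normalization, transform, pooling.

The variance-stabilizing transform here is the shifted log
``X = log2(count / size_factor + 1)`` of median-of-ratios-normalized
counts: deterministic, dependency-free, and agreeing with log2 of the
normalized count for large counts. Downstream statistics (PCA grouping,
log2FC signs and ranks) are insensitive to the difference from a
shrinkage-based regularized log at bloom-scale counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import CountMatrix


def day_sums(cm: CountMatrix) -> pd.DataFrame:
    """Per-day replicate-summed counts (genes x days, survey day order)."""
    sheet = cm.samples.loc[cm.counts.columns]
    days = list(pd.unique(sheet["day"]))
    pooled = cm.counts.T.groupby(sheet["day"]).sum().T
    return pooled[days]


def filter_low_coverage(cm: CountMatrix, min_mean_per_day: float = 5.0) -> CountMatrix:
    """Drop transcripts covered by fewer than ``min_mean_per_day`` reads
    on average per day (day coverage = sum over that day's replicates).

    The boundary is kept: a gene whose day-sums average exactly the
    threshold survives.
    """
    means = day_sums(cm).mean(axis=1)
    keep = means >= min_mean_per_day
    return CountMatrix(cm.counts.loc[keep], cm.samples)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, geometric-mean normalized to 1.

    For genes positive in all samples, s_j is the median of
    x_gj / geometric-mean_g. If no gene is positive everywhere, falls
    back to total-count ratios with a warning.
    """
    x = counts.to_numpy(float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        logs = np.log(x[all_pos])
        log_ratios = logs - logs.mean(axis=1, keepdims=True)
        log_s = np.median(log_ratios, axis=0)
    else:
        warnings.warn(
            "no gene with positive counts in all samples; using total-count ratios",
            RuntimeWarning,
            stacklevel=2,
        )
        totals = x.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total counts")
        log_s = np.log(totals)
    log_s = log_s - log_s.mean()
    return pd.Series(np.exp(log_s), index=counts.columns, name="size_factor")


def transform(counts: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    """Shifted log2 of normalized counts: X_gj = log2(x_gj / s_j + 1)."""
    sv = s.reindex(counts.columns)
    if (sv <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts / sv + 1.0)


def pool_replicates(cm: CountMatrix) -> CountMatrix:
    """Sum replicate columns within each day (one column per day).

    The pooled sample sheet carries day = sample_id and replicate 1; a
    ``group`` column is propagated when all replicates of a day agree.
    """
    pooled = day_sums(cm)
    sheet = cm.samples.loc[cm.counts.columns]
    rows = []
    for day in pooled.columns:
        sub = sheet[sheet["day"] == day]
        row = {"day": day, "replicate": 1}
        if "group" in sheet.columns and sub["group"].nunique() == 1:
            row["group"] = sub["group"].iloc[0]
        rows.append(row)
    pooled_sheet = pd.DataFrame(rows, index=pd.Index(pooled.columns, name="sample_id"))
    return CountMatrix(pooled, pooled_sheet)


def lower_median(values: np.ndarray) -> float:
    """Lower median (order statistic), an actually observed value."""
    v = np.sort(np.asarray(values))
    return float(v[(len(v) - 1) // 2])


def log2fc_over_median(pooled_counts: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    """log2FC of each condition over the gene's cross-condition median.

    log2FC_gi = X_gi - X-_g where X is the shifted-log transform of the
    normalized condition counts and X-_g transforms the (lower) median
    of the gene's raw pooled counts with size factor 1 — the median
    pseudo-sample is an observed count, kept on the transform's domain.
    """
    X = transform(pooled_counts, s)
    med = pooled_counts.apply(lambda row: lower_median(row.to_numpy()), axis=1)
    x_ref = np.log2(med + 1.0)
    return X.sub(x_ref, axis=0)


def pca_group(
    transformed: pd.DataFrame,
    k: int = 3,
    samplesheet: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Centered PCA over samples plus a k-group labelling.

    Returns (per-sample PC coordinates, variance fractions summing to 1,
    group labels). Explicit ``group`` labels in the sample sheet take
    precedence; otherwise groups come from seeded k-means on the first
    two principal components — a reproducible stand-in for grouping
    samples by visual inspection of the PCA.
    """
    n = transformed.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    Y = transformed.T.to_numpy(float)  # samples x genes
    pca = PCA(n_components=min(n, Y.shape[1]))
    coords = pca.fit_transform(Y - Y.mean(axis=0, keepdims=True))
    var_frac = pca.explained_variance_ratio_
    pcs = pd.DataFrame(
        coords,
        index=transformed.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    if samplesheet is not None and "group" in samplesheet.columns:
        labels = samplesheet.loc[transformed.columns, "group"].astype(str)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = pd.Series(
            km.fit_predict(pcs.iloc[:, : min(2, pcs.shape[1])]).astype(str),
            index=transformed.columns,
        )
    labels.name = "group"
    return pcs, var_frac, labels
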