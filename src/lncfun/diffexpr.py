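"""Two-group differential expression and unsupervised hierarchical clustering.

A feature is called differentially expressed when its absolute fold change
(ratio of anti-logged group means on the linear scale, folded to >= 1)
strictly exceeds ``fc_threshold`` AND its two-sided Student's t-test p-value
on the log2 values is strictly below ``p_threshold``. The pooled-variance
(classic Student) test is the default; Welch's correction is available via
``equal_var=False``. Raw p-values are thresholded for the calls themselves;
a Benjamini–Hochberg q-value column is emitted for information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrich import bh_fdr
from .expression_io import ExpressionMatrix

__all__ = ["log2_transform", "differential_expression", "hierarchical_clustering", "ClusterResult"]


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return the matrix on the log2 scale; requires positive linear input."""
    if matrix.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    return ExpressionMatrix(
        values=np.log2(matrix.values),
        feature_class=matrix.feature_class,
        scale="log2",
        design=matrix.design,
    )


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    *,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature two-group comparison on a log2-scale matrix.

    Returns a DataFrame indexed by feature with the linear-scale group means,
    absolute fold change (max of the ratio and its inverse), direction
    ('up' = higher in *group_a*), t statistic, p-value, informational BH
    q-value, significance flag, and a degenerate flag for zero-variance
    features (reported with p = 1).
    """
    if matrix.scale != "log2":
        raise ValueError("differential expression expects a log2-scale matrix")
    samples_a = matrix.samples_in_group(group_a)
    samples_b = matrix.samples_in_group(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(samples_a)} {group_a!r}, "
            f"{len(samples_b)} {group_b!r})"
        )
    a = matrix.values[samples_a].to_numpy(float)
    b = matrix.values[samples_b].to_numpy(float)

    mean_a_log2 = a.mean(axis=1)
    mean_b_log2 = b.mean(axis=1)
    # anti-logged group means (GeneSpring convention), not means of ratios
    mean_a = np.exp2(mean_a_log2)
    mean_b = np.exp2(mean_b_log2)
    log2_ratio = mean_a_log2 - mean_b_log2
    fc_abs = np.exp2(np.abs(log2_ratio))
    direction = np.where(log2_ratio > 0, "up", np.where(log2_ratio < 0, "down", "none"))

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_value = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    # zero pooled variance: the test statistic is undefined; report p = 1
    degenerate = (a.var(axis=1) + b.var(axis=1)) == 0
    t_stat = np.where(degenerate, np.nan, t_stat)
    p_value = np.where(degenerate, 1.0, p_value)

    significant = (fc_abs > fc_threshold) & (p_value < p_threshold)
    return pd.DataFrame(
        {
            "feature_class": matrix.feature_class,
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "log2_ratio": log2_ratio,
            "fold_change_abs": fc_abs,
            "direction": direction,
            "t_statistic": t_stat,
            "p_value": p_value,
            "q_value": bh_fdr(p_value),
            "significant": significant,
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )


@dataclass
class ClusterResult:
    """Agglomerative clustering of one matrix axis."""

    linkage: np.ndarray  # scipy (n-1) x 4 merge tree
    leaf_order: list[str]
    ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must encode n-1 merges")
        if sorted(self.leaf_order) != sorted(self.ids):
            raise ValueError("leaf order must be a permutation of the input IDs")


def hierarchical_clustering(matrix: ExpressionMatrix, axis: str = "features") -> ClusterResult:
    """Average-linkage clustering with distance 1 - Pearson correlation.

    Rows (or samples) are standardised first; constant items get distance 1
    to everything, with a warning. Ties are broken deterministically by
    input order (scipy's behaviour on an explicit condensed matrix).
    """
    if axis not in ("features", "samples"):
        raise ValueError("axis must be 'features' or 'samples'")
    data = matrix.values.to_numpy(float)
    ids = matrix.feature_ids
    if axis == "samples":
        data = data.T
        ids = matrix.sample_ids
    if data.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")

    sd = data.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant item(s); their distance is set to 1"
        )
    centered = data - data.mean(axis=1, keepdims=True)
    safe_sd = np.where(constant, 1.0, sd)
    z = centered / safe_sd[:, None]
    corr = np.corrcoef(z) if not constant.any() else None
    if corr is None:
        n = data.shape[0]
        corr = np.zeros((n, n))
        ok = ~constant
        if ok.sum() >= 2:
            corr[np.ix_(ok, ok)] = np.corrcoef(z[ok])
        np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(linkage)
    return ClusterResult(linkage=linkage, leaf_order=[ids[i] for i in order], ids=list(ids))
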