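"""lncRNA–mRNA co-expression edges from Pearson correlation.

Each differentially expressed lncRNA is correlated with each differentially
expressed mRNA across all samples (both groups pooled). An edge is retained
when |r| strictly exceeds ``r_threshold`` AND the two-sided p-value of the
correlation (t transformation on n-2 degrees of freedom) is strictly below
``p_threshold``. Note that at n = 6 samples the p-value filter binds at the
|r| = 0.8 boundary (p ~ 0.056 there), so both filters are always applied
independently.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix

__all__ = ["pearson_r", "pearson_pvalue", "build_coexpression_edges", "top_n_edges"]

EDGE_COLUMNS = ["lncrna_id", "mrna_id", "r", "p_value", "sign"]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson's correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation from n observations.

    Uses the exact null relation t = r * sqrt(n-2) / sqrt(1-r^2) with n-2
    degrees of freedom. |r| = 1 returns 0 (degenerate but conventional).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def build_coexpression_edges(
    matrix: ExpressionMatrix,
    de_lncrnas: list[str],
    de_mrnas: list[str],
    r_threshold: float = 0.8,
    p_threshold: float = 0.05,
    *,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """All (DE lncRNA, DE mRNA) pairs passing both strict thresholds.

    Correlations are computed across every sample in the matrix by default
    (both groups pooled); pass ``samples`` — e.g. one group's sample IDs —
    to correlate over a subset instead. Features with zero variance are
    skipped with a warning. Returns a DataFrame with columns lncrna_id,
    mrna_id, r, p_value, sign, sorted by (lncrna_id, mrna_id) for
    reproducible output.
    """
    missing = [f for f in list(de_lncrnas) + list(de_mrnas) if f not in matrix.values.index]
    if missing:
        raise KeyError(f"features not in matrix: {missing}")
    if samples is None:
        samples = matrix.sample_ids
    else:
        absent = [s for s in samples if s not in matrix.values.columns]
        if absent:
            raise KeyError(f"samples not in matrix: {absent}")
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")

    def _usable(ids: list[str]) -> list[str]:
        vals = matrix.values.loc[ids, samples].to_numpy(float)
        keep = vals.std(axis=1) > 0
        dropped = [f for f, k in zip(ids, keep) if not k]
        if dropped:
            warnings.warn(f"skipping zero-variance feature(s): {dropped}")
        return [f for f, k in zip(ids, keep) if k]

    lncs = _usable(list(de_lncrnas))
    mrnas = _usable(list(de_mrnas))
    if not lncs or not mrnas:
        return pd.DataFrame(columns=EDGE_COLUMNS)

    def _standardize(ids: list[str]) -> np.ndarray:
        v = matrix.values.loc[ids, samples].to_numpy(float)
        v = v - v.mean(axis=1, keepdims=True)
        return v / np.sqrt((v * v).sum(axis=1, keepdims=True))

    r_mat = np.clip(_standardize(lncs) @ _standardize(mrnas).T, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r_mat * np.sqrt(n - 2) / np.sqrt(1.0 - r_mat * r_mat)
    p_mat = np.where(np.abs(r_mat) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))

    keep = (np.abs(r_mat) > r_threshold) & (p_mat < p_threshold)
    li, mi = np.nonzero(keep)
    edges = pd.DataFrame(
        {
            "lncrna_id": [lncs[i] for i in li],
            "mrna_id": [mrnas[j] for j in mi],
            "r": r_mat[li, mi],
            "p_value": p_mat[li, mi],
            "sign": np.where(r_mat[li, mi] >= 0, "+", "-"),
        }
    )
    return edges.sort_values(["lncrna_id", "mrna_id"], ignore_index=True)


def top_n_edges(edges: pd.DataFrame, n: int = 500) -> pd.DataFrame:
    """The n strongest edges by |r| (ties: p ascending, then pair name)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ranked = edges.assign(_abs_r=edges["r"].abs()).sort_values(
        ["_abs_r", "p_value", "lncrna_id", "mrna_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    return ranked.drop(columns="_abs_r").head(n).reset_index(drop=True)
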