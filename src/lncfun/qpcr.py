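"""Relative qPCR quantification by the 2^-ddCt method.

Technical replicates are averaged per (sample, gene) first, then each gene
is normalised to the reference gene within each sample (dCt = Ct_gene -
Ct_reference), ddCt is the difference of group-mean dCt (case minus
control), and the fold change is 2^-ddCt. The group comparison p-value is a
two-sided Student's t-test on the per-sample dCt values. The log2 fold
change is -ddCt exactly: positive when the gene is up in the case group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["read_ct_table", "validate_ct_table", "delta_delta_ct", "concordance_check"]

CT_COLUMNS = ["sample_id", "group", "gene_id", "replicate", "ct"]


def read_ct_table(path) -> pd.DataFrame:
    cts = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(cts.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return cts


def validate_ct_table(cts: pd.DataFrame, reference_gene: str) -> None:
    missing = set(CT_COLUMNS) - set(cts.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (cts["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    samples = set(cts["sample_id"])
    with_ref = set(cts.loc[cts["gene_id"] == reference_gene, "sample_id"])
    if samples - with_ref:
        raise ValueError(
            f"reference gene {reference_gene!r} missing for sample(s): "
            f"{sorted(samples - with_ref)}"
        )


def delta_delta_ct(
    cts: pd.DataFrame,
    reference_gene: str,
    case_group: str,
    control_group: str,
) -> pd.DataFrame:
    """Per-gene relative quantification between two groups.

    Returns a DataFrame indexed by gene with group-mean dCt, ddCt, fold
    change (2^-ddCt), log2 fold change (-ddCt), direction, and the t-test
    p-value on per-sample dCt.
    """
    validate_ct_table(cts, reference_gene)
    for group in (case_group, control_group):
        if group not in set(cts["group"]):
            raise ValueError(f"group {group!r} not present in Ct table")
    # average technical replicates, then normalise within sample
    mean_ct = (
        cts.groupby(["sample_id", "group", "gene_id"], sort=True)["ct"].mean().reset_index()
    )
    ref = mean_ct[mean_ct["gene_id"] == reference_gene].set_index("sample_id")["ct"]
    dct = mean_ct[mean_ct["gene_id"] != reference_gene].copy()
    dct["delta_ct"] = dct["ct"].to_numpy() - ref.loc[dct["sample_id"]].to_numpy()

    rows = []
    for gene, sub in dct.groupby("gene_id", sort=True):
        case_vals = sub.loc[sub["group"] == case_group, "delta_ct"].to_numpy()
        ctrl_vals = sub.loc[sub["group"] == control_group, "delta_ct"].to_numpy()
        if case_vals.size == 0 or ctrl_vals.size == 0:
            raise ValueError(f"gene {gene!r} absent from one group")
        ddct = case_vals.mean() - ctrl_vals.mean()
        if case_vals.size >= 2 and ctrl_vals.size >= 2:
            with np.errstate(divide="ignore", invalid="ignore"):
                _, p_value = stats.ttest_ind(case_vals, ctrl_vals, equal_var=True)
            p_value = 1.0 if not np.isfinite(p_value) else float(p_value)
        else:
            p_value = np.nan
        log2_fc = -ddct
        rows.append(
            {
                "gene_id": gene,
                f"delta_ct_{case_group}": case_vals.mean(),
                f"delta_ct_{control_group}": ctrl_vals.mean(),
                "delta_delta_ct": ddct,
                "fold_change": float(2.0 ** log2_fc),
                "log2_fold_change": float(log2_fc),
                "direction": "up" if log2_fc > 0 else ("down" if log2_fc < 0 else "none"),
                "p_value": p_value,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def concordance_check(qpcr: pd.DataFrame, de: pd.DataFrame) -> pd.DataFrame:
    """Direction agreement between qPCR and array differential expression.

    Joins on gene ID (qPCR result vs DE result, both indexed by feature) and
    flags whether the up/down calls agree. The summary fraction is stored in
    ``result.attrs["agreement_fraction"]``.
    """
    shared = qpcr.index.intersection(de.index)
    if shared.empty:
        raise ValueError("no shared gene IDs between qPCR and DE tables")
    out = pd.DataFrame(
        {
            "qpcr_direction": qpcr.loc[shared, "direction"],
            "array_direction": de.loc[shared, "direction"],
            "qpcr_log2_fc": qpcr.loc[shared, "log2_fold_change"],
            "array_log2_fc": de.loc[shared, "log2_ratio"],
        }
    )
    out["agree"] = out["qpcr_direction"] == out["array_direction"]
    out.attrs["agreement_fraction"] = float(out["agree"].mean())
    return out
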