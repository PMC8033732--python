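"""Hypergeometric gene-set enrichment with Benjamini–Hochberg FDR.

Used twice in the pipeline: to annotate each lncRNA with the GO/KEGG terms
over-represented among its co-expressed mRNAs (guilt by association), and to
score the overlap between a lncRNA's co-expressed mRNAs and transcription
factor regulons (trans-regulation screening).

The enrichment p-value is the upper tail P(X >= k) of the hypergeometric
distribution — drawing the query from a universe of N genes of which K
belong to the set — which is the over-representation direction of the
cumulative distribution function. Significance requires raw p < 0.05 AND
BH q < 0.01 (both strict), with BH computed within each gene-set category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import GeneSetCollection

__all__ = [
    "hypergeom_upper_tail",
    "bh_fdr",
    "enrich_query",
    "annotate_lncrnas",
    "LncAnnotationResult",
]

RESULT_COLUMNS = [
    "set_name",
    "category",
    "universe_size",
    "set_size",
    "query_size",
    "overlap",
    "p_value",
    "q_value",
    "overlap_members",
]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # survival function is evaluated in log space internally; stable for large N
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_query(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test every set in *collection* for over-representation in *query*.

    Sets are intersected with the universe first; sets that empty out are
    dropped. The query must be a subset of the universe. One row per tested
    set, BH-adjusted across all tested sets of the collection (one category).
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not query:
        raise ValueError("empty query")
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError(f"query genes outside universe: {sorted(query - universe)[:5]}")
    restricted = collection.restrict(universe)
    N, n = len(universe), len(query)
    rows = []
    for name, members in sorted(restricted.sets.items()):
        overlap = sorted(query & members)
        rows.append(
            {
                "set_name": name,
                "category": collection.category,
                "universe_size": N,
                "set_size": len(members),
                "query_size": n,
                "overlap": len(overlap),
                "p_value": hypergeom_upper_tail(len(overlap), len(members), n, N),
                "overlap_members": ",".join(overlap),
            }
        )
    result = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "q_value"])
    result["q_value"] = bh_fdr(result["p_value"]) if len(result) else []
    return result[RESULT_COLUMNS]


@dataclass
class LncAnnotationResult:
    """Guilt-by-association annotations of lncRNAs.

    ``annotations`` holds the significant (lncRNA, gene set) assignments;
    ``per_lncrna`` has one row for every queried lncRNA (kept even when no
    annotation is significant); ``hit_counts`` ranks annotations by how many
    lncRNAs they were assigned to (the pooled "hit number" summary).
    """

    annotations: pd.DataFrame
    per_lncrna: pd.DataFrame
    hit_counts: pd.DataFrame


def annotate_lncrnas(
    edges: pd.DataFrame,
    collection: GeneSetCollection,
    universe: Iterable[str],
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.01,
    top_k: int = 20,
) -> LncAnnotationResult:
    """Assign each lncRNA the sets enriched among its co-expressed mRNAs.

    For every lncRNA in *edges*, its co-expressed mRNAs (intersected with
    the universe) form the query. Sets with p < p_threshold and BH
    q < fdr_threshold are assigned, at most *top_k* per lncRNA (best p
    first). Enrichment is skipped (no annotations) for lncRNAs whose query
    empties out after intersection.
    """
    if edges.empty:
        raise ValueError("no co-expression edges to annotate from")
    universe = frozenset(universe)
    ann_frames = []
    per_lnc_rows = []
    for lnc, sub in edges.groupby("lncrna_id", sort=True):
        query = frozenset(sub["mrna_id"]) & universe
        n_sig = 0
        if query:
            res = enrich_query(query, collection, universe)
            sig = res[(res["p_value"] < p_threshold) & (res["q_value"] < fdr_threshold)]
            sig = sig.sort_values(["p_value", "set_name"], kind="mergesort").head(top_k)
            n_sig = len(sig)
            if n_sig:
                ann_frames.append(sig.assign(lncrna_id=lnc))
        per_lnc_rows.append(
            {"lncrna_id": lnc, "n_coexpressed_mrnas": len(query), "n_significant_sets": n_sig}
        )
    annotations = (
        pd.concat(ann_frames, ignore_index=True)[["lncrna_id"] + RESULT_COLUMNS]
        if ann_frames
        else pd.DataFrame(columns=["lncrna_id"] + RESULT_COLUMNS)
    )
    per_lncrna = pd.DataFrame(per_lnc_rows)
    hit_counts = (
        annotations.groupby(["set_name", "category"], sort=True)
        .size()
        .rename("n_lncrnas")
        .reset_index()
        .sort_values(["n_lncrnas", "set_name"], ascending=[False, True], ignore_index=True)
        if len(annotations)
        else pd.DataFrame(columns=["set_name", "category", "n_lncrnas"])
    )
    return LncAnnotationResult(annotations=annotations, per_lncrna=per_lncrna, hit_counts=hit_counts)
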