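"""Cis- and trans-regulatory inference and network construction.

A co-expression edge is a candidate *cis* regulation when the two loci share
a chromosome and lie within 100 kbp of each other (nearest interval edges,
overlap = distance 0, boundary inclusive; strand is ignored because the
window spans both sides of the lncRNA). A lncRNA is a candidate *trans*
regulator through a transcription factor when its co-expressed mRNAs overlap
the TF's regulon significantly (hypergeometric p < 0.05 and BH FDR < 0.01).

"Prediction reliability" for ranking the top lncRNA–TF links is
operationalised as the enrichment p-value (ascending), with ties broken by
overlap size (descending) and then names.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import networkx as nx
import pandas as pd

from .enrich import enrich_query
from .expression_io import GeneLociCatalog, GeneSetCollection

__all__ = ["find_cis_pairs", "find_trans_links", "build_networks", "summarize_network"]

CIS_COLUMNS = ["lncrna_id", "mrna_id", "chromosome", "genomic_distance", "r", "p_value", "sign"]


def _gap_distance(row_a: pd.Series, row_b: pd.Series) -> int:
    """bp gap between nearest edges of two intervals; 0 when they overlap."""
    return max(row_a["start"] - row_b["end"], row_b["start"] - row_a["end"], 0)


def _tss(row: pd.Series) -> int:
    return int(row["end"]) if row["strand"] == "-" else int(row["start"])


def find_cis_pairs(
    edges: pd.DataFrame,
    loci: GeneLociCatalog,
    window: int = 100_000,
    *,
    mode: str = "gap",
) -> pd.DataFrame:
    """Co-expression edges whose endpoints are within *window* bp (inclusive).

    ``mode="gap"`` (default) measures the nearest-edge gap between the two
    intervals; ``mode="tss"`` measures |TSS - TSS| instead. Pairs missing a
    locus are skipped with a warning.
    """
    if mode not in ("gap", "tss"):
        raise ValueError("mode must be 'gap' or 'tss'")
    rows = []
    skipped = []
    for edge in edges.itertuples(index=False):
        if edge.lncrna_id not in loci or edge.mrna_id not in loci:
            skipped.append((edge.lncrna_id, edge.mrna_id))
            continue
        locus_l = loci.locus(edge.lncrna_id)
        locus_m = loci.locus(edge.mrna_id)
        if locus_l["chrom"] != locus_m["chrom"]:
            continue
        if mode == "gap":
            distance = int(_gap_distance(locus_l, locus_m))
        else:
            distance = abs(_tss(locus_l) - _tss(locus_m))
        if distance <= window:
            rows.append(
                {
                    "lncrna_id": edge.lncrna_id,
                    "mrna_id": edge.mrna_id,
                    "chromosome": locus_l["chrom"],
                    "genomic_distance": distance,
                    "r": edge.r,
                    "p_value": edge.p_value,
                    "sign": edge.sign,
                }
            )
    if skipped:
        warnings.warn(f"{len(skipped)} pair(s) skipped for missing loci, e.g. {skipped[:3]}")
    return pd.DataFrame(rows, columns=CIS_COLUMNS)


def find_trans_links(
    edges: pd.DataFrame,
    tf_collection: GeneSetCollection,
    universe: Iterable[str],
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """(lncRNA, TF) links whose regulon overlap passes both thresholds.

    For each lncRNA, its co-expressed mRNAs are tested against every TF
    regulon; BH adjustment runs across the regulons tested for that lncRNA.
    """
    if tf_collection.category != "TF":
        raise ValueError("tf_collection must have category 'TF'")
    universe = frozenset(universe)
    frames = []
    for lnc, sub in edges.groupby("lncrna_id", sort=True):
        query = frozenset(sub["mrna_id"]) & universe
        if not query:
            continue
        res = enrich_query(query, tf_collection, universe)
        hit = res[(res["p_value"] < p_threshold) & (res["q_value"] < fdr_threshold)]
        if len(hit):
            frames.append(hit.assign(lncrna_id=lnc).rename(columns={"set_name": "tf_name"}))
    if not frames:
        return pd.DataFrame(
            columns=["lncrna_id", "tf_name", "category", "universe_size", "set_size",
                     "query_size", "overlap", "p_value", "q_value", "overlap_members"]
        )
    out = pd.concat(frames, ignore_index=True)
    cols = ["lncrna_id", "tf_name"] + [c for c in out.columns if c not in ("lncrna_id", "tf_name")]
    return out[cols]


def _rank_links(trans_links: pd.DataFrame) -> pd.DataFrame:
    return trans_links.sort_values(
        ["p_value", "overlap", "lncrna_id", "tf_name"],
        ascending=[True, False, True, True],
        kind="mergesort",
        ignore_index=True,
    )


def build_networks(
    trans_links: pd.DataFrame,
    edges: pd.DataFrame,
    top_pairs: int = 100,
    top_core: int = 10,
) -> tuple[nx.DiGraph, nx.DiGraph]:
    """The lncRNA–TF network and the core lncRNA–TF–mRNA network.

    The two-element network keeps the *top_pairs* most reliable lncRNA–TF
    links; the three-element core network expands the *top_core* best links
    with the co-expressed mRNAs that belong to the TF's regulon (typed
    ``coexp+``/``coexp-`` lncRNA–mRNA edges and ``trans`` TF–mRNA edges).
    """
    ranked = _rank_links(trans_links)
    edge_sign = {
        (e.lncrna_id, e.mrna_id): e.sign for e in edges.itertuples(index=False)
    }

    def _add_link(g: nx.DiGraph, link) -> None:
        g.add_node(link.lncrna_id, node_type="lncRNA")
        g.add_node(link.tf_name, node_type="TF")
        g.add_edge(link.lncrna_id, link.tf_name, interaction="trans", p_value=link.p_value)

    two = nx.DiGraph()
    for link in ranked.head(top_pairs).itertuples(index=False):
        _add_link(two, link)

    three = nx.DiGraph()
    for link in ranked.head(top_core).itertuples(index=False):
        _add_link(three, link)
        members = link.overlap_members.split(",") if link.overlap_members else []
        for mrna in members:
            three.add_node(mrna, node_type="mRNA")
            three.add_edge(link.tf_name, mrna, interaction="trans")
            sign = edge_sign.get((link.lncrna_id, mrna))
            if sign is not None:
                three.add_edge(link.lncrna_id, mrna, interaction=f"coexp{sign}")
    return two, three


def summarize_network(pairs: pd.DataFrame) -> dict[str, int]:
    """Distinct-endpoint and sign counts of a cis-pair (or similar) table.

    Accepts any table with ``lncrna_id`` and ``mrna_id`` columns and a
    correlation column named ``r`` or ``correlation``.
    """
    if pairs.empty:
        return {
            "n_pairs": 0, "n_lncrnas": 0, "n_mrnas": 0,
            "n_positive": 0, "n_negative": 0,
        }
    r_col = "r" if "r" in pairs.columns else "correlation"
    r = pairs[r_col].astype(float)
    return {
        "n_pairs": int(len(pairs)),
        "n_lncrnas": int(pairs["lncrna_id"].nunique()),
        "n_mrnas": int(pairs["mrna_id"].nunique()),
        "n_positive": int((r > 0).sum()),
        "n_negative": int((r < 0).sum()),
    }
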