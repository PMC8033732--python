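import numpy as np
import pandas as pd
import pytest

from lncfun.coexpression import build_coexpression_edges
from lncfun.diffexpr import log2_transform
from lncfun.enrich import hypergeom_upper_tail
from lncfun.expression_io import GeneLociCatalog, GeneSetCollection, load_cis_table_fixture
from lncfun.regnet import build_networks, find_cis_pairs, find_trans_links, summarize_network


def _loci(rows) -> GeneLociCatalog:
    df = pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "strand"])
    return GeneLociCatalog(df.set_index("name"))


def _edge(l, m, r=0.9, p=0.001):
    return {"lncrna_id": l, "mrna_id": m, "r": r, "p_value": p, "sign": "+" if r >= 0 else "-"}


class TestFindCisPairs:
    def test_same_chromosome_within_window_retained(self):
        loci = _loci(
            [("lnc-CXCL12-4", "chr10", 44000000, 44002000, "+"),
             ("CXCL12", "chr10", 44060000, 44090000, "-")]
        )
        edges = pd.DataFrame([_edge("lnc-CXCL12-4", "CXCL12", r=0.966)])
        cis = find_cis_pairs(edges, loci)
        assert len(cis) == 1
        assert cis["chromosome"].iloc[0] == "chr10"
        assert cis["genomic_distance"].iloc[0] == 44060000 - 44002000

    def test_different_chromosomes_excluded(self):
        loci = _loci([("l1", "chr1", 0, 1000, "+"), ("m1", "chr2", 0, 1000, "+")])
        assert find_cis_pairs(pd.DataFrame([_edge("l1", "m1")]), loci).empty

    def test_gap_exactly_window_included(self):
        loci = _loci(
            [("l1", "chr1", 0, 1000, "+"), ("m1", "chr1", 101000, 102000, "+")]
        )
        cis = find_cis_pairs(pd.DataFrame([_edge("l1", "m1")]), loci, window=100_000)
        assert len(cis) == 1 and cis["genomic_distance"].iloc[0] == 100_000

    def test_one_bp_beyond_window_excluded(self):
        loci = _loci(
            [("l1", "chr1", 0, 1000, "+"), ("m1", "chr1", 101001, 102000, "+")]
        )
        assert find_cis_pairs(pd.DataFrame([_edge("l1", "m1")]), loci).empty

    def test_overlapping_intervals_distance_zero(self):
        loci = _loci([("l1", "chr1", 0, 5000, "+"), ("m1", "chr1", 2000, 7000, "-")])
        cis = find_cis_pairs(pd.DataFrame([_edge("l1", "m1")]), loci)
        assert cis["genomic_distance"].iloc[0] == 0

    def test_missing_locus_skipped_with_warning(self):
        loci = _loci([("l1", "chr1", 0, 1000, "+")])
        with pytest.warns(UserWarning, match="missing loci"):
            cis = find_cis_pairs(pd.DataFrame([_edge("l1", "m1")]), loci)
        assert cis.empty

    def test_distance_symmetric_under_endpoint_swap(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            s1, s2 = rng.integers(0, 300_000, size=2)
            loci = _loci(
                [("l1", "chr1", s1, s1 + 1000, "+"), ("m1", "chr1", s2, s2 + 1000, "+")]
            )
            swapped = _loci(
                [("l1", "chr1", s2, s2 + 1000, "+"), ("m1", "chr1", s1, s1 + 1000, "+")]
            )
            d1 = find_cis_pairs(pd.DataFrame([_edge("l1", "m1")]), loci, window=10**9)
            d2 = find_cis_pairs(pd.DataFrame([_edge("l1", "m1")]), swapped, window=10**9)
            assert d1["genomic_distance"].iloc[0] == d2["genomic_distance"].iloc[0]

    def test_matches_brute_force_on_random_layout(self):
        rng = np.random.default_rng(11)
        names = [f"l{i}" for i in range(8)] + [f"m{i}" for i in range(8)]
        rows, layout = [], {}
        for name in names:
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 400_000))
            rows.append((name, chrom, start, start + 1000, "+"))
            layout[name] = (chrom, start, start + 1000)
        loci = _loci(rows)
        edges = pd.DataFrame([_edge(l, m) for l in layout if l[0] == "l" for m in layout if m[0] == "m"])
        got = set(
            zip(*(find_cis_pairs(edges, loci, window=100_000)[c] for c in ("lncrna_id", "mrna_id")))
        )
        expected = set()
        for e in edges.itertuples(index=False):
            (c1, s1, e1), (c2, s2, e2) = layout[e.lncrna_id], layout[e.mrna_id]
            if c1 == c2 and max(s1 - e2, s2 - e1, 0) <= 100_000:
                expected.add((e.lncrna_id, e.mrna_id))
        assert got == expected

    def test_tss_mode_uses_strand(self):
        # gap between intervals is 0 (overlap) but TSSs are 150 kbp apart
        loci = _loci(
            [("l1", "chr1", 0, 160_000, "+"), ("m1", "chr1", 100_000, 150_000, "-")]
        )
        edges = pd.DataFrame([_edge("l1", "m1")])
        assert len(find_cis_pairs(edges, loci, mode="gap")) == 1
        assert find_cis_pairs(edges, loci, mode="tss").empty


class TestFindTransLinks:
    def test_planted_regulon_recovered(self, small_dataset):
        matrix, _, collections, truth = small_dataset
        log2 = log2_transform(matrix)
        lncs = sorted({l for l, _, _ in truth.coexpressed_pairs})
        mrnas = sorted({m for _, m, _ in truth.coexpressed_pairs})
        edges = build_coexpression_edges(log2, lncs, mrnas)
        links = find_trans_links(edges, collections["TF"], matrix.features_of_class("mRNA"))
        got = set(zip(links["lncrna_id"], links["tf_name"]))
        recovered_lncs = set(edges["lncrna_id"])
        expected = {(l, tf) for l, tf in truth.trans_links if l in recovered_lncs}
        assert expected <= got

    def test_disjoint_regulons_give_no_links(self):
        universe = [f"g{i}" for i in range(100)]
        tf = GeneSetCollection(
            sets={"TFX": frozenset(f"g{i}" for i in range(50, 60))}, category="TF"
        )
        edges = pd.DataFrame([_edge("l1", f"g{i}") for i in range(5)])
        assert find_trans_links(edges, tf, universe).empty

    def test_thresholds_off_links_everything(self):
        universe = [f"g{i}" for i in range(30)]
        tf = GeneSetCollection(
            sets={"TF1": frozenset(["g0"]), "TF2": frozenset(["g20", "g21"])},
            category="TF",
        )
        edges = pd.DataFrame([_edge("l1", "g0"), _edge("l2", "g1")])
        links = find_trans_links(edges, tf, universe, p_threshold=1.1, fdr_threshold=1.1)
        assert len(links) == 4  # every (lncRNA, TF) pair tested

    def test_stored_enrichment_reverifies(self, small_dataset):
        matrix, _, collections, truth = small_dataset
        log2 = log2_transform(matrix)
        lncs = sorted({l for l, _, _ in truth.coexpressed_pairs})
        mrnas = sorted({m for _, m, _ in truth.coexpressed_pairs})
        edges = build_coexpression_edges(log2, lncs, mrnas)
        universe = matrix.features_of_class("mRNA")
        links = find_trans_links(edges, collections["TF"], universe)
        for link in links.itertuples(index=False):
            p = hypergeom_upper_tail(
                link.overlap, link.set_size, link.query_size, link.universe_size
            )
            assert link.p_value == pytest.approx(p, rel=1e-12)

    def test_wrong_category_rejected(self):
        go = GeneSetCollection(sets={"S": frozenset(["g0"])}, category="GO_BP")
        with pytest.raises(ValueError, match="category 'TF'"):
            find_trans_links(pd.DataFrame([_edge("l1", "g0")]), go, ["g0"])


class TestBuildNetworks:
    def _links(self, rows):
        return pd.DataFrame(
            rows,
            columns=["lncrna_id", "tf_name", "p_value", "overlap", "overlap_members"],
        )

    def test_all_links_kept_when_below_top(self):
        links = self._links(
            [(f"l{i}", f"TF{i}", 0.001 * (i + 1), 5, "") for i in range(5)]
        )
        two, _ = build_networks(links, pd.DataFrame(columns=["lncrna_id", "mrna_id", "sign"]))
        assert two.number_of_edges() == 5

    def test_ranking_matches_brute_force(self):
        rng = np.random.default_rng(2)
        rows = [
            (f"l{rng.integers(0, 9)}", f"TF{rng.integers(0, 9)}",
             float(rng.choice([1e-5, 1e-4, 1e-3])), int(rng.integers(1, 9)), "")
            for _ in range(30)
        ]
        links = self._links(rows).drop_duplicates(["lncrna_id", "tf_name"])
        expected = sorted(
            links.itertuples(index=False),
            key=lambda x: (x.p_value, -x.overlap, x.lncrna_id, x.tf_name),
        )[:10]
        _, three = build_networks(
            links, pd.DataFrame(columns=["lncrna_id", "mrna_id", "sign"]), top_core=10
        )
        expected_edges = {(x.lncrna_id, x.tf_name) for x in expected}
        got_edges = {
            (u, v) for u, v, d in three.edges(data=True) if d["interaction"] == "trans"
        }
        assert got_edges == expected_edges

    def test_three_element_network_has_no_orphans(self, small_dataset):
        matrix, _, collections, truth = small_dataset
        log2 = log2_transform(matrix)
        lncs = sorted({l for l, _, _ in truth.coexpressed_pairs})
        mrnas = sorted({m for _, m, _ in truth.coexpressed_pairs})
        edges = build_coexpression_edges(log2, lncs, mrnas)
        links = find_trans_links(edges, collections["TF"], matrix.features_of_class("mRNA"))
        two, three = build_networks(links, edges)
        for g in (two, three):
            endpoints = {n for e in g.edges() for n in e}
            assert set(g.nodes()) == endpoints
            assert not any(u == v for u, v in g.edges())


class TestSummarizeNetwork:
    def test_packaged_fixture_counts(self):
        summary = summarize_network(load_cis_table_fixture())
        assert summary["n_lncrnas"] == 35
        assert summary["n_pairs"] == 41

    def test_empty_table(self):
        empty = pd.DataFrame(columns=["lncrna_id", "mrna_id", "r"])
        assert summarize_network(empty) == {
            "n_pairs": 0, "n_lncrnas": 0, "n_mrnas": 0, "n_positive": 0, "n_negative": 0,
        }

    def test_matches_naive_counts_on_random_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            k = int(rng.integers(1, 30))
            df = pd.DataFrame(
                {
                    "lncrna_id": [f"l{rng.integers(0, 10)}" for _ in range(k)],
                    "mrna_id": [f"m{rng.integers(0, 10)}" for _ in range(k)],
                    "r": rng.uniform(-1, 1, k),
                }
            )
            s = summarize_network(df)
            assert s["n_pairs"] == len(df)
            assert s["n_lncrnas"] == len(set(df["lncrna_id"]))
            assert s["n_mrnas"] == len(set(df["mrna_id"]))
            assert s["n_positive"] + s["n_negative"] == (df["r"] != 0).sum()
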