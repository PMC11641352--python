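import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgvscreen import (
    GeneSet,
    GeneSetError,
    ScoredGeneList,
    gmt_universe,
    hypergeom_enrich,
    merge_disease_genes,
    merge_neighbor_lists,
    overlap,
    rank_molecules,
    read_edge_list,
    read_gene_list,
    read_gmt,
    top_hubs,
)

from .oracles import bh_adjust, degree_tally, hypergeom_upper_tail_enumeration


def unscored(source, genes):
    return ScoredGeneList(source=source, records=tuple((g, None) for g in genes))


class TestMergeDiseaseGenes:
    def test_union_deduplicates(self):
        merged = merge_disease_genes(
            [unscored("s1", ["a", "b"]), unscored("s2", ["b", "c"]), unscored("s3", ["c", "d"])]
        )
        assert merged.genes == {"A", "B", "C", "D"}

    def test_score_filter_is_strictly_greater(self):
        scored = ScoredGeneList(
            source="db", records=(("g1", 4.9), ("g2", 5.0), ("g3", 5.1))
        )
        assert merge_disease_genes([scored], threshold=5.0).genes == {"G3"}
        assert merge_disease_genes([scored], threshold=5.0, inclusive=True).genes == {"G2", "G3"}

    def test_three_source_union_arithmetic(self):
        """Sources of sizes 1386, 859 and 770 sharing 586 multiply-listed
        symbols merge to 2429 unique genes."""
        src1 = unscored("relevance", [f"G{i:04d}" for i in range(1, 1387)])
        src2 = unscored("curated", [f"G{i:04d}" for i in range(1, 301)]
                        + [f"H{i:04d}" for i in range(1, 560)])
        src3 = unscored("mined", [f"G{i:04d}" for i in range(301, 587)]
                        + [f"K{i:04d}" for i in range(1, 485)])
        assert len(src1.records) == 1386
        assert len(src2.records) == 859
        assert len(src3.records) == 770
        merged = merge_disease_genes([src1, src2, src3])
        assert len(merged) == 2429

    def test_empty_union_rejected(self):
        with pytest.raises(GeneSetError):
            merge_disease_genes([ScoredGeneList(source="s", records=(("g", 1.0),))], threshold=5.0)
        with pytest.raises(GeneSetError):
            merge_disease_genes([])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.text(alphabet="ABCDE", min_size=1, max_size=3), min_size=1), min_size=1))
    def test_union_size_bounded_by_total(self, lists):
        sources = [unscored(f"s{i}", genes) for i, genes in enumerate(lists)]
        merged = merge_disease_genes(sources)
        normalized = [{g.upper() for g in genes} for genes in lists]
        assert len(merged) <= sum(len(s) for s in normalized)
        if len(merged) == sum(len(s) for s in normalized):
            for i, a in enumerate(normalized):
                for b in normalized[i + 1:]:
                    assert not (a & b)


class TestOverlap:
    def test_intersection_and_count(self):
        targets = GeneSet.from_iterable("t", ["g1", "g2", "g3"])
        disease = GeneSet.from_iterable("d", ["g2", "g3", "g4"])
        inter, count = overlap(targets, disease)
        assert inter.genes == {"G2", "G3"} and count == 2

    def test_disjoint_identity_and_commutativity(self):
        a = GeneSet.from_iterable("a", ["x", "y"])
        b = GeneSet.from_iterable("b", ["z"])
        assert overlap(a, b)[1] == 0
        assert overlap(a, a)[0].genes == a.genes
        assert overlap(a, b)[0].genes == overlap(b, a)[0].genes


class TestRankMolecules:
    def test_forced_ordering_with_tie_rule(self):
        disease = GeneSet.from_iterable("d", [f"g{i}" for i in range(10)])
        tmap = {
            "A": GeneSet.from_iterable("A", ["g0", "g1", "g2", "g3", "g4"]),
            "B": GeneSet.from_iterable("B", ["g0", "g1", "g2"]),
            "C": GeneSet.from_iterable("C", ["g5", "g6", "g7"]),
            "D": GeneSet.from_iterable("D", ["g8"]),
        }
        assert [m for m, _c in rank_molecules(tmap, disease, top=3)] == ["A", "B", "C"]

    def test_all_zero_counts_sort_by_id(self):
        disease = GeneSet.from_iterable("d", ["zzz"])
        tmap = {m: GeneSet.from_iterable(m, ["other"]) for m in ("b", "a", "c")}
        assert [m for m, _c in rank_molecules(tmap, disease, top=3)] == ["a", "b", "c"]

    def test_empty_map_rejected(self):
        with pytest.raises(GeneSetError):
            rank_molecules({}, GeneSet.from_iterable("d", ["g"]), top=1)

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(21)
        pool = [f"G{i:03d}" for i in range(60)]
        disease = GeneSet.from_iterable("d", pool[:30])
        tmap = {
            f"MOL{i:02d}": GeneSet.from_iterable(
                f"MOL{i:02d}", rng.choice(pool, size=rng.integers(1, 25), replace=False)
            )
            for i in range(20)
        }
        got = rank_molecules(tmap, disease, top=20)
        counts = {m: len(ts.genes & disease.genes) for m, ts in tmap.items()}
        want = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        assert got == want


class TestTopHubs:
    def test_star_center_is_the_hub(self):
        star = nx.star_graph(5)
        star = nx.relabel_nodes(star, {0: "H", **{i: f"L{i}" for i in range(1, 6)}})
        assert top_hubs(star, n=1)[0][0] == "H"

    def test_truncation_bound(self):
        g = nx.path_graph(4)
        assert len(top_hubs(g, n=10)) == 4

    def test_empty_network_rejected(self):
        with pytest.raises(GeneSetError):
            top_hubs(nx.Graph(), n=1)

    def test_matches_brute_force_degree_tally(self):
        g = nx.gnp_random_graph(30, 0.2, seed=17)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        tally = degree_tally(list(g.edges()))
        want = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
        got = [(g_, d) for g_, d in top_hubs(g, n=10) if d > 0]
        assert got == want


class TestHypergeomEnrich:
    def make_universe(self, n):
        return GeneSet.from_iterable("u", [f"g{i}" for i in range(n)])

    def test_enumerated_example(self):
        """N=10, K=5, n=4, k=4: only C(5,4)·C(5,0)+C(5,5)... = 5 of the 210
        draws contain ≥4 annotated genes."""
        universe = self.make_universe(10)
        query = GeneSet.from_iterable("q", [f"g{i}" for i in range(4)])
        annotations = {"term": {f"g{i}" for i in range(5)}}
        result = hypergeom_enrich(query, annotations, universe)[0]
        assert result.p_value == pytest.approx(5 / 210, abs=1e-12)

    def test_empty_term_gives_p_one(self):
        universe = self.make_universe(8)
        query = GeneSet.from_iterable("q", ["g0", "g1"])
        result = hypergeom_enrich(query, {"empty": set()}, universe)[0]
        assert result.p_value == 1.0 and result.overlap == 0

    def test_query_outside_universe_rejected_with_symbols(self):
        universe = self.make_universe(5)
        query = GeneSet.from_iterable("q", ["g0", "weird"])
        with pytest.raises(GeneSetError, match="WEIRD"):
            hypergeom_enrich(query, {"t": {"g0"}}, universe)

    def test_matches_exhaustive_enumeration_small_universes(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            big_n = int(rng.integers(4, 13))
            big_k = int(rng.integers(1, big_n + 1))
            n = int(rng.integers(1, big_n + 1))
            genes = [f"g{i}" for i in range(big_n)]
            universe = GeneSet.from_iterable("u", genes)
            query = GeneSet.from_iterable("q", rng.choice(genes, size=n, replace=False))
            term = set(rng.choice(genes, size=big_k, replace=False))
            result = hypergeom_enrich(query, {"t": term}, universe)[0]
            want = hypergeom_upper_tail_enumeration(
                big_n, big_k, n, len(query.genes & {g.upper() for g in term})
            )
            assert result.p_value == pytest.approx(want, abs=1e-12)

    def test_bh_adjustment_matches_step_up_rule(self):
        # p-values 0.01, 0.02, 0.03 with m=3 all adjust to 0.03
        universe = self.make_universe(40)
        query = GeneSet.from_iterable("q", [f"g{i}" for i in range(10)])
        annotations = {
            "t1": {f"g{i}" for i in range(12)},
            "t2": {f"g{i}" for i in range(5, 20)},
            "t3": {f"g{i}" for i in range(8, 30)},
        }
        results = hypergeom_enrich(query, annotations, universe)
        raw = [r.p_value for r in results]
        want = bh_adjust(raw)
        got = [r.p_adjusted for r in results]
        assert got == pytest.approx(want, abs=1e-12)
        for r in results:
            assert 0.0 <= r.p_value <= r.p_adjusted <= 1.0
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


class TestMergeNeighborLists:
    def test_union_with_single_duplicate_gives_41(self):
        hubs = GeneSet.from_iterable("hubs", ["h1", "h2"])
        list1 = GeneSet.from_iterable("n1", [f"a{i}" for i in range(20)])
        # one symbol duplicated between the two neighbor lists
        list2 = GeneSet.from_iterable("n2", [f"b{i}" for i in range(19)] + ["a0"])
        assert len(merge_neighbor_lists(hubs, [list1, list2])) == 41

    def test_disjoint_lists_add_up(self):
        hubs = GeneSet.from_iterable("hubs", ["h1", "h2"])
        lists = [
            GeneSet.from_iterable("n1", [f"a{i}" for i in range(20)]),
            GeneSet.from_iterable("n2", [f"b{i}" for i in range(20)]),
        ]
        assert len(merge_neighbor_lists(hubs, lists)) == 42

    def test_identical_lists_collapse(self):
        genes = [f"a{i}" for i in range(15)]
        hubs = GeneSet.from_iterable("hubs", genes[:2])
        lists = [GeneSet.from_iterable(f"n{i}", genes) for i in range(3)]
        assert len(merge_neighbor_lists(hubs, lists)) == 15


class TestFileFormats:
    def test_gene_list_with_scores(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("# source db\nlep\t7.2\nPOMC\t4.0\nMC4R\n")
        scored = read_gene_list(path)
        assert scored.records == (("lep", 7.2), ("POMC", 4.0), ("MC4R", None))

    def test_edge_list_drops_self_loops_and_duplicates(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("a\tb\nb\ta\nc\tc\nb\tc\n")
        g = read_edge_list(path)
        assert g.number_of_edges() == 2
        assert not list(nx.selfloop_edges(g))

    def test_gmt_round_trip_and_universe(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("path1\tdesc\tg1\tg2\ng2only\tdesc\tg2\tg3\t\n")
        annotations = read_gmt(path)
        assert annotations["path1"] == {"G1", "G2"}
        assert gmt_universe(annotations).genes == {"G1", "G2", "G3"}
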