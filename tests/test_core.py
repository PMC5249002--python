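"""Compendium model: parsing, merging, ranking, set arithmetic."""

import itertools

import pytest

from obesinet.core import (
    Compendium,
    FormatError,
    GeneRecord,
    ValidationError,
    assign_rank,
    assign_ranks,
    intersect_at_least,
    merge_sources,
    parse_gene_table,
    venn_regions,
    write_gene_table,
)


def _table(tmp_path, text, name="genes.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "symbol\tsources\tgwas_comments\tcoding\n"


class TestParseGeneTable:
    def test_empty_table_gives_empty_compendium(self, tmp_path):
        comp = parse_gene_table(_table(tmp_path, HEADER))
        assert len(comp) == 0

    def test_multi_source_row(self, tmp_path):
        text = HEADER + "BDNF\tPublications;OMIM_allelic_variants;GWAS_meta_analysis\t\tprotein_coding\n"
        comp = parse_gene_table(_table(tmp_path, text))
        assert len(comp["bdnf"].sources) == 3

    def test_duplicate_rows_merge_by_union(self, tmp_path):
        text = HEADER + "LEP\tPublications\t\tprotein_coding\nlep\tSyndromes\tnearest gene\tprotein_coding\n"
        comp = parse_gene_table(_table(tmp_path, text))
        assert len(comp) == 1
        assert comp["LEP"].sources == {"Publications", "Syndromes"}
        assert comp["LEP"].gwas_comments == {"nearest gene"}

    def test_missing_symbol_column_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            parse_gene_table(_table(tmp_path, "gene\tsources\nLEP\tPublications\n"))

    def test_unknown_source_label_names_the_row(self, tmp_path):
        text = HEADER + "LEP\tPublications\t\tprotein_coding\nMC4R\tNotASource\t\tprotein_coding\n"
        with pytest.raises(ValidationError, match="row 3"):
            parse_gene_table(_table(tmp_path, text))

    def test_write_read_round_trip(self, tmp_path, rng):
        comp = Compendium()
        sources = ["Publications", "OMIM_all_text", "GWAS_meta_analysis", "Syndromes"]
        for i in range(30):
            picked = {sources[j] for j in rng.choice(4, size=rng.integers(1, 4), replace=False)}
            comments = {"biological candidate"} if rng.random() < 0.3 else set()
            comp.add(GeneRecord(symbol=f"G{i:03d}", sources=picked, gwas_comments=comments))
        path = tmp_path / "out.tsv"
        write_gene_table(comp, path)
        back = parse_gene_table(path)
        assert back.symbols() == comp.symbols()
        for rec in comp:
            assert back[rec.symbol].sources == rec.sources
            assert back[rec.symbol].gwas_comments == rec.gwas_comments


class TestMergeSources:
    def test_disjoint_union(self):
        comp = merge_sources(
            [("Publications", {"A", "B", "C"}), ("Syndromes", {"D", "E", "F", "G"})]
        )
        assert len(comp) == 7

    def test_gwas_brain_overlap_sizes(self, fixture_bundle):
        """34 TSEA-brain + 50 DEG GWAS genes sharing 13 -> 71 unique."""
        venn = fixture_bundle["gwas_venn"]
        comp = merge_sources(
            [("Publications", venn["TSEA_brain"]), ("Syndromes", venn["DEG"])]
        )
        assert len(comp) == 71

    def test_against_brute_force_union(self, rng):
        labels = ["Publications", "OMIM_allelic_variants", "GWAS_meta_analysis"]
        pool = [f"G{i}" for i in range(40)]
        sets = [
            (lab, {pool[j] for j in rng.choice(40, size=15, replace=False)})
            for lab in labels
        ]
        comp = merge_sources(sets)
        expected = {}
        for lab, symbols in sets:
            for s in symbols:
                expected.setdefault(s, set()).add(lab)
        assert comp.symbols() == set(expected)
        for sym, labs in expected.items():
            assert comp[sym].sources == labs

    def test_inclusion_exclusion(self, rng):
        a = {f"G{i}" for i in rng.choice(50, size=20, replace=False)}
        b = {f"G{i}" for i in rng.choice(50, size=25, replace=False)}
        comp = merge_sources([("Publications", a), ("Syndromes", b)])
        assert len(comp) == len(a) + len(b) - len(a & b)

    def test_idempotent_and_order_independent(self):
        sets = [("Publications", {"A", "B"}), ("Syndromes", {"B", "C"})]
        once = merge_sources(sets)
        twice = merge_sources(sets + sets)
        swapped = merge_sources(sets[::-1])
        for other in (twice, swapped):
            assert other.symbols() == once.symbols()
            assert all(other[s].sources == once[s].sources for s in once.symbols())

    def test_empty_input_gives_empty_compendium(self):
        assert len(merge_sources([])) == 0

    def test_provenance_counts_match_membership(self, rng):
        comp = merge_sources(
            [("Publications", {"A", "B"}), ("GWAS_meta_analysis", {"B", "C", "D"})]
        )
        prov = comp.provenance
        assert prov["Publications"] == 2
        assert prov["GWAS_meta_analysis"] == 3


class TestAssignRank:
    def test_curated_source_gives_rank_1(self):
        rec = assign_rank(GeneRecord(symbol="LEP", sources={"Publications"}))
        assert rec.rank == "Rank_1"

    def test_gwas_with_biological_tag_gives_rank_1(self):
        rec = assign_rank(
            GeneRecord(
                symbol="FTO",
                sources={"GWAS_meta_analysis"},
                gwas_comments={"Biological candidate"},
            )
        )
        assert rec.rank == "Rank_1"

    def test_gwas_without_comment_gives_rank_2(self):
        rec = assign_rank(GeneRecord(symbol="X1", sources={"GWAS_meta_analysis"}))
        assert rec.rank == "Rank_2"

    def test_tag_match_is_exact_not_substring(self):
        rec = assign_rank(
            GeneRecord(
                symbol="X1",
                sources={"GWAS_meta_analysis"},
                gwas_comments={"maybe a biological candidate gene"},
            )
        )
        assert rec.rank == "Rank_2"

    def test_empty_sources_rejected(self):
        with pytest.raises(ValidationError):
            assign_rank(GeneRecord(symbol="X1", sources=set()))

    def test_rank2_records_are_gwas_only(self, rng):
        """Every Rank_2 record comes entirely from the GWAS set."""
        labels = ["Publications", "Syndromes", "GWAS_meta_analysis"]
        comp = Compendium()
        for i in range(60):
            picked = {labels[j] for j in rng.choice(3, size=rng.integers(1, 3), replace=False)}
            comp.add(GeneRecord(symbol=f"G{i}", sources=picked))
        assign_ranks(comp)
        for rec in comp:
            if rec.rank == "Rank_2":
                assert rec.sources == {"GWAS_meta_analysis"}
            if rec.sources != {"GWAS_meta_analysis"}:
                assert rec.rank == "Rank_1"


class TestIntersectAtLeast:
    def test_k1_returns_all(self, fixture_bundle):
        comp = fixture_bundle["multi_source"]
        assert intersect_at_least(comp, 1) == comp.symbols()

    def test_printed_multi_source_genes(self, fixture_bundle):
        """The eight genes present in at least three (OMIM-collapsed) sets."""
        found = intersect_at_least(fixture_bundle["multi_source"], 3)
        assert found == {
            "BDNF", "MC4R", "NTRK2", "PCSK1", "POMC", "SH2B1", "TUB", "BBS4",
        }

    def test_omim_collapse_changes_counting(self):
        comp = Compendium(
            [GeneRecord(symbol="A", sources={"OMIM_allelic_variants", "OMIM_all_text", "Publications"})]
        )
        assert intersect_at_least(comp, 3, collapse_omim=False) == {"A"}
        assert intersect_at_least(comp, 3, collapse_omim=True) == set()

    def test_against_brute_force(self, rng):
        labels = list(
            {"Publications", "OMIM_allelic_variants", "OMIM_all_text",
             "Syndromes", "GWAS_meta_analysis"}
        )
        comp = Compendium()
        for i in range(40):
            picked = {labels[j] for j in rng.choice(5, size=rng.integers(1, 6), replace=False)}
            comp.add(GeneRecord(symbol=f"G{i}", sources=picked))
        for k in range(1, 6):
            expected = set()
            for rec in comp:
                eff = {("OMIM" if s.startswith("OMIM") else s) for s in rec.sources}
                if len(eff) >= k:
                    expected.add(rec.symbol)
            assert intersect_at_least(comp, k) == expected

    def test_invalid_k(self, fixture_bundle):
        with pytest.raises(ValidationError):
            intersect_at_least(fixture_bundle["multi_source"], 0)


class TestVennRegions:
    def test_identical_pair(self):
        regions = venn_regions({"A": {"x"}, "B": {"x"}})
        assert regions == {"A": 0, "B": 0, "A&B": 1}

    def test_printed_gwas_brain_regions(self, fixture_bundle):
        """TSEA-brain (34) vs DEG (50) within GWAS: regions 21 / 37 / 13."""
        venn = fixture_bundle["gwas_venn"]
        regions = venn_regions({"TSEA": venn["TSEA_brain"], "DEG": venn["DEG"]})
        assert regions == {"TSEA": 21, "DEG": 37, "TSEA&DEG": 13}

    def test_three_sets_against_enumeration(self, rng):
        pool = [f"G{i}" for i in range(30)]
        sets = {
            name: {pool[j] for j in rng.choice(30, size=12, replace=False)}
            for name in ("A", "B", "C")
        }
        regions = venn_regions(sets)
        for r in range(1, 4):
            for combo in itertools.combinations(("A", "B", "C"), r):
                expected = set(pool)
                for name in ("A", "B", "C"):
                    expected &= sets[name] if name in combo else (set(pool) - sets[name])
                assert regions["&".join(combo)] == len(expected)
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_more_than_three_sets_rejected(self):
        with pytest.raises(ValidationError):
            venn_regions({n: set() for n in "ABCD"})
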