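"""Annotation parsing, copy census and nifH context typing."""

import warnings

import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_nifh_types
from pseudonif.genome_census import (
    BalanceCategory,
    CdsRecord,
    CopyCounts,
    GenomeAnnotation,
    census_summary,
    classify_nifh,
    copy_balance_category,
    filter_genomes,
    gene_class,
    genome_type_flags,
    nitrogenase_copy_counts,
    parse_feature_table,
    parse_gff3,
    percentage,
    write_feature_table,
)

FT_HEADER = "#replicon\tstart\tend\tstrand\tfeature\tgene\tlocus_tag\tproduct\tpseudo\n"


def ft_row(rep="chr1", start=1, end=900, strand="+", feature="CDS",
           gene="nifh", tag="L1", product="nitrogenase iron protein", pseudo=""):
    return f"{rep}\t{start}\t{end}\t{strand}\t{feature}\t{gene}\t{tag}\t{product}\t{pseudo}\n"


class TestFeatureTableParser:
    def test_toy_table_in_coordinate_order(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            FT_HEADER
            + ft_row(start=2001, end=2900, tag="L3", gene="nifk")
            + ft_row(start=1, end=900, tag="L1", gene="nifh")
            + ft_row(start=1001, end=1900, tag="L2", gene="nifd")
        )
        ann = parse_feature_table(path)
        assert [r.locus_tag for r in ann.records] == ["L1", "L2", "L3"]

    def test_pseudo_flag_parsed(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(FT_HEADER + ft_row(pseudo="true"))
        ann = parse_feature_table(path)
        assert ann.records[0].is_pseudo

    def test_non_cds_rows_dropped(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(FT_HEADER + ft_row(feature="gene") + ft_row(tag="L2"))
        ann = parse_feature_table(path)
        assert [r.locus_tag for r in ann.records] == ["L2"]

    def test_malformed_row_names_line_number(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(FT_HEADER + ft_row() + "chr1\tonly\tthree\n")
        with pytest.raises(ValueError, match=r":3"):
            parse_feature_table(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(FT_HEADER)
        with pytest.warns(UserWarning, match="empty"):
            ann = parse_feature_table(path)
        assert ann.records == []


GFF = """##gff-version 3
chr1\tsim\tCDS\t100\t999\t.\t-\t0\tID=c1;locus_tag=L1;gene=nifH;product=nitrogenase iron protein
"""


class TestGff3Parser:
    def test_minus_strand_preserved(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(GFF)
        ann = parse_gff3(path)
        assert ann.records[0].strand == "-"
        assert ann.records[0].gene_symbol == "nifh"
        assert (ann.records[0].start, ann.records[0].end) == (100, 999)

    def test_missing_locus_tag_synthesized_with_warning(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text("chr1\tsim\tCDS\t1\t90\t.\t+\t0\tID=c1;gene=nifH\n")
        with pytest.warns(UserWarning, match="synthesized"):
            ann = parse_gff3(path)
        assert ann.records[0].locus_tag

    def test_gene_features_only_warns_empty(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text("chr1\tsim\tgene\t1\t90\t.\t+\t.\tID=g1\n")
        with pytest.warns(UserWarning, match="no CDS"):
            ann = parse_gff3(path)
        assert ann.records == []

    def test_round_trip_feature_table_gff3_equivalence(self, tmp_path, genome_factory):
        genome = genome_factory("G1", ["nifh", "dnaa", ("nifd", "-"), "nifk"])
        ft = tmp_path / "G1.tsv"
        write_feature_table(genome, ft)
        from_ft = parse_feature_table(ft, genome_id="G1")
        gff = tmp_path / "G1.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in genome.records:
                fh.write(
                    f"{r.replicon_id}\tsim\tCDS\t{r.start}\t{r.end}\t.\t{r.strand}\t0\t"
                    f"locus_tag={r.locus_tag};gene={r.gene_symbol};product={r.product}\n"
                )
        from_gff = parse_gff3(gff, genome_id="G1")
        assert from_ft.records == from_gff.records
        assert classify_nifh(from_ft) == classify_nifh(from_gff)


class TestFilterGenomes:
    def meta(self, **completeness):
        return pd.DataFrame(
            [
                {"genome_id": g, "genus": "clostridium", "species": "sp",
                 "completeness": c}
                for g, c in completeness.items()
            ]
        )

    def test_completeness_boundary_inclusive(self, genome_factory, config):
        genomes = [genome_factory(g, ["nifh"]) for g in ("A", "B")]
        kept = filter_genomes(genomes, self.meta(A=0.95, B=0.94), config)
        assert [g.genome_id for g in kept] == ["A"]

    def test_missing_completeness_excluded_with_warning(self, genome_factory, config):
        genomes = [genome_factory("A", ["nifh"])]
        with pytest.warns(UserWarning, match="completeness"):
            kept = filter_genomes(genomes, self.meta(A=np.nan), config)
        assert kept == []

    def test_pseudogene_only_nifh_genome_dropped(self, config):
        rec = CdsRecord("chr", 1, 900, "+", "L1", "nifh",
                        "nitrogenase iron protein", is_pseudo=True)
        genome = GenomeAnnotation(genome_id="A", records=[rec])
        meta = self.meta(A=1.0)
        assert filter_genomes([genome], meta, config) == []


class TestCopyCounts:
    @pytest.mark.parametrize(
        "genes, expected",
        [
            (["nifh", "nifd", "nifk"], (1, 1, 1)),
            (["nifh", "vnfd"], (1, 1, 0)),
            (["nifh", ("nifh", "+", "plasmid_1")], (2, 0, 0)),
            (["anfd", "anfk", "vnfk"], (0, 1, 2)),
        ],
    )
    def test_symbol_membership(self, genome_factory, genes, expected):
        counts = nitrogenase_copy_counts(genome_factory("G", genes))
        assert (counts.n_H, counts.n_Dlike, counts.n_Klike) == expected

    def test_product_fallback_when_symbol_missing(self, genome_factory):
        g = genome_factory("G", [""])
        # product says nitrogenase iron protein even though symbol is empty
        assert gene_class(g.records[0]) is None
        rec = CdsRecord("chr", 1, 900, "+", "L", "", "nitrogenase iron protein")
        assert gene_class(rec) == "H"


class TestBalanceCategory:
    @pytest.mark.parametrize(
        "counts, category, only_h",
        [
            ((1, 1, 1), BalanceCategory.EQUAL, False),
            ((2, 1, 1), BalanceCategory.H_EXCESS, False),
            ((3, 0, 0), BalanceCategory.H_EXCESS, True),
            ((0, 1, 0), BalanceCategory.NO_H, False),
            ((1, 2, 1), BalanceCategory.OTHER_IMBALANCE, False),
            ((2, 2, 1), BalanceCategory.OTHER_IMBALANCE, False),
        ],
    )
    def test_examples(self, counts, category, only_h):
        got = copy_balance_category(CopyCounts(*counts))
        assert got == (category, only_h)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            copy_balance_category(CopyCounts(0, 0, 0))

    def test_partition_is_total_and_exclusive(self, rng):
        for _ in range(300):
            c = CopyCounts(*(int(x) for x in rng.integers(0, 4, size=3)))
            if c.total() == 0:
                continue
            cat, only_h = copy_balance_category(c)
            assert cat in BalanceCategory
            if only_h:
                assert cat == BalanceCategory.H_EXCESS


class TestClassifyNifh:
    def test_adjacent_nifd_is_t1(self, genome_factory):
        calls = classify_nifh(genome_factory("G", ["nifh", "nifd"]))
        assert [c.nifh_type for c in calls] == ["T1"]
        assert calls[0].neighborhood_hits[0][2] == 1  # signed CDS offset

    def test_eleven_same_strand_cds_away_is_t2(self, genome_factory):
        genes = ["nifh"] + ["dnaa"] * 11 + ["nifd"]
        calls = classify_nifh(genome_factory("G", genes))
        assert [c.nifh_type for c in calls] == ["T2"]

    def test_ten_same_strand_cds_away_is_t1(self, genome_factory):
        genes = ["nifh"] + ["dnaa"] * 9 + ["nifd"]
        calls = classify_nifh(genome_factory("G", genes))
        assert [c.nifh_type for c in calls] == ["T1"]

    def test_opposite_strand_neighbors_do_not_count_distance(self, genome_factory):
        # 11 decoys between, but on the opposite strand: nifD is 1 away
        genes = ["nifh"] + [("dnaa", "-")] * 11 + ["nifd"]
        calls = classify_nifh(genome_factory("G", genes))
        assert [c.nifh_type for c in calls] == ["T1"]

    def test_opposite_strand_nifd_nearby_is_t2(self, genome_factory):
        calls = classify_nifh(genome_factory("G", ["nifh", ("nifd", "-")]))
        assert [c.nifh_type for c in calls] == ["T2"]

    def test_nifd_on_other_replicon_is_t2(self, genome_factory):
        genes = ["nifh", ("nifd", "+", "plasmid_1")]
        calls = classify_nifh(genome_factory("G", genes))
        assert [c.nifh_type for c in calls] == ["T2"]

    def test_sole_nifh_is_t3(self, genome_factory):
        calls = classify_nifh(genome_factory("G", ["dnaa", "nifh", "gyrb"]))
        assert [c.nifh_type for c in calls] == ["T3"]

    def test_vnfk_three_away_is_t1(self, genome_factory):
        genes = ["nifh", "dnaa", "dnaa", "vnfk"]
        calls = classify_nifh(genome_factory("G", genes))
        assert [c.nifh_type for c in calls] == ["T1"]
        assert calls[0].neighborhood_hits[0][1] == "vnfk"

    def test_shared_nifd_supports_both_nifh_copies(self, genome_factory):
        calls = classify_nifh(genome_factory("G", ["nifh", "nifd", "nifh"]))
        assert [c.nifh_type for c in calls] == ["T1", "T1"]

    def test_agrees_with_brute_force_on_random_layouts(self, rng):
        from conftest import make_genome

        symbols = ["nifh", "nifd", "nifk", "vnfd", "anfk", "dnaa", "gyrb", "reca"]
        for trial in range(100):
            n = int(rng.integers(1, 25))
            genes = [
                (
                    symbols[rng.integers(0, len(symbols))],
                    "+" if rng.random() < 0.5 else "-",
                    f"rep{rng.integers(0, 3)}",
                )
                for _ in range(n)
            ]
            genome = make_genome(f"G{trial}", genes)
            got = {c.locus_tag: c.nifh_type for c in classify_nifh(genome)}
            expected = brute_force_nifh_types(
                [(r, gene_class(r)) for r in genome.records], radius=10
            )
            assert got == expected

    def test_t3_never_cooccurs_with_t1_or_t2(self, genome_factory, rng):
        # mutual exclusion over random single-replicon layouts
        symbols = ["nifh", "nifd", "dnaa"]
        for trial in range(200):
            genes = [
                (symbols[rng.integers(0, 3)], "+" if rng.random() < 0.5 else "-")
                for _ in range(int(rng.integers(1, 15)))
            ]
            calls = classify_nifh(genome_factory(f"G{trial}", genes))
            types = {c.nifh_type for c in calls}
            assert not ("T3" in types and types & {"T1", "T2"})


class TestCensusSummary:
    def test_counts_by_type(self, genome_factory, config):
        genomes = [genome_factory(f"A{i}", ["nifh", "nifd", "nifk"]) for i in range(10)]
        genomes += [genome_factory(f"B{i}", ["nifh"]) for i in range(5)]
        calls = {g.genome_id: classify_nifh(g, config) for g in genomes}
        summary = census_summary(genomes, calls, config)
        assert summary["types"]["has_T1"] == 10
        assert summary["types"]["T2_not_T1"] == 0
        assert summary["types"]["has_T3"] == 5

    def test_genome_with_t1_and_t2_counted_in_both(self, genome_factory, config):
        genes = ["nifh", "nifd", "nifk"] + ["dnaa"] * 11 + ["nifh"]
        g = genome_factory("G", genes)
        calls = {"G": classify_nifh(g, config)}
        flags = genome_type_flags(calls["G"])
        assert flags["has_T1"] and flags["has_T2"]
        summary = census_summary([g], calls, config)
        assert summary["types"]["has_T1"] == 1
        assert summary["types"]["has_T2"] == 1
        assert summary["types"]["T2_not_T1"] == 0

    def test_empty_input_all_zero(self, config):
        summary = census_summary([], {}, config)
        assert summary["n_genomes"] == 0
        assert all(v == 0 for v in summary["types"].values())


class TestPercentage:
    @pytest.mark.parametrize(
        "part, whole, digits, expected",
        [
            (1457, 6529, 1, 22.3),
            (96, 1457, 2, 6.59),
            (0, 100, 1, 0.0),
            (1, 8, 1, 12.5),
        ],
    )
    def test_examples(self, part, whole, digits, expected):
        assert percentage(part, whole, digits) == expected

    def test_zero_whole_rejected(self):
        with pytest.raises(ValueError):
            percentage(1, 0)
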