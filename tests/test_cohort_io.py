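import numpy as np
import pytest

from mutgraph.cohort_io import (
    GeneCatalog,
    ValidationError,
    build_gene_catalog,
    read_count_table,
    read_gene_list,
    read_labels,
    read_mutation_counts,
    read_ppi,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=GENE,Number=.,Type=String,Description="Gene">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(path, records):
    path.write_text(VCF_HEADER + "".join(records))
    return path


def rec(gene, pos=100, filt="PASS"):
    return f"1\t{pos}\t.\tA\tT\t.\t{filt}\tGENE={gene}\n"


class TestReadMutationCounts:
    def test_counts_records_per_catalog_gene(self, tmp_path, small_catalog):
        vcf = write_vcf(
            tmp_path / "p1.vcf", [rec("TP53", 100), rec("TP53", 110), rec("BRCA1", 120)]
        )
        m = read_mutation_counts({"p1": vcf}, small_catalog)
        assert m.counts.tolist() == [[1, 0, 2]]  # catalog order BRCA1, KRAS, TP53

    def test_unknown_gene_contributes_nothing(self, tmp_path, small_catalog):
        vcf = write_vcf(tmp_path / "p1.vcf", [rec("XYZ")])
        m = read_mutation_counts({"p1": vcf}, small_catalog)
        assert m.counts.sum() == 0

    def test_empty_body_gives_zero_row(self, tmp_path, small_catalog):
        vcf = write_vcf(tmp_path / "p1.vcf", [])
        m = read_mutation_counts({"p1": vcf}, small_catalog)
        assert m.counts.tolist() == [[0, 0, 0]]

    def test_pass_only_skips_failed_filters(self, tmp_path, small_catalog):
        vcf = write_vcf(
            tmp_path / "p1.vcf",
            [rec("TP53", 100), rec("TP53", 110, filt="lowq"), rec("KRAS", 120, filt=".")],
        )
        m = read_mutation_counts({"p1": vcf}, small_catalog, pass_only=True)
        assert m.counts.tolist() == [[0, 1, 1]]

    def test_multi_gene_annotation_increments_each(self, tmp_path, small_catalog):
        vcf = (tmp_path / "p1.vcf")
        vcf.write_text(VCF_HEADER + "1\t100\t.\tA\tT\t.\tPASS\tGENE=TP53,BRCA1\n")
        m = read_mutation_counts({"p1": vcf}, small_catalog)
        assert m.counts.tolist() == [[1, 0, 1]]

    def test_record_order_is_irrelevant(self, tmp_path, small_catalog):
        records = [rec("TP53", 100), rec("BRCA1", 200), rec("KRAS", 300), rec("TP53", 400)]
        a = write_vcf(tmp_path / "a.vcf", records)
        b = write_vcf(tmp_path / "b.vcf", records[::-1])
        ma = read_mutation_counts({"p": a}, small_catalog)
        mb = read_mutation_counts({"p": b}, small_catalog)
        assert np.array_equal(ma.counts, mb.counts)

    def test_malformed_vcf_names_file(self, tmp_path, small_catalog):
        bad = tmp_path / "bad.vcf"
        bad.write_text("not a vcf at all\n")
        with pytest.raises(ValidationError, match="bad.vcf"):
            read_mutation_counts({"p1": bad}, small_catalog)


class TestReadCountTable:
    def write(self, tmp_path, header, rows):
        p = tmp_path / "counts.tsv"
        p.write_text("patient\t" + "\t".join(header) + "\n" + "\n".join(rows) + "\n")
        return p

    def test_matching_table_is_identity(self, tmp_path, small_catalog):
        p = self.write(tmp_path, small_catalog.genes, ["p1\t1\t0\t2", "p2\t3\t2\t0"])
        m = read_count_table(p, small_catalog)
        assert m.counts.tolist() == [[1, 0, 2], [3, 2, 0]]
        assert m.patients == ("p1", "p2")

    def test_columns_reordered_to_catalog(self, tmp_path, small_catalog):
        p = self.write(tmp_path, ("TP53", "KRAS", "BRCA1"), ["p1\t2\t0\t1"])
        m = read_count_table(p, small_catalog)
        assert m.counts.tolist() == [[1, 0, 2]]

    def test_missing_catalog_gene_becomes_zero_column(self, tmp_path, small_catalog):
        p = self.write(tmp_path, ("BRCA1", "TP53"), ["p1\t1\t2"])
        m = read_count_table(p, small_catalog)
        assert m.counts.tolist() == [[1, 0, 2]]

    def test_negative_cell_rejected_with_location(self, tmp_path, small_catalog):
        p = self.write(tmp_path, small_catalog.genes, ["p1\t1\t-2\t0"])
        with pytest.raises(ValidationError, match="KRAS"):
            read_count_table(p, small_catalog)


class TestReadPPI:
    def write(self, tmp_path, rows, mapping):
        links = tmp_path / "links.txt"
        links.write_text("protein1 protein2 combined_score\n" + "".join(r + "\n" for r in rows))
        mp = tmp_path / "map.tsv"
        mp.write_text("".join(f"{p}\t{g}\n" for p, g in mapping))
        return links, mp

    MAPPING = [("A", "gA"), ("B", "gB"), ("C", "gC")]

    def test_threshold_and_reciprocal_dedup(self, tmp_path):
        links, mp = self.write(tmp_path, ["A B 900", "B A 900", "B C 700"], self.MAPPING)
        net = read_ppi(links, mp, min_score=800)
        assert net.edges == {frozenset(("A", "B"))}

    def test_zero_threshold_keeps_both_edges(self, tmp_path):
        links, mp = self.write(tmp_path, ["A B 900", "B A 900", "B C 700"], self.MAPPING)
        assert len(read_ppi(links, mp, min_score=0).edges) == 2

    def test_self_edge_rejected_with_warning(self, tmp_path):
        links, mp = self.write(tmp_path, ["A A 950", "A B 900"], self.MAPPING)
        with pytest.warns(UserWarning, match="self-edge"):
            net = read_ppi(links, mp)
        assert net.edges == {frozenset(("A", "B"))}

    def test_unmapped_protein_dropped_with_edges(self, tmp_path):
        links, mp = self.write(tmp_path, ["A B 900", "B Z 950"], self.MAPPING)
        net = read_ppi(links, mp)
        assert net.edges == {frozenset(("A", "B"))}

    def test_non_numeric_score_is_parse_error(self, tmp_path):
        links, mp = self.write(tmp_path, ["A B 900", "B C high"], self.MAPPING)
        with pytest.raises(ValidationError, match="non-numeric"):
            read_ppi(links, mp)

    def test_duplicate_mapping_rejected(self, tmp_path):
        links, mp = self.write(tmp_path, ["A B 900"], [("A", "gA"), ("B", "gA")])
        with pytest.raises(ValidationError, match="one-to-one"):
            read_ppi(links, mp)

    def test_idempotent_on_own_serialization(self, tmp_path):
        links, mp = self.write(tmp_path, ["A B 900", "B C 700", "C A 500"], self.MAPPING)
        net = read_ppi(links, mp)
        rows = [f"{a} {b} {net.score[frozenset((a, b))]}" for a, b in
                sorted(tuple(sorted(e)) for e in net.edges)]
        links2 = tmp_path / "links2.txt"
        links2.write_text("protein1 protein2 combined_score\n" + "".join(r + "\n" for r in rows))
        net2 = read_ppi(links2, mp)
        assert net2.edges == net.edges and net2.score == net.score


class TestBuildGeneCatalog:
    def test_three_way_intersection(self, small_ppi):
        cat = build_gene_catalog({"BRCA1", "KRAS", "NRAS"}, {"KRAS", "TP53"}, small_ppi)
        assert cat.genes == ("KRAS",)

    def test_identical_sets_pass_through_sorted(self, small_ppi):
        cat = build_gene_catalog({"TP53", "BRCA1"}, {"TP53", "BRCA1"}, small_ppi)
        assert cat.genes == ("BRCA1", "TP53")

    def test_disjoint_sets_raise(self, small_ppi):
        with pytest.raises(ValidationError, match="empty gene catalog"):
            build_gene_catalog({"NRAS"}, {"EGFR"}, small_ppi)

    def test_catalog_never_exceeds_smallest_source(self, small_ppi):
        mutated, hallmark = {"BRCA1", "KRAS", "TP53", "X1"}, {"BRCA1", "KRAS", "TP53"}
        cat = build_gene_catalog(mutated, hallmark, small_ppi)
        assert len(cat) <= min(len(mutated), len(hallmark), len(small_ppi.proteins))


class TestSmallReaders:
    def test_labels_aliases_and_duplicates(self, tmp_path):
        p = tmp_path / "labels.tsv"
        p.write_text("p1\tcase\np2\t0\np3\tCONTROL\np4\t1\n")
        labels = read_labels(p)
        assert labels.label == {"p1": 1, "p2": 0, "p3": 0, "p4": 1}
        p.write_text("p1\tcase\np1\tcontrol\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_labels(p)

    def test_gene_list_plain_and_gmt(self, tmp_path):
        plain = tmp_path / "genes.txt"
        plain.write_text("TP53\nBRCA1\n")
        assert read_gene_list(plain) == {"TP53", "BRCA1"}
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("SET1\tdesc\tTP53\tKRAS\nSET2\tdesc\tBRCA1\n")
        assert read_gene_list(gmt) == {"TP53", "KRAS", "BRCA1"}

    def test_duplicate_gene_rejected_by_catalog(self):
        with pytest.raises(ValidationError):
            GeneCatalog(("A", "A"), {"A": "pA"})


class TestAlleleDosage:
    def test_dosage_counts_alt_alleles(self, tmp_path, small_catalog):
        vcf = tmp_path / "p1.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=.,Type=String,Description="Gene">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tT\t.\tPASS\tGENE=TP53\tGT\t0/1\n"
            "1\t200\t.\tA\tT\t.\tPASS\tGENE=TP53\tGT\t1/1\n"
            "1\t300\t.\tA\tT\t.\tPASS\tGENE=BRCA1\tGT\t0/0\n"
        )
        by_record = read_mutation_counts({"p1": vcf}, small_catalog)
        assert by_record.counts.tolist() == [[1, 0, 2]]
        by_dosage = read_mutation_counts({"p1": vcf}, small_catalog, allele_dosage=True)
        assert by_dosage.counts.tolist() == [[0, 0, 3]]  # het + hom-alt; hom-ref drops
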