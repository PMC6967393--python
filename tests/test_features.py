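from __future__ import annotations

import numpy as np
import pytest

import m6atlas as m
from m6atlas.features import CATEGORIES


def _iv1(intervals):
    """0-based half-open -> 1-based inclusive, for readable assertions."""
    return [(s + 1, e) for s, e in intervals]


class TestReadAnnotation:
    def test_plus_strand_gene_decomposition(self, toy_gff_path, toy_genome):
        """Exons [11-40, 61-100], CDS [21-40, 61-90] (1-based) must yield
        5'UTR [11-20], 3'UTR [91-100], intron [41-60]."""
        (g,) = m.read_annotation(toy_gff_path, toy_genome)
        assert g.biotype == "protein_coding"
        assert _iv1(g.utr5) == [(11, 20)]
        assert _iv1(g.utr3) == [(91, 100)]
        assert _iv1(g.introns) == [(41, 60)]
        assert _iv1(g.cds) == [(21, 40), (61, 90)]
        # exhaustive position check across the 90-bp span
        labelled = {}
        for name, ivs in (("utr5", g.utr5), ("cds", g.cds), ("utr3", g.utr3), ("intron", g.introns)):
            for s, e in ivs:
                for p in range(s, e):
                    assert p not in labelled
                    labelled[p] = name
        assert set(labelled) == set(range(10, 100))

    def test_minus_strand_utrs_swap(self, toy_gff_minus_path, toy_genome):
        (g,) = m.read_annotation(toy_gff_minus_path, toy_genome)
        assert _iv1(g.utr5) == [(91, 100)]
        assert _iv1(g.utr3) == [(11, 20)]
        assert g.tss == 99  # 0-based position of base 100

    def test_single_exon_cds_equals_exon(self, tmp_path, toy_genome):
        gff = (
            "##gff-version 3\n"
            "c1\tt\tgene\t11\t40\t.\t+\t.\tID=g1;gene_biotype=protein_coding\n"
            "c1\tt\tmRNA\t11\t40\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "c1\tt\texon\t11\t40\t.\t+\t.\tID=e1;Parent=g1.t1\n"
            "c1\tt\tCDS\t11\t40\t.\t+\t0\tID=c1x;Parent=g1.t1\n"
        )
        p = tmp_path / "t.gff3"
        p.write_text(gff)
        (g,) = m.read_annotation(p, toy_genome)
        assert g.utr5 == [] and g.utr3 == [] and g.introns == []

    def test_cds_outside_exons_rejects_gene(self, tmp_path, toy_genome):
        gff = (
            "##gff-version 3\n"
            "c1\tt\tgene\t11\t40\t.\t+\t.\tID=g1;gene_biotype=protein_coding\n"
            "c1\tt\tmRNA\t11\t40\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "c1\tt\texon\t11\t30\t.\t+\t.\tID=e1;Parent=g1.t1\n"
            "c1\tt\tCDS\t11\t40\t.\t+\t0\tID=c1x;Parent=g1.t1\n"
        )
        p = tmp_path / "t.gff3"
        p.write_text(gff)
        assert m.read_annotation(p, toy_genome) == []

    def test_multi_transcript_longest_cds_and_exon_union(self, tmp_path, toy_genome):
        gff = (
            "##gff-version 3\n"
            "c1\tt\tgene\t11\t100\t.\t+\t.\tID=g1;gene_biotype=protein_coding\n"
            "c1\tt\tmRNA\t11\t60\t.\t+\t.\tID=t1;Parent=g1\n"
            "c1\tt\texon\t11\t60\t.\t+\t.\tID=t1e;Parent=t1\n"
            "c1\tt\tCDS\t11\t60\t.\t+\t0\tID=t1c;Parent=t1\n"
            "c1\tt\tmRNA\t11\t100\t.\t+\t.\tID=t2;Parent=g1\n"
            "c1\tt\texon\t11\t100\t.\t+\t.\tID=t2e;Parent=t2\n"
            "c1\tt\tCDS\t21\t40\t.\t+\t0\tID=t2c;Parent=t2\n"
        )
        p = tmp_path / "t.gff3"
        p.write_text(gff)
        (g,) = m.read_annotation(p, toy_genome)
        assert _iv1(g.exons) == [(11, 100)]
        assert _iv1(g.cds) == [(11, 60)]  # t1 has the longer CDS


class TestBuildPartition:
    def test_base_counts_conserve_genome_size(self, toy_gff_path, toy_genome):
        models = m.read_annotation(toy_gff_path, toy_genome)
        part = m.build_partition(models, toy_genome)
        assert int(part.counts()["n_bases"].sum()) == 200

    def test_adenine_counts_conserve_total(self, toy_gff_path, toy_genome):
        models = m.read_annotation(toy_gff_path, toy_genome)
        part = m.build_partition(models, toy_genome)
        seq = toy_genome["c1"]
        assert int(part.counts()["n_adenines"].sum()) == seq.count("A") + seq.count("T")

    def test_no_genes_all_intergenic_strand_adenines(self):
        g = m.GenomeSequence({"c1": "AATT"})
        part = m.build_partition([], g)
        row = part.counts().set_index("category").loc["intergenic"]
        assert row["n_adenines_plus"] == 2  # the two As
        assert row["n_adenines_minus"] == 2  # the two Ts
        assert row["n_bases"] == 4

    def test_cds_wins_over_other_genes_intron(self, toy_genome):
        cds_gene = m.GeneModel(
            gene_id="a", chrom="c1", start=10, end=60, strand="+",
            biotype="protein_coding", exons=[(10, 60)], cds=[(10, 60)],
        )
        intron_gene = m.GeneModel(
            gene_id="b", chrom="c1", start=0, end=100, strand="+",
            biotype="protein_coding", exons=[(0, 10), (90, 100)],
            cds=[(0, 10), (90, 100)], introns=[(10, 90)],
        )
        part = m.build_partition([cds_gene, intron_gene], toy_genome)
        assert part.category_at("c1", 30) == "CDS"
        assert part.category_at("c1", 75) == "intron"

    def test_synthetic_partition_exhaustive(self, default_bundle):
        counts = default_bundle.partition.counts()
        total = sum(default_bundle.genome.lengths.values())
        assert int(counts["n_bases"].sum()) == total


class TestAnnotateSites:
    def test_cds_site_gets_gene_id(self, toy_gff_path, toy_genome):
        models = m.read_annotation(toy_gff_path, toy_genome)
        part = m.build_partition(models, toy_genome)
        pos = next(
            p for p in range(21, 41) if toy_genome.base("c1", p) in "AT"
        )
        strand = "+" if toy_genome.base("c1", pos) == "A" else "-"
        table = m.SiteTable(
            [m.ModificationRecord(chrom="c1", position=pos, strand=strand, coverage=30)]
        )
        ann = m.annotate_sites(table, part, models)
        assert ann.loc[0, "category"] == "CDS"
        assert ann.loc[0, "gene_id"] == "g1"

    def test_upstream_of_minus_gene_is_negative_distance(self):
        g = m.GenomeSequence({"c1": "C" * 400 + "A" + "C" * 99})  # A at 1-based 401
        gene = m.GeneModel(
            gene_id="g", chrom="c1", start=100, end=251, strand="-",
            biotype="protein_coding", exons=[(100, 251)], cds=[(100, 251)],
        )
        part = m.build_partition([gene], g)
        table = m.SiteTable(
            [m.ModificationRecord(chrom="c1", position=401, strand="+", coverage=30)]
        )
        ann = m.annotate_sites(table, part, [gene])
        # TSS at 0-based 250; site at 400 is 150 bp 5' of the - strand gene
        assert ann.loc[0, "tss_distance"] == -150
        assert ann.loc[0, "category"] == "intergenic"
        assert ann.loc[0, "gene_id"] is None

    def test_category_counts_match_per_site_lookup(self, default_bundle, default_table):
        """Vectorised category counting agrees with a per-site brute-force
        lookup against the partition arrays."""
        part = default_bundle.partition
        ann = m.annotate_sites(default_table, part, default_bundle.models)
        assert len(ann) == len(default_table)
        brute = {}
        for r in default_table:
            c = CATEGORIES[part.codes[r.chrom][r.position - 1]]
            brute[c] = brute.get(c, 0) + 1
        got = ann["category"].value_counts().to_dict()
        assert got == brute

    def test_unknown_chromosome_dropped_with_warning(self, default_bundle, default_table):
        part = default_bundle.partition
        extra = m.ModificationRecord(chrom="chrX", position=5, strand="+", coverage=99)
        table = m.SiteTable(list(default_table) + [extra])
        ann = m.annotate_sites(table, part, default_bundle.models)
        assert len(ann) == len(default_table)
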