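from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import m6atlas as m
from m6atlas.landscape import format_percent

from oracles import binom_two_sided


class TestDensityFormatting:
    @pytest.mark.parametrize(
        "n_sites, n_adenines, expected",
        [
            (160_256, 115_469_501, "0.139%"),  # genome-wide
            (1_686, 97_754, "1.725%"),  # chloroplast
            (21_827, 16_284_514, "0.134%"),
            (31_267, 22_291_714, "0.140%"),
            (0, 1_000, "0.000%"),
        ],
    )
    def test_density_percent_half_up(self, n_sites, n_adenines, expected):
        assert format_percent(n_sites, n_adenines) == expected

    def test_zero_denominator_is_undefined_not_zero(self):
        assert format_percent(0, 0) == "NA"

    def test_density_from_counts_totals(self):
        df = pd.DataFrame(
            {
                "group": ["a", "b"],
                "n_adenines_minus": [40, 10],
                "n_adenines_plus": [50, 20],
                "n_sites_minus": [1, 2],
                "n_sites_plus": [3, 4],
            }
        )
        out = m.density_from_counts(df)
        total = out[out["group"] == "Total"].iloc[0]
        assert total["n_adenines"] == 120 and total["n_sites"] == 10
        assert out["density"].iloc[0] == pytest.approx(4 / 90)

    def test_chromosome_table_counts_conserve(self, default_bundle, default_table):
        df = m.density_table(default_table, default_bundle.genome)
        total = df[df["group"] == "Total"].iloc[0]
        assert total["n_sites"] == len(default_table)
        assert total["n_adenines"] == sum(
            default_bundle.genome.total_adenines(c).get(s)
            for c in default_bundle.genome.chroms
            for s in "+-"
        )

    def test_category_table_counts_conserve(self, default_bundle, default_table):
        df = m.density_table(
            default_table,
            default_bundle.genome,
            partition=default_bundle.partition,
            group_by="category",
        )
        assert df[df["group"] == "Total"]["n_sites"].iloc[0] == len(default_table)


def _uniform_partition(n_a: int, rate_category: str = "CDS"):
    """A genome of n_a adenines all in one category, for enrichment toys."""
    seq = "A" * n_a
    g = m.GenomeSequence({"c1": seq})
    gene = m.GeneModel(
        gene_id="g", chrom="c1", start=0, end=n_a, strand="+",
        biotype="protein_coding", exons=[(0, n_a)], cds=[(0, n_a)],
    )
    return g, m.build_partition([gene], g)


class TestEnrichment:
    def test_binomial_p_matches_bruteforce_oracle(self):
        """1,000 category adenines at genome rate 0.01 with 20 observed:
        expected 10, two-sided p from direct pmf summation."""
        g, part = _uniform_partition(2_000)
        # 2,000 adenines total; plant 20 sites in CDS (first 1,000) and 0 in
        # a second half we relabel intergenic by shrinking the gene
        gene = m.GeneModel(
            gene_id="g", chrom="c1", start=0, end=1_000, strand="+",
            biotype="protein_coding", exons=[(0, 1_000)], cds=[(0, 1_000)],
        )
        part = m.build_partition([gene], g)
        records = [
            m.ModificationRecord(chrom="c1", position=p, strand="+", coverage=30)
            for p in range(1, 21)
        ]
        table = m.SiteTable(records)
        res = m.enrichment_test(table, part).set_index("category")
        row = res.loc["CDS"]
        assert row["expected"] == pytest.approx(10.0)
        oracle = binom_two_sided(20, 1_000, 20 / 2_000)
        assert row["p_value"] == pytest.approx(oracle, abs=1e-12)
        # frozen from the oracle: minimum-likelihood two-sided summation
        assert oracle == pytest.approx(0.0037676, abs=1e-6)

    def test_observed_equal_expected_is_central(self):
        g = m.GenomeSequence({"c1": "A" * 2_000})
        gene = m.GeneModel(
            gene_id="g", chrom="c1", start=0, end=1_000, strand="+",
            biotype="protein_coding", exons=[(0, 1_000)], cds=[(0, 1_000)],
        )
        part = m.build_partition([gene], g)
        records = [
            m.ModificationRecord(chrom="c1", position=p, strand="+", coverage=30)
            for p in list(range(1, 11)) + list(range(1_001, 1_011))
        ]
        res = m.enrichment_test(m.SiteTable(records), part).set_index("category")
        assert res.loc["CDS", "p_value"] >= 0.5
        assert res.loc["CDS", "ratio"] == pytest.approx(1.0)

    def test_zero_rate_degenerate(self):
        g, part = _uniform_partition(100)
        res = m.enrichment_test(m.SiteTable([]), part).set_index("category")
        assert res.loc["CDS", "p_value"] == 1.0
        assert np.isnan(res.loc["CDS", "ratio"])

    def test_ratio_above_one_iff_observed_above_expected(self, default_bundle, default_table):
        res = m.enrichment_test(default_table, default_bundle.partition)
        nonzero = res[res["expected"] > 0]
        assert ((nonzero["ratio"] > 1) == (nonzero["observed"] > nonzero["expected"])).all()

    def test_unknown_category_rejected(self, default_bundle, default_table):
        with pytest.raises(ValueError):
            m.enrichment_test(
                default_table, default_bundle.partition, categories=("promoter",)
            )

    def test_wilcoxon_mode_runs(self, default_bundle, default_table):
        res = m.enrichment_test(default_table, default_bundle.partition, test="wilcoxon")
        assert (res["test_name"] == "wilcoxon").all()
        assert res["p_value"].between(0, 1).all()


def _site(pos, frac):
    return m.ModificationRecord(chrom="c1", position=pos, strand="+", coverage=30, frac=frac)


class TestLevelBins:
    def test_boundaries_left_closed(self):
        table = m.SiteTable([_site(1, 0.50), _site(2, 0.35), _site(3, 0.65), _site(4, 0.349)])
        bins = m.bin_levels(table)
        # 0.35 moderate (left edge), 0.65 high (left edge), 0.50 moderate
        assert (bins.low, bins.moderate, bins.high) == (1, 2, 1)

    def test_missing_frac_counted_separately(self):
        table = m.SiteTable(
            [_site(1, 0.1), _site(2, 0.4), _site(3, 0.9),
             m.ModificationRecord(chrom="c1", position=4, strand="+", coverage=30)]
        )
        bins = m.bin_levels(table)
        assert (bins.low, bins.moderate, bins.high, bins.missing) == (1, 1, 1, 1)
        assert bins.total == 4

    def test_conservation_on_synthetic(self, default_table):
        bins = m.bin_levels(default_table)
        assert bins.total == len(default_table)


class TestGeneMethylation:
    def _cohort(self, densities):
        """Genes on an all-A genome with the requested site counts per 100 A."""
        n = len(densities)
        length = 100
        g = m.GenomeSequence({"c1": "A" * (n * length)})
        models, records = [], []
        pos = 1
        for i, d in enumerate(densities):
            start = i * length
            models.append(
                m.GeneModel(
                    gene_id=f"g{i}", chrom="c1", start=start, end=start + length,
                    strand="+", biotype="protein_coding",
                    exons=[(start, start + length)], cds=[(start, start + length)],
                )
            )
            for k in range(d):
                records.append(
                    m.ModificationRecord(chrom="c1", position=start + k + 1, strand="+", coverage=30)
                )
        return m.SiteTable(records), models, g

    def test_twofold_mean_is_moderate(self):
        # methylated densities {2, 2, 8} per 100 adenines: mean 4, so the
        # 8-site gene sits exactly at 2x the mean (K = 1, still moderate)
        # and the 2-site genes at K = -1 (the other closed boundary)
        table, models, g = self._cohort([2, 2, 8, 0])
        df = m.gene_methylation(table, models, g).set_index("gene_id")
        assert df[df["n_sites"] > 0]["density"].mean() == pytest.approx(0.04)
        assert df.loc["g2", "K"] == pytest.approx(1.0)
        assert df.loc["g2", "klass"] == "moderate"
        assert df.loc["g0", "K"] == pytest.approx(-1.0)
        assert df.loc["g0", "klass"] == "moderate"
        assert df.loc["g3", "klass"] == "non"

    def test_fourfold_mean_is_high(self):
        # methylated densities {1, 1, 1, 1, 16}: mean 4, the 16-site gene is
        # 4x the mean (K = 2, high) and the 1-site genes K = -2 (low)
        table, models, g = self._cohort([1, 1, 1, 1, 16, 0])
        df = m.gene_methylation(table, models, g).set_index("gene_id")
        assert df.loc["g4", "K"] == pytest.approx(2.0)
        assert df.loc["g4", "klass"] == "high"
        assert df.loc["g0", "klass"] == "low"

    def test_class_sizes_match_bruteforce(self, default_bundle, default_table):
        df = m.gene_methylation(default_table, default_bundle.models, default_bundle.genome)
        meth = df[df["n_sites"] > 0]
        mean = meth["density"].mean()
        expect = {"non": int((df["n_sites"] == 0).sum()), "high": 0, "low": 0, "moderate": 0}
        for d in meth["density"]:
            K = np.log2(d / mean)
            expect["high" if K > 1 else ("low" if K < -1 else "moderate")] += 1
        got = df["klass"].value_counts().to_dict()
        assert {k: got.get(k, 0) for k in expect} == expect

    def test_strand_restriction_reduces_counts(self, default_bundle, default_table):
        both = m.gene_methylation(default_table, default_bundle.models, default_bundle.genome)
        one = m.gene_methylation(
            default_table, default_bundle.models, default_bundle.genome, strand_restricted=True
        )
        assert (one["n_sites"] <= both["n_sites"]).all()
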