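from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import m6atlas as m
from m6atlas.association import QpcrResult

from oracles import bh_adjust, fisher_greater


class TestJoinAndFilter:
    def test_positivity_filter(self):
        meth = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "density": [0.002, 0.0, 0.001]}
        )
        expr = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "fpkm": [5.0, 3.0, 0.0]})
        out = m.join_and_filter(meth, expr)
        assert list(out["gene_id"]) == ["g1"]

    def test_disjoint_ids_rejected(self):
        meth = pd.DataFrame({"gene_id": ["g1"], "density": [0.1]})
        expr = pd.DataFrame({"gene_id": ["g2"], "fpkm": [1.0]})
        with pytest.raises(ValueError):
            m.join_and_filter(meth, expr)

    def test_matches_bruteforce_predicate(self):
        rng = np.random.default_rng(9)
        n = 1_000
        ids = [f"g{i}" for i in range(n)]
        dens = rng.random(n) * (rng.random(n) > 0.3)
        fpkm = rng.random(n) * (rng.random(n) > 0.3)
        meth = pd.DataFrame({"gene_id": ids, "density": dens})
        expr = pd.DataFrame({"gene_id": ids, "fpkm": fpkm})
        out = m.join_and_filter(meth, expr)
        brute = {i for i, (d, f) in enumerate(zip(dens, fpkm)) if d > 0 and f > 0}
        assert set(out["gene_id"]) == {f"g{i}" for i in brute}


class TestMeanSplit:
    def test_strict_inequalities(self):
        df = pd.DataFrame(
            {"gene_id": list("abcd"), "fpkm": [1.0, 2.0, 3.0, 10.0],
             "density": [0.1, 0.2, 0.3, 0.4]}
        )
        comp = m.mean_split_comparison(df, split_on="fpkm")
        assert (comp.n_high, comp.n_low, comp.n_ties) == (1, 3, 0)
        assert np.isnan(comp.p_value)  # a 1-gene group supports no t test

    def test_tie_at_mean_excluded(self):
        df = pd.DataFrame(
            {"gene_id": list("abcde"), "fpkm": [1.0, 2.0, 4.0, 4.0, 9.0],
             "density": [0.1, 0.2, 0.3, 0.4, 0.5]}
        )
        comp = m.mean_split_comparison(df, split_on="fpkm")  # mean = 4.0
        assert comp.n_ties == 2
        assert comp.n_high + comp.n_low + comp.n_ties == 5

    def test_all_equal_is_degenerate(self):
        df = pd.DataFrame({"gene_id": list("abc"), "fpkm": [2.0] * 3, "density": [0.1] * 3})
        with pytest.raises(ValueError):
            m.mean_split_comparison(df, split_on="fpkm")

    def test_planted_effect_recovered(self):
        df = m.simulate.simulate_expression_table(2_000, beta=0.5, seed=3)
        comp = m.mean_split_comparison(df, split_on="density")
        assert comp.direction == 1
        assert comp.p_value < 0.01


class TestDdct:
    @pytest.mark.parametrize(
        "target, reference, expected",
        [
            ([25.0], [20.0], 0.03125),
            ([22.0], [22.0], 1.0),
            ([25.1, 25.0, 24.9], [20.0, 20.0, 20.0], 0.03125),
        ],
    )
    def test_closed_form(self, target, reference, expected):
        assert m.ddct(target, reference) == pytest.approx(expected)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            m.ddct([], [20.0])

    @settings(max_examples=50, derandomize=True)
    @given(
        ct=st.floats(10, 35),
        delta=st.floats(0.1, 5),
        ref=st.floats(10, 35),
    )
    def test_monotone_decreasing_in_target_ct(self, ct, delta, ref):
        assert m.ddct([ct + delta], [ref]) < m.ddct([ct], [ref])
        assert m.ddct([ct], [ref + delta]) > m.ddct([ct], [ref])


class TestQpcrGroupTest:
    def test_welch_t_matches_hand_formula(self):
        hi = [0.5, 0.6, 0.7]
        lo = [0.05, 0.06, 0.07]
        results = [QpcrResult(f"h{i}", "high-density", v) for i, v in enumerate(hi)] + [
            QpcrResult(f"l{i}", "low-density", v) for i, v in enumerate(lo)
        ]
        comp = m.qpcr_group_test(results, log2_scale=False)
        # Welch t from first principles
        m1, m2 = np.mean(hi), np.mean(lo)
        v1, v2 = np.var(hi, ddof=1), np.var(lo, ddof=1)
        t = (m1 - m2) / math.sqrt(v1 / 3 + v2 / 3)
        assert comp.t_statistic == pytest.approx(t)
        assert comp.mean_high > comp.mean_low

    def test_identical_groups_null(self):
        vals = [0.5, 0.6, 0.7]
        results = [QpcrResult(f"h{i}", "high-density", v) for i, v in enumerate(vals)] + [
            QpcrResult(f"l{i}", "low-density", v) for i, v in enumerate(vals)
        ]
        comp = m.qpcr_group_test(results)
        assert comp.p_value == pytest.approx(1.0)
        assert comp.mean_high == pytest.approx(comp.mean_low)

    def test_single_member_group_rejected(self):
        results = [
            QpcrResult("h0", "high-density", 0.5),
            QpcrResult("l0", "low-density", 0.05),
            QpcrResult("l1", "low-density", 0.06),
        ]
        with pytest.raises(ValueError):
            m.qpcr_group_test(results)

    def test_from_ct_builds_relative_expression(self):
        r = QpcrResult.from_ct("g", "high-density", [25.0], [20.0])
        assert r.relative_expression == pytest.approx(0.03125)


class TestGoEnrichment:
    def _setup(self):
        universe = [f"g{i}" for i in range(100)]
        term_genes = set(universe[:20])
        go_map = pd.DataFrame(
            [{"gene_id": g, "term": "T"} for g in term_genes]
            + [{"gene_id": g, "term": "ALL"} for g in universe]
        )
        klass = {f"g{i}": ("high" if i < 10 else "rest") for i in range(100)}
        classes = pd.DataFrame({"gene_id": universe, "klass": [klass[g] for g in universe]})
        return classes, go_map

    def test_fisher_p_matches_hypergeometric_oracle(self):
        classes, go_map = self._setup()
        # class "high": genes g0..g9, 8 of which... here all 10 carry T;
        # use a sharper hand case below instead
        out = m.go_enrichment(classes, go_map).set_index(["klass", "term"])
        k, n, K, N = 10, 10, 20, 100
        oracle = fisher_greater(k, n - k, K - k, N - n - (K - k))
        assert out.loc[("high", "T"), "p_value"] == pytest.approx(oracle, abs=1e-12)

    def test_spec_style_case(self):
        # class of 10 genes with 8 annotated; universe 100, term covers 20
        oracle = fisher_greater(8, 2, 12, 78)
        assert oracle == pytest.approx(3.0e-5, abs=2e-5)

    def test_ubiquitous_term_never_significant(self):
        classes, go_map = self._setup()
        out = m.go_enrichment(classes, go_map).set_index(["klass", "term"])
        assert out.loc[("high", "ALL"), "p_value"] == pytest.approx(1.0)
        assert not out.loc[("high", "ALL"), "significant"]

    def test_bh_adjustment_matches_hand_formula(self):
        ps = [0.001, 0.01, 0.02, 0.9]
        assert bh_adjust(ps) == pytest.approx([0.004, 0.02, 1.2 / 45, 0.9])
        # and the pipeline's q-values agree with the same hand formula
        classes, go_map = self._setup()
        out = m.go_enrichment(classes, go_map)
        for _, grp in out.groupby("klass"):
            assert grp["q_value"].to_numpy() == pytest.approx(
                bh_adjust(list(grp["p_value"]))
            )

    def test_q_at_least_p_and_order_preserved(self, default_bundle, default_table):
        gm = m.gene_methylation(default_table, default_bundle.models, default_bundle.genome)
        out = m.go_enrichment(gm, default_bundle.go_map)
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()
        for _, grp in out.groupby("klass"):
            s = grp.sort_values("p_value")
            assert s["q_value"].is_monotonic_increasing
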