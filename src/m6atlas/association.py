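"""Methylation-expression association, qPCR relative expression, and GO
term over-representation.

The computational arm joins per-gene 6mA density with FPKM, keeps genes
positive in both, splits at the arithmetic mean of one variable (ties at
the mean excluded) and compares the other variable between the two groups
by a two-sample t test (Welch by default — group sizes are typically very
unbalanced).  The experimental arm computes 2^(-dCt) relative expression
from replicate Ct values against a reference gene and contrasts
high-density vs low-density gene groups.  GO enrichment is a one-sided
Fisher exact test per (gene class, term) with Benjamini-Hochberg adjustment
within class, significant at q < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def join_and_filter(gene_meth: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    """Inner-join per-gene methylation with expression and keep genes with
    both FPKM > 0 and 6mA density > 0."""
    joined = gene_meth.merge(expression, on="gene_id", how="inner")
    if joined.empty:
        raise ValueError("no genes shared between methylation and expression tables")
    kept = joined[(joined["fpkm"] > 0) & (joined["density"] > 0)].reset_index(drop=True)
    logger.info(
        "join: %d shared genes, %d retained after positivity filter",
        len(joined),
        len(kept),
    )
    if kept.empty:
        raise ValueError("positivity filter removed every gene")
    return kept


@dataclass
class GroupComparison:
    split_on: str
    measure: str
    n_high: int
    n_low: int
    n_ties: int
    mean_high: float
    mean_low: float
    sem_high: float
    sem_low: float
    t_statistic: float
    p_value: float
    test: str

    @property
    def direction(self) -> int:
        """Sign of (high-group mean - low-group mean) of the measure."""
        return int(np.sign(self.mean_high - self.mean_low))


def _sem(x: np.ndarray) -> float:
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def mean_split_comparison(
    joined: pd.DataFrame,
    split_on: str = "fpkm",
    *,
    welch: bool = True,
) -> GroupComparison:
    """Split genes at the arithmetic mean of *split_on* and t-test the
    other variable (density <-> fpkm) between the two groups.

    High = value strictly above the mean, low = strictly below; exact ties
    are excluded.  Both groups need at least two genes.
    """
    measure = "density" if split_on == "fpkm" else "fpkm"
    vals = joined[split_on].to_numpy(dtype=float)
    mean = vals.mean()
    high = joined.loc[vals > mean, measure].to_numpy(dtype=float)
    low = joined.loc[vals < mean, measure].to_numpy(dtype=float)
    n_ties = int((vals == mean).sum())
    if len(high) == 0 or len(low) == 0:
        raise ValueError(
            f"mean split on {split_on!r} left an empty group "
            f"(sizes {len(high)}/{len(low)}, {n_ties} ties excluded)"
        )
    if len(high) >= 2 and len(low) >= 2:
        t, p = stats.ttest_ind(high, low, equal_var=not welch)
    else:
        logger.warning("a split group has < 2 genes: t test undefined")
        t, p = np.nan, np.nan
    return GroupComparison(
        split_on=split_on,
        measure=measure,
        n_high=len(high),
        n_low=len(low),
        n_ties=n_ties,
        mean_high=float(high.mean()),
        mean_low=float(low.mean()),
        sem_high=_sem(high),
        sem_low=_sem(low),
        t_statistic=float(t),
        p_value=float(p),
        test="welch_t" if welch else "student_t",
    )


def ddct(ct_target: Sequence[float], ct_reference: Sequence[float]) -> float:
    """Relative expression 2^(-dCt), dCt = mean(Ct_target) - mean(Ct_ref)."""
    if len(ct_target) == 0 or len(ct_reference) == 0:
        raise ValueError("need at least one Ct replicate per gene")
    dct = float(np.mean(ct_target)) - float(np.mean(ct_reference))
    if not np.isfinite(dct):
        raise ValueError("non-finite Ct values")
    return 2.0 ** (-dct)


@dataclass
class QpcrResult:
    """One gene's qPCR readout relative to the reference gene."""

    gene_id: str
    group: str  # "high-density" | "low-density"
    relative_expression: float

    @classmethod
    def from_ct(
        cls,
        gene_id: str,
        group: str,
        ct_target: Sequence[float],
        ct_reference: Sequence[float],
    ) -> "QpcrResult":
        return cls(gene_id, group, ddct(ct_target, ct_reference))


def qpcr_group_test(
    results: Sequence[QpcrResult],
    *,
    log2_scale: bool = True,
    welch: bool = True,
) -> GroupComparison:
    """Two-sample t test of relative expression between the high-density
    and low-density gene groups (on log2 scale by default)."""
    groups: dict[str, list[float]] = {}
    for r in results:
        groups.setdefault(r.group, []).append(r.relative_expression)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(groups)}")
    hi_label = "high-density" if "high-density" in groups else sorted(groups)[0]
    lo_label = next(g for g in groups if g != hi_label)
    hi = np.array(groups[hi_label], dtype=float)
    lo = np.array(groups[lo_label], dtype=float)
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("each group needs at least two genes")
    xh, xl = (np.log2(hi), np.log2(lo)) if log2_scale else (hi, lo)
    t, p = stats.ttest_ind(xh, xl, equal_var=not welch)
    return GroupComparison(
        split_on="density-group",
        measure="log2_relative_expression" if log2_scale else "relative_expression",
        n_high=len(hi),
        n_low=len(lo),
        n_ties=0,
        mean_high=float(xh.mean()),
        mean_low=float(xl.mean()),
        sem_high=_sem(xh),
        sem_low=_sem(xl),
        t_statistic=float(t),
        p_value=float(p),
        test="welch_t" if welch else "student_t",
    )


def go_enrichment(
    gene_classes: Mapping[str, set[str]] | pd.DataFrame,
    go_map: pd.DataFrame,
    *,
    universe: set[str] | None = None,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-class GO term over-representation.

    *gene_classes* maps class label -> gene set (or a DataFrame with
    ``gene_id``/``klass`` columns); *go_map* has ``gene_id``/``term``
    columns.  The default universe is every gene with at least one GO
    annotation.  One-sided Fisher exact test per (class, term), BH-adjusted
    within class; ``significant`` marks q < *q_threshold*.
    """
    if isinstance(gene_classes, pd.DataFrame):
        gene_classes = {
            k: set(g["gene_id"]) for k, g in gene_classes.groupby("klass")
        }
    annotated: dict[str, set[str]] = {}
    for gid, term in zip(go_map["gene_id"], go_map["term"]):
        annotated.setdefault(term, set()).add(gid)
    if universe is None:
        universe = set(go_map["gene_id"])
    if not universe:
        raise ValueError("empty GO universe")
    N = len(universe)
    rows = []
    for klass, genes in gene_classes.items():
        members = genes & universe
        n = len(members)
        if n == 0:
            logger.warning("class %r has no genes in the universe: skipped", klass)
            continue
        klass_rows = []
        for term, term_genes in sorted(annotated.items()):
            tg = term_genes & universe
            K = len(tg)
            k = len(tg & members)
            p = stats.fisher_exact(
                [[k, n - k], [K - k, N - n - (K - k)]], alternative="greater"
            ).pvalue
            klass_rows.append(
                {"klass": klass, "term": term, "k": k, "n": n, "K": K, "N": N, "p_value": p}
            )
        if klass_rows:
            ps = [r["p_value"] for r in klass_rows]
            _, qs, _, _ = multipletests(ps, method="fdr_bh")
            for r, q in zip(klass_rows, qs):
                r["q_value"] = float(q)
                r["significant"] = bool(q < q_threshold)
            rows.extend(klass_rows)
    return pd.DataFrame(
        rows,
        columns=["klass", "term", "k", "n", "K", "N", "p_value", "q_value", "significant"],
    )


def go_overlap_summary(enrichment: pd.DataFrame) -> pd.DataFrame:
    """How many significant terms each combination of classes shares
    (Venn-style counts)."""
    sig = enrichment[enrichment["significant"]]
    by_class = {k: set(g["term"]) for k, g in sig.groupby("klass")}
    term_classes: dict[str, frozenset[str]] = {}
    for term in set(sig["term"]):
        term_classes[term] = frozenset(k for k, ts in by_class.items() if term in ts)
    combos = pd.Series([term_classes[t] for t in term_classes]).value_counts()
    return pd.DataFrame(
        {
            "classes": ["+".join(sorted(c)) for c in combos.index],
            "n_terms": combos.to_numpy(),
        }
    )
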