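"""Density tables, methylation-level bins, enrichment tests, gene classes.

6mA density is the ratio of called 6mA sites to adenines in the same
grouping (chromosome, strand, feature category or gene), reported as a
percentage.  Observed-versus-expected enrichment compares each category's
site count with ``n_adenines(category) x genome-wide rate`` by an exact
two-sided binomial test (minimum-likelihood two-sided), or optionally by a
Wilcoxon signed-rank test across per-chromosome observed-expected
differences.

Gene-level methylation is summarized by K = log2(density / mean density of
methylated genes): K > 1 high, K < -1 low, |K| <= 1 moderate, and genes
without any site form their own "non" class and never enter the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .features import CATEGORIES, FeaturePartition, GeneModel
from .io import GenomeSequence, SiteTable

logger = logging.getLogger(__name__)


def format_percent(n_sites: int, n_adenines: int, decimals: int = 3) -> str:
    """Density as a percent string, rounded half-up (e.g. ``'0.139%'``).

    Returns ``'NA'`` when the denominator is zero (undefined, not 0).
    """
    if n_adenines == 0:
        return "NA"
    pct = Decimal(100 * n_sites) / Decimal(n_adenines)
    q = Decimal(1).scaleb(-decimals)
    return f"{pct.quantize(q, rounding=ROUND_HALF_UP)}%"


def density_from_counts(df: pd.DataFrame, *, total_label: str = "Total") -> pd.DataFrame:
    """Append densities and a totals row to a table of per-group counts.

    Expects columns ``group``, ``n_adenines`` and ``n_sites`` (per-strand
    columns ``n_adenines_plus/minus``, ``n_sites_plus/minus`` are summed to
    the totals when the total columns are absent).
    """
    df = df.copy()
    for col in ("n_adenines", "n_sites"):
        if col not in df.columns:
            df[col] = df[f"{col}_plus"] + df[f"{col}_minus"]
    total = {"group": total_label}
    for col in df.columns:
        if col.startswith(("n_adenines", "n_sites")):
            total[col] = int(df[col].sum())
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["density"] = np.where(
            df["n_adenines"] > 0, df["n_sites"] / df["n_adenines"], np.nan
        )
    df["density_pct"] = [
        format_percent(int(s), int(a)) for s, a in zip(df["n_sites"], df["n_adenines"])
    ]
    return df


def density_table(
    table: SiteTable,
    genome: GenomeSequence,
    *,
    partition: FeaturePartition | None = None,
    group_by: str = "chromosome",
) -> pd.DataFrame:
    """Per-group site counts, adenine counts and densities.

    ``group_by`` is one of ``chromosome``, ``strand`` or ``category`` (the
    latter requires *partition*).  A ``Total`` row is appended.
    """
    sites = table.to_frame()
    if group_by == "chromosome":
        rows = []
        for chrom in genome.chroms:
            sub = sites[sites["chrom"] == chrom]
            a = genome.total_adenines(chrom)
            rows.append(
                {
                    "group": chrom,
                    "n_adenines_minus": a["-"],
                    "n_adenines_plus": a["+"],
                    "n_sites_minus": int((sub["strand"] == "-").sum()),
                    "n_sites_plus": int((sub["strand"] == "+").sum()),
                }
            )
        return density_from_counts(pd.DataFrame(rows))
    if group_by == "strand":
        a = genome.total_adenines()
        rows = [
            {
                "group": s,
                "n_adenines": a[s],
                "n_sites": int((sites["strand"] == s).sum()),
            }
            for s in ("+", "-")
        ]
        return density_from_counts(pd.DataFrame(rows))
    if group_by == "category":
        if partition is None:
            raise ValueError("category grouping requires a FeaturePartition")
        counts = partition.counts().set_index("category")
        cat = [
            partition.category_at(r.chrom, r.position) for r in table
        ]
        obs = pd.Series(cat).value_counts()
        rows = [
            {
                "group": c,
                "n_adenines_minus": int(counts.loc[c, "n_adenines_minus"]),
                "n_adenines_plus": int(counts.loc[c, "n_adenines_plus"]),
                "n_sites": int(obs.get(c, 0)),
            }
            for c in CATEGORIES
        ]
        return density_from_counts(pd.DataFrame(rows))
    raise ValueError(f"unknown group_by {group_by!r}")


@dataclass
class EnrichmentResult:
    category: str
    observed: int
    expected: float
    ratio: float  # NaN when expected == 0
    p_value: float
    test_name: str


def enrichment_test(
    table: SiteTable,
    partition: FeaturePartition,
    *,
    test: str = "binomial",
    categories: tuple[str, ...] = CATEGORIES,
) -> pd.DataFrame:
    """Observed vs expected site counts per feature category.

    Expected = category adenines x genome-wide rate (total sites / total
    adenines).  ``test='binomial'``: exact two-sided binomial p-value of the
    observed count.  ``test='wilcoxon'``: signed-rank test on per-chromosome
    observed-expected differences (needs several chromosomes to have power).
    """
    adenines = partition.adenines_by_category()
    for c in categories:
        if c not in adenines:
            raise ValueError(f"category {c!r} absent from partition")
    total_a = sum(adenines.values())
    rate = len(table) / total_a if total_a else 0.0
    obs_by_cat: dict[str, int] = {c: 0 for c in CATEGORIES}
    obs_by_chrom_cat: dict[tuple[str, str], int] = {}
    for r in table:
        c = partition.category_at(r.chrom, r.position)
        obs_by_cat[c] += 1
        obs_by_chrom_cat[(r.chrom, c)] = obs_by_chrom_cat.get((r.chrom, c), 0) + 1

    a_chrom_cat: dict[str, np.ndarray] = {}
    if test == "wilcoxon":
        for chrom, codes in partition.codes.items():
            seq = np.frombuffer(partition.genome[chrom].encode(), dtype="S1")
            at = (seq == b"A") | (seq == b"T")
            a_chrom_cat[chrom] = np.bincount(codes[at], minlength=len(CATEGORIES))

    rows = []
    for c in categories:
        n_a = adenines[c]
        observed = obs_by_cat[c]
        expected = n_a * rate
        ratio = observed / expected if expected > 0 else float("nan")
        if test == "binomial":
            if n_a == 0 or rate == 0:
                p = 1.0
            else:
                p = stats.binomtest(observed, n_a, rate).pvalue
        elif test == "wilcoxon":
            code = CATEGORIES.index(c)
            diffs = [
                obs_by_chrom_cat.get((chrom, c), 0) - int(a_chrom_cat[chrom][code]) * rate
                for chrom in partition.codes
            ]
            diffs = [d for d in diffs if d != 0]
            p = stats.wilcoxon(diffs).pvalue if len(diffs) >= 1 else 1.0
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "category": c,
                "n_adenines": n_a,
                "observed": observed,
                "expected": expected,
                "ratio": ratio,
                "p_value": p,
                "test_name": test,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LevelBins:
    """Counts of sites by methylated fraction: low [0,35), moderate
    [35,65), high [65,100] (percent scale); sites lacking a fraction are
    counted separately."""

    low: int
    moderate: int
    high: int
    missing: int

    @property
    def total(self) -> int:
        return self.low + self.moderate + self.high + self.missing


def bin_levels(table: SiteTable) -> LevelBins:
    low = moderate = high = missing = 0
    for r in table:
        if r.frac is None:
            missing += 1
        elif r.frac * 100 < 35:
            low += 1
        elif r.frac * 100 < 65:
            moderate += 1
        else:
            high += 1
    return LevelBins(low, moderate, high, missing)


def level_track(table: SiteTable, genome: GenomeSequence, window: int = 10_000) -> pd.DataFrame:
    """Per-window counts of low/moderate/high-level sites, as a plain track
    table (chrom, start, end, low, moderate, high) for external plotting."""
    rows = {}
    for r in table:
        if r.frac is None:
            continue
        w = (r.position - 1) // window
        key = (r.chrom, w)
        if key not in rows:
            rows[key] = [0, 0, 0]
        lvl = 0 if r.frac * 100 < 35 else (1 if r.frac * 100 < 65 else 2)
        rows[key][lvl] += 1
    out = [
        {
            "chrom": c,
            "start": w * window,
            "end": min((w + 1) * window, genome.lengths[c]),
            "low": v[0],
            "moderate": v[1],
            "high": v[2],
        }
        for (c, w), v in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["chrom", "start", "end", "low", "moderate", "high"])


def gene_methylation(
    table: SiteTable,
    models: list[GeneModel],
    genome: GenomeSequence,
    *,
    strand_restricted: bool = False,
) -> pd.DataFrame:
    """Per-gene 6mA site count, adenine count, density, K and class.

    The denominator counts adenines on both strands of the gene span; sites
    on either strand count (``strand_restricted=True`` keeps only sites on
    the gene's own strand).  K = log2(density / mean density over genes with
    at least one site); class: high (K>1), low (K<-1), moderate (|K|<=1),
    non (no sites).
    """
    pos_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for r in table:
        pos_by_chrom.setdefault(r.chrom, []).append((r.position - 1, r.strand))
    sorted_pos = {
        c: (np.array([p for p, _ in sorted(v)]), [s for _, s in sorted(v)])
        for c, v in pos_by_chrom.items()
    }
    rows = []
    for m in models:
        seq = genome[m.chrom][m.start : m.end]
        n_a = seq.count("A") + seq.count("T")
        n_sites = 0
        if m.chrom in sorted_pos:
            arr, strands = sorted_pos[m.chrom]
            lo, hi = np.searchsorted(arr, [m.start, m.end])
            if strand_restricted:
                n_sites = sum(1 for i in range(lo, hi) if strands[i] == m.strand)
            else:
                n_sites = int(hi - lo)
        density = n_sites / n_a if n_a else np.nan
        rows.append(
            {
                "gene_id": m.gene_id,
                "biotype": m.biotype,
                "n_sites": n_sites,
                "n_adenines": n_a,
                "density": density,
            }
        )
    df = pd.DataFrame(rows)
    methylated = df["n_sites"] > 0
    mean_density = df.loc[methylated, "density"].mean() if methylated.any() else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        df["K"] = np.where(methylated, np.log2(df["density"] / mean_density), np.nan)
    df["klass"] = "non"
    df.loc[methylated & (df["K"] > 1), "klass"] = "high"
    df.loc[methylated & (df["K"] < -1), "klass"] = "low"
    df.loc[methylated & (df["K"].abs() <= 1), "klass"] = "moderate"
    df.attrs["mean_density_methylated"] = mean_density
    return df
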