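"""TSS-anchored occupancy profiles and within-gene site-position profiles.

Occupancy: for each 50-bp window tiling [-1000, +1000) around the TSS in
transcription orientation, the fraction of genes of a class (protein-coding
or lncRNA) carrying at least one 6mA site in that window.  The denominator
is the total class size, not the methylated subset, so adding an
unmethylated gene can only lower occupancies.

Relative position: 6mA sites falling inside gene bodies, binned by
normalized position along the gene (0 = 5' end), frequencies summing to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import GeneModel
from .io import SiteTable


def _sites_by_chrom(table: SiteTable) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sorted 0-based positions and aligned strand array per chromosome."""
    tmp: dict[str, list[tuple[int, str]]] = {}
    for r in table:
        tmp.setdefault(r.chrom, []).append((r.position - 1, r.strand))
    out = {}
    for c, v in tmp.items():
        v.sort()
        out[c] = (
            np.array([p for p, _ in v], dtype=np.int64),
            np.array([s for _, s in v]),
        )
    return out


def tss_occupancy(
    table: SiteTable,
    models: list[GeneModel],
    biotype: str,
    *,
    span: int = 1000,
    window: int = 50,
    same_strand_only: bool = False,
) -> pd.DataFrame:
    """Per-window methylated-gene fraction around the TSS for one class.

    Windows are half-open [x, x+window) in transcription-oriented
    coordinates relative to the TSS (the TSS sits at the left edge of the
    first downstream window).  Minus-strand genes are mirrored about their
    TSS.  Genes whose window runs off a chromosome end still count in the
    denominator.  Sites on either strand count unless *same_strand_only*.
    """
    genes = [m for m in models if m.biotype == biotype]
    if not genes:
        raise ValueError(f"no genes of biotype {biotype!r}")
    n_windows = 2 * span // window
    hits = np.zeros(n_windows, dtype=np.int64)
    by_chrom = _sites_by_chrom(table)
    for g in genes:
        if g.chrom not in by_chrom:
            continue
        pos, strands = by_chrom[g.chrom]
        lo, hi = np.searchsorted(pos, [g.tss - span, g.tss + span + 1])
        seen = set()
        for i in range(lo, hi):
            if same_strand_only and strands[i] != g.strand:
                continue
            rel = pos[i] - g.tss if g.strand == "+" else g.tss - pos[i]
            if -span <= rel < span:
                seen.add((rel + span) // window)
        for w in seen:
            hits[w] += 1
    starts = np.arange(-span, span, window)
    return pd.DataFrame(
        {
            "class": biotype,
            "window_start": starts,
            "window_end": starts + window,
            "n_methylated_genes": hits,
            "n_genes": len(genes),
            "occupancy": hits / len(genes),
        }
    )


@dataclass
class OccupancyContrast:
    """Two-sample t test on per-window occupancies of the central windows
    (default the 200 bp on either side of the TSS) between two classes."""

    window_starts: np.ndarray
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float


def central_occupancy_contrast(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    *,
    central: tuple[int, int] = (-200, 200),
) -> OccupancyContrast:
    lo, hi = central
    sel_a = profile_a[(profile_a.window_start >= lo) & (profile_a.window_end <= hi)]
    sel_b = profile_b[(profile_b.window_start >= lo) & (profile_b.window_end <= hi)]
    t, p = stats.ttest_ind(sel_a.occupancy, sel_b.occupancy, equal_var=False)
    return OccupancyContrast(
        window_starts=sel_a.window_start.to_numpy(),
        mean_a=float(sel_a.occupancy.mean()),
        mean_b=float(sel_b.occupancy.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )


def site_counts_per_gene(
    table: SiteTable, models: list[GeneModel], biotype: str | None = None
) -> tuple[pd.Series, float]:
    """Histogram of genes by 6mA site count (bins 0..9 and "10+") and the
    fraction of genes carrying at least one site."""
    genes = [m for m in models if biotype is None or m.biotype == biotype]
    if not genes:
        raise ValueError(f"no genes of biotype {biotype!r}")
    by_chrom = {c: p for c, (p, _) in _sites_by_chrom(table).items()}
    counts = []
    for g in genes:
        if g.chrom in by_chrom:
            lo, hi = np.searchsorted(by_chrom[g.chrom], [g.start, g.end])
            counts.append(int(hi - lo))
        else:
            counts.append(0)
    labels = [str(i) for i in range(10)] + ["10+"]
    hist = pd.Series(0, index=labels, dtype=np.int64)
    for c in counts:
        hist[str(c) if c < 10 else "10+"] += 1
    frac = sum(1 for c in counts if c > 0) / len(genes)
    return hist, frac


def relative_position_profile(
    table: SiteTable, models: list[GeneModel], biotype: str, bins: int = 50
) -> pd.DataFrame:
    """Frequencies of gene-body 6mA sites along the normalized gene
    coordinate (bin 0 = 5' end); frequencies sum to 1."""
    genes = [m for m in models if m.biotype == biotype]
    if not genes:
        raise ValueError(f"no genes of biotype {biotype!r}")
    by_chrom = {c: p for c, (p, _) in _sites_by_chrom(table).items()}
    counts = np.zeros(bins, dtype=np.int64)
    for g in genes:
        if g.chrom not in by_chrom:
            continue
        pos = by_chrom[g.chrom]
        lo, hi = np.searchsorted(pos, [g.start, g.end])
        for p in pos[lo:hi]:
            offset = p - g.start if g.strand == "+" else g.end - 1 - p
            b = min(bins * offset // g.length, bins - 1)
            counts[b] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no gene-body sites for biotype {biotype!r}")
    return pd.DataFrame(
        {
            "class": biotype,
            "bin": np.arange(bins),
            "n_sites": counts,
            "frequency": counts / total,
        }
    )
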