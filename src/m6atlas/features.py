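"""Gene models, genome partition into feature classes, and site annotation.

The genome is labelled position-by-position into six mutually exclusive
categories — 5'UTR, CDS, 3'UTR, intron, ncRNA (tRNA/rRNA/lncRNA gene
bodies) and intergenic.  Where annotations overlap, coding function wins:
priority CDS > 5'UTR > 3'UTR > ncRNA > intron > intergenic.  Categories are
unstranded regions; a site's strand never changes its category.

All intervals here are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GenomeSequence, SiteTable

logger = logging.getLogger(__name__)

#: Partition categories, in paint order (lowest priority first). The code
#: of a category is its index here; higher code wins at overlaps.
CATEGORIES = ("intergenic", "intron", "ncRNA", "threeUTR", "fiveUTR", "CDS")
CATEGORY_CODE = {c: i for i, c in enumerate(CATEGORIES)}

CODING = "protein_coding"
NONCODING_BIOTYPES = {"lncRNA", "tRNA", "rRNA"}

_NC_FEATURE_TYPES = {
    "lnc_RNA": "lncRNA",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "ncRNA": "lncRNA",
}

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """Single representative model per gene.

    For multi-transcript genes exons are the union over transcripts and the
    CDS comes from the transcript with the longest total CDS.  ``tss`` is
    the 0-based coordinate of the first transcribed base (span start on +,
    span end - 1 on -).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    introns: list[Interval] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start

    def category_intervals(self) -> dict[str, list[Interval]]:
        if self.biotype == CODING:
            return {
                "fiveUTR": self.utr5,
                "CDS": self.cds,
                "threeUTR": self.utr3,
                "intron": self.introns,
            }
        return {"ncRNA": [(self.start, self.end)]}


def _merge(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(span: Interval, holes: list[Interval]) -> list[Interval]:
    """Pieces of *span* not covered by the merged *holes*."""
    s, e = span
    out = []
    cur = s
    for hs, he in _merge(holes):
        if hs > cur:
            out.append((cur, min(hs, e)))
        cur = max(cur, he)
        if cur >= e:
            break
    if cur < e:
        out.append((cur, e))
    return [iv for iv in out if iv[0] < iv[1]]


def _gene_biotype(db: gffutils.FeatureDB, gene) -> str:
    for key in ("gene_biotype", "biotype", "gene_type"):
        if key in gene.attributes:
            bt = gene.attributes[key][0]
            return bt if bt == CODING or bt in NONCODING_BIOTYPES else "lncRNA"
    child_types = {c.featuretype for c in db.children(gene, level=1)}
    if "mRNA" in child_types or "CDS" in child_types:
        return CODING
    for t, bt in _NC_FEATURE_TYPES.items():
        if t in child_types:
            return bt
    return ""  # unknown


def _build_coding_model(db, gene, gene_id: str) -> GeneModel:
    strand = gene.strand
    exons, all_cds = [], {}
    utr5_explicit, utr3_explicit = [], []
    transcripts = list(db.children(gene, level=1, featuretype="mRNA"))
    parents = transcripts if transcripts else [gene]
    for tr in parents:
        tr_cds = []
        for f in db.children(tr, featuretype=("exon", "CDS", "five_prime_UTR", "three_prime_UTR")):
            iv = (f.start - 1, f.end)
            if f.featuretype == "exon":
                exons.append(iv)
            elif f.featuretype == "CDS":
                tr_cds.append(iv)
            elif f.featuretype == "five_prime_UTR":
                utr5_explicit.append(iv)
            else:
                utr3_explicit.append(iv)
        if tr_cds:
            all_cds[tr.id] = _merge(tr_cds)
    exons = _merge(exons)
    span = (gene.start - 1, gene.end)
    if not exons:
        exons = [span]
    # representative CDS: the transcript with the largest total CDS length
    cds: list[Interval] = []
    if all_cds:
        cds = max(all_cds.values(), key=lambda ivs: sum(e - s for s, e in ivs))
    for s, e in cds:
        if not any(xs <= s and e <= xe for xs, xe in exons):
            raise ValueError(f"CDS [{s},{e}) outside exons of gene {gene_id!r}")
    introns = _subtract(span, exons)
    utr5, utr3 = utr5_explicit, utr3_explicit
    if not (utr5 or utr3) and cds:
        # derive UTRs as exonic sequence outside the CDS extent
        cds_lo, cds_hi = cds[0][0], cds[-1][1]
        left, right = [], []
        for s, e in exons:
            for ps, pe in _subtract((s, e), cds):
                if pe <= cds_lo:
                    left.append((ps, pe))
                elif ps >= cds_hi:
                    right.append((ps, pe))
        utr5, utr3 = (left, right) if strand == "+" else (right, left)
    return GeneModel(
        gene_id=gene_id,
        chrom=gene.seqid,
        start=span[0],
        end=span[1],
        strand=strand,
        biotype=CODING,
        exons=exons,
        cds=cds,
        utr5=_merge(utr5),
        utr3=_merge(utr3),
        introns=introns,
    )


def read_annotation(path: str | Path, genome: GenomeSequence) -> list[GeneModel]:
    """Parse a GFF3 annotation into one representative model per gene.

    Genes failing internal consistency (CDS outside exons, span outside the
    chromosome) are skipped with a warning; genes of unknown biotype are
    classified ncRNA (lncRNA) with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        if gene.seqid not in genome:
            logger.warning("gene %s on unknown chromosome %s: skipped", gene_id, gene.seqid)
            continue
        if not (1 <= gene.start <= gene.end <= genome.lengths[gene.seqid]):
            logger.warning("gene %s outside chromosome bounds: skipped", gene_id)
            continue
        biotype = _gene_biotype(db, gene)
        if not biotype:
            logger.warning("gene %s has unknown biotype: classified as lncRNA", gene_id)
            biotype = "lncRNA"
        if biotype == CODING:
            try:
                models.append(_build_coding_model(db, gene, gene_id))
            except ValueError as exc:
                logger.warning("gene %s rejected: %s", gene_id, exc)
        else:
            span = (gene.start - 1, gene.end)
            exons = _merge(
                [(f.start - 1, f.end) for f in db.children(gene, featuretype="exon")]
            ) or [span]
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=gene.seqid,
                    start=span[0],
                    end=span[1],
                    strand=gene.strand,
                    biotype=biotype,
                    exons=exons,
                )
            )
    return models


class FeaturePartition:
    """Per-position category labels plus per-category base/adenine counts."""

    def __init__(self, codes: dict[str, np.ndarray], genome: GenomeSequence):
        self.codes = codes
        self.genome = genome
        self._counts: pd.DataFrame | None = None

    def category_at(self, chrom: str, position: int) -> str:
        """Category label at a 1-based position."""
        return CATEGORIES[self.codes[chrom][position - 1]]

    def counts(self) -> pd.DataFrame:
        """Per-category totals: bases, adenines on each strand.

        Adenine on the minus strand is a T on the forward sequence.
        """
        if self._counts is None:
            n_cat = len(CATEGORIES)
            base = np.zeros(n_cat, dtype=np.int64)
            a_plus = np.zeros(n_cat, dtype=np.int64)
            a_minus = np.zeros(n_cat, dtype=np.int64)
            for chrom, codes in self.codes.items():
                seq = np.frombuffer(self.genome[chrom].encode(), dtype="S1")
                base += np.bincount(codes, minlength=n_cat)
                a_plus += np.bincount(codes[seq == b"A"], minlength=n_cat)
                a_minus += np.bincount(codes[seq == b"T"], minlength=n_cat)
            self._counts = pd.DataFrame(
                {
                    "category": CATEGORIES,
                    "n_bases": base,
                    "n_adenines_plus": a_plus,
                    "n_adenines_minus": a_minus,
                    "n_adenines": a_plus + a_minus,
                }
            )
        return self._counts

    def adenines_by_category(self) -> dict[str, int]:
        df = self.counts()
        return dict(zip(df["category"], df["n_adenines"]))


def build_partition(models: list[GeneModel], genome: GenomeSequence) -> FeaturePartition:
    """Label every genomic position with exactly one category.

    Categories are painted in increasing priority so that the final label at
    any position is the highest-priority annotation covering it; unpainted
    positions stay intergenic.  Exhaustiveness is structural (the array is
    initialized to intergenic), disjointness is structural (one code per
    position).
    """
    codes = {c: np.zeros(n, dtype=np.uint8) for c, n in genome.lengths.items()}
    by_cat: dict[str, list[tuple[str, int, int]]] = {c: [] for c in CATEGORIES}
    for m in models:
        for cat, ivs in m.category_intervals().items():
            for s, e in ivs:
                by_cat[cat].append((m.chrom, s, e))
    for cat in CATEGORIES[1:]:  # paint order = priority order, low to high
        code = CATEGORY_CODE[cat]
        for chrom, s, e in by_cat[cat]:
            codes[chrom][s:e] = code
    return FeaturePartition(codes, genome)


def _gene_trees(models: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for m in models:
        trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end, m)
    return trees


def annotate_sites(
    table: SiteTable, partition: FeaturePartition, models: list[GeneModel]
) -> pd.DataFrame:
    """Assign each site its partition category, host gene and TSS distance.

    The host gene is the overlapping gene whose own intervals of the site's
    category contain the position (ties broken by span start, then gene id);
    intergenic sites carry no gene.  TSS distance is signed in transcription
    orientation of the *nearest* TSS on the chromosome: negative = upstream.
    """
    trees = _gene_trees(models)
    tss_by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom in {m.chrom for m in models}:
        ms = sorted((m for m in models if m.chrom == chrom), key=lambda m: m.tss)
        tss_by_chrom[chrom] = (np.array([m.tss for m in ms], dtype=np.int64), ms)

    rows = []
    n_unknown = 0
    for r in table:
        if r.chrom not in partition.codes:
            n_unknown += 1
            continue
        pos0 = r.position - 1
        category = partition.category_at(r.chrom, r.position)
        gene_id = None
        if category != "intergenic" and r.chrom in trees:
            hits = sorted(
                (iv.data for iv in trees[r.chrom][pos0]),
                key=lambda m: (m.start, m.gene_id),
            )
            exact = [
                m
                for m in hits
                if any(
                    s <= pos0 < e
                    for s, e in m.category_intervals().get(category, [])
                )
            ]
            chosen = exact[0] if exact else (hits[0] if hits else None)
            gene_id = chosen.gene_id if chosen else None
        tss_distance = None
        if r.chrom in tss_by_chrom:
            arr, ms = tss_by_chrom[r.chrom]
            i = int(np.searchsorted(arr, pos0))
            best = None
            for j in (i - 1, i):
                if 0 <= j < len(ms):
                    d = abs(pos0 - arr[j])
                    if best is None or d < best[0]:
                        best = (d, ms[j])
            if best is not None:
                g = best[1]
                tss_distance = pos0 - g.tss if g.strand == "+" else g.tss - pos0
        rows.append(
            {
                "chrom": r.chrom,
                "position": r.position,
                "strand": r.strand,
                "category": category,
                "gene_id": gene_id,
                "tss_distance": tss_distance,
            }
        )
    if n_unknown:
        logger.warning("%d sites on chromosomes absent from the partition", n_unknown)
    return pd.DataFrame(
        rows,
        columns=["chrom", "position", "strand", "category", "gene_id", "tss_distance"],
    )


def write_partition_counts(partition: FeaturePartition, path: str | Path) -> None:
    df = partition.counts()
    with open(path, "w") as fh:
        fh.write("# per-category base and adenine counts (adenine- = T on forward)\n")
        df.to_csv(fh, sep="\t", index=False)
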