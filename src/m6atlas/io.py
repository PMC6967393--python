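"""Readers and writers for the external formats the pipeline consumes.

Formats handled here:

* genome FASTA (via :mod:`Bio.SeqIO`),
* base-modification calls in the ``modifications.gff`` dialect emitted by
  SMRT kinetic-detection tools (9 GFF-style columns, ``key=value``
  attributes holding ``coverage``, ``IPDRatio`` and, when the caller asked
  for methylated-fraction estimation, ``frac``),
* BED6 export of the filtered site table,
* two-column gene-expression TSV (``gene_id``, FPKM).

Coordinate convention: external formats are 1-based inclusive and
:class:`ModificationRecord.position` keeps that convention, mirroring the
dialect it came from.  Every *computed* structure in the package (gene-model
intervals, partition arrays, flank windows) is 0-based half-open; the only
conversion is ``position - 1``, done where a record meets an array.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Characters accepted in genome sequences (IUPAC nucleotide codes).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Uppercase nucleotide sequences keyed by chromosome identifier.

    Lookups are 1-based (matching the external call/annotation formats);
    out-of-bounds access raises ``ValueError``.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {str(c): s.upper() for c, s in sequences.items()}
        if len(self._seqs) != len(sequences):
            raise ValueError("duplicate chromosome identifiers")
        for chrom, seq in self._seqs.items():
            bad = set(seq) - IUPAC_DNA
            if bad:
                pos = next(i for i, b in enumerate(seq) if b in bad)
                raise ValueError(
                    f"non-IUPAC character {seq[pos]!r} in {chrom!r} at position {pos + 1}"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __len__(self) -> int:
        return len(self._seqs)

    def base(self, chrom: str, position: int, strand: str = "+") -> str:
        """Base at a 1-based position, complemented when ``strand == '-'``."""
        seq = self._seqs[chrom]
        if not 1 <= position <= len(seq):
            raise ValueError(
                f"position {position} outside [1, {len(seq)}] on {chrom!r}"
            )
        b = seq[position - 1]
        return b.translate(_COMPLEMENT) if strand == "-" else b

    def window(self, chrom: str, position: int, flank: int, strand: str = "+") -> str:
        """``2*flank + 1`` bases centered on a 1-based position, read 5'->3'
        on *strand*; runs past a chromosome end are padded with ``N``."""
        seq = self._seqs[chrom]
        if not 1 <= position <= len(seq):
            raise ValueError(
                f"position {position} outside [1, {len(seq)}] on {chrom!r}"
            )
        lo, hi = position - 1 - flank, position + flank
        core = seq[max(lo, 0) : min(hi, len(seq))]
        out = "N" * max(0, -lo) + core + "N" * max(0, hi - len(seq))
        return revcomp(out) if strand == "-" else out

    def total_adenines(self, chrom: str | None = None) -> dict[str, int]:
        """Adenine counts per strand: ``+`` counts A on the forward sequence,
        ``-`` counts T on the forward sequence (A on the reverse strand)."""
        chroms = [chrom] if chrom else self.chroms
        plus = sum(self._seqs[c].count("A") for c in chroms)
        minus = sum(self._seqs[c].count("T") for c in chroms)
        return {"+": plus, "-": minus}


def read_genome(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Duplicate headers and non-IUPAC characters are rejected; sequences are
    uppercased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate chromosome id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class ModificationRecord:
    """One called modified base.

    ``position`` is 1-based, on ``chrom``; ``strand`` is the strand carrying
    the methylated adenine.  ``ipd_ratio`` is the interpulse-duration ratio
    (dimensionless kinetic signal); ``frac`` is the estimated fraction of
    molecules methylated at the site, absent when the caller did not request
    fraction estimation.
    """

    chrom: str
    position: int
    strand: str
    coverage: int
    ipd_ratio: float = 1.0
    frac: float | None = None
    qv: int | None = None
    mod_type: str = "m6A"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.frac is not None and not 0.0 <= self.frac <= 1.0:
            raise ValueError(f"frac {self.frac} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.position, self.strand)


@dataclass
class ParseReport:
    """Counters accumulated while reading a modifications file."""

    n_parsed: int = 0
    skipped_types: Counter = field(default_factory=Counter)
    n_out_of_bounds: int = 0
    n_not_adenine: int = 0
    n_malformed: int = 0
    messages: list[str] = field(default_factory=list)

    def warn(self, msg: str) -> None:
        if len(self.messages) < 100:
            self.messages.append(msg)
        logger.warning(msg)


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"attribute {item!r} is not key=value")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def read_modifications(
    path: str | Path,
    genome: GenomeSequence,
    *,
    mod_type: str = "m6A",
    strict: bool = False,
) -> tuple[list[ModificationRecord], ParseReport]:
    """Parse a ``modifications.gff``-dialect file.

    Only records of *mod_type* are retained (others are counted in the
    report).  Positions are validated against *genome* and records whose
    reference base is not adenine on the called strand are excluded with a
    count — with ``strict=True`` any rejected line raises instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ModificationRecord] = []
    report = ParseReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) != 9:
                report.n_malformed += 1
                report.warn(f"line {lineno}: expected 9 columns, got {len(cols)}")
                if strict:
                    raise ValueError(f"line {lineno}: malformed record")
                continue
            if cols[2] != mod_type:
                report.skipped_types[cols[2]] += 1
                continue
            try:
                position = int(cols[3])
                strand = cols[6]
                attrs = _parse_attributes(cols[8])
                coverage = int(round(float(attrs["coverage"])))
                ipd = float(attrs.get("IPDRatio", 1.0))
                frac = float(attrs["frac"]) if "frac" in attrs else None
                qv = (
                    int(round(float(attrs["identificationQv"])))
                    if "identificationQv" in attrs
                    else None
                )
            except (KeyError, ValueError) as exc:
                report.n_malformed += 1
                report.warn(f"line {lineno}: malformed attributes ({exc})")
                if strict:
                    raise ValueError(f"line {lineno}: malformed record") from exc
                continue
            chrom = cols[0]
            if chrom not in genome or not 1 <= position <= genome.lengths[chrom]:
                report.n_out_of_bounds += 1
                report.warn(f"line {lineno}: position {chrom}:{position} out of bounds")
                if strict:
                    raise ValueError(f"line {lineno}: out-of-bounds record")
                continue
            if genome.base(chrom, position, strand) != "A":
                report.n_not_adenine += 1
                if strict:
                    raise ValueError(
                        f"line {lineno}: reference base at {chrom}:{position}({strand}) is not A"
                    )
                continue
            records.append(
                ModificationRecord(
                    chrom=chrom,
                    position=position,
                    strand=strand,
                    coverage=coverage,
                    ipd_ratio=ipd,
                    frac=frac,
                    qv=qv,
                    mod_type=mod_type,
                )
            )
            report.n_parsed += 1
    return records, report


class SiteTable:
    """Filtered, sorted, unique collection of modification calls."""

    def __init__(
        self,
        records: Iterable[ModificationRecord],
        *,
        coverage_cutoff: int | None = None,
        source: str | None = None,
    ):
        recs = sorted(records, key=lambda r: r.key)
        seen = set()
        for r in recs:
            if r.key in seen:
                raise ValueError(f"duplicate site {r.key}")
            seen.add(r.key)
        self.records: list[ModificationRecord] = recs
        self.coverage_cutoff = coverage_cutoff
        self.source = source
        self._by_chrom: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ModificationRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.records],
                "position": [r.position for r in self.records],
                "strand": [r.strand for r in self.records],
                "coverage": [r.coverage for r in self.records],
                "ipd_ratio": [r.ipd_ratio for r in self.records],
                "frac": [r.frac for r in self.records],
            }
        )

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted 0-based site positions per chromosome (both strands)."""
        if self._by_chrom is None:
            out: dict[str, list[int]] = {}
            for r in self.records:
                out.setdefault(r.chrom, []).append(r.position - 1)
            self._by_chrom = {c: np.array(sorted(p), dtype=np.int64) for c, p in out.items()}
        return self._by_chrom


def filter_by_coverage(
    records: Iterable[ModificationRecord],
    cutoff: int = 25,
    *,
    source: str | None = None,
) -> SiteTable:
    """Drop records with coverage strictly below *cutoff*.

    A record whose coverage equals the cutoff is retained (sites with *less
    than* cutoff-fold coverage are excluded).
    """
    if cutoff < 0:
        raise ValueError("coverage cutoff must be >= 0")
    records = list(records)
    kept = [r for r in records if r.coverage >= cutoff]
    logger.info(
        "coverage filter (>= %d): kept %d of %d records", cutoff, len(kept), len(records)
    )
    return SiteTable(kept, coverage_cutoff=cutoff, source=source)


def write_sites_bed(table: SiteTable, path: str | Path) -> None:
    """BED6 export: 0-based half-open, name = modification type, score =
    ``round(100 * frac)`` (0 when frac is absent)."""
    with open(path, "w") as fh:
        fh.write("# BED6 6mA sites: chrom start end name score(frac*100) strand\n")
        for r in table:
            score = int(round(100 * r.frac)) if r.frac is not None else 0
            fh.write(
                f"{r.chrom}\t{r.position - 1}\t{r.position}\t{r.mod_type}\t{score}\t{r.strand}\n"
            )


def read_sites_bed(path: str | Path) -> SiteTable:
    """Read a BED6 file produced by :func:`write_sites_bed`.

    Coverage is not representable in BED and comes back as 0; score is
    interpreted as ``frac * 100``.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            records.append(
                ModificationRecord(
                    chrom=chrom,
                    position=int(start) + 1,
                    strand=strand.strip(),
                    coverage=0,
                    frac=int(score) / 100.0,
                    mod_type=name,
                )
            )
    return SiteTable(records, source=str(path))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Two-column expression TSV (``gene_id``, FPKM) -> validated DataFrame.

    Header row optional.  Duplicate gene ids, negative and non-numeric FPKM
    values are rejected with the offending line number / gene id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gene_ids: list[str] = []
    fpkms: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated columns")
            gid, raw = parts[0], parts[1]
            try:
                val = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"line {lineno}: non-numeric FPKM {raw!r}") from None
            if val < 0:
                raise ValueError(f"line {lineno}: negative FPKM for {gid!r}")
            gene_ids.append(gid)
            fpkms.append(val)
    df = pd.DataFrame({"gene_id": gene_ids, "fpkm": fpkms})
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate gene_id {dup.iloc[0]!r} in expression table")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_id", "fpkm"]].to_csv(path, sep="\t", index=False)
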