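"""Flank extraction, positional base composition, and an enumerative
degenerate-motif scanner.

Each called site contributes a 9-mer read 5'->3' on the methylated strand
(position 0 = the methylated A; minus-strand windows are
reverse-complemented; chromosome ends are padded with N).  The motif
scanner enumerates exact k-mers (k = 5..7) over every window placement that
keeps the methylated A inside the motif, scores each against a background
of unmethylated adenine flanks by a one-sided Fisher exact test, greedily
collapses near-identical k-mers into IUPAC consensus strings, and reports
Bonferroni E-values (p x number of candidates tested).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomeSequence, SiteTable, revcomp

logger = logging.getLogger(__name__)

BASES = "ACGT"

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

IUPAC_SETS = {v: set(k) for k, v in IUPAC.items()}


@dataclass
class FlankSet:
    """Site-centered sequence windows of width ``2*flank + 1``."""

    flanks: list[str]
    flank: int = 4

    def __post_init__(self) -> None:
        w = 2 * self.flank + 1
        for f in self.flanks:
            if len(f) != w:
                raise ValueError(f"flank {f!r} is not {w} bp")

    def __len__(self) -> int:
        return len(self.flanks)

    def __iter__(self):
        return iter(self.flanks)


def extract_flanks(table: SiteTable, genome: GenomeSequence, flank: int = 4) -> FlankSet:
    """One window per site; the flank count always equals the site count."""
    return FlankSet(
        [genome.window(r.chrom, r.position, flank, r.strand) for r in table],
        flank=flank,
    )


def composition(flanks: FlankSet) -> pd.DataFrame:
    """Per-position base frequencies over non-N observations.

    Rows are positions -flank..+flank (0 = methylated A), columns A/C/G/T;
    each row sums to 1.  A separate ``n_N`` column counts excluded Ns.
    """
    if len(flanks) == 0:
        raise ValueError("empty flank set")
    w = 2 * flanks.flank + 1
    counts = np.zeros((w, 4), dtype=np.int64)
    n_N = np.zeros(w, dtype=np.int64)
    idx = {b: i for i, b in enumerate(BASES)}
    for f in flanks:
        for i, b in enumerate(f):
            if b in idx:
                counts[i, idx[b]] += 1
            else:
                n_N[i] += 1
    denom = counts.sum(axis=1, keepdims=True)
    freq = np.divide(counts, denom, out=np.zeros_like(counts, dtype=float), where=denom > 0)
    df = pd.DataFrame(freq, columns=list(BASES))
    df.insert(0, "position", np.arange(-flanks.flank, flanks.flank + 1))
    df["n_N"] = n_N
    return df


def sample_background_flanks(
    genome: GenomeSequence,
    table: SiteTable,
    n: int,
    *,
    flank: int = 4,
    seed: int = 0,
) -> FlankSet:
    """Flanks of *n* adenines sampled uniformly genome-wide, excluding the
    called sites, on either strand."""
    rng = np.random.default_rng(seed)
    called = {(r.chrom, r.position, r.strand) for r in table}
    chroms = genome.chroms
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=np.float64)
    weights = lengths / lengths.sum()
    out: list[str] = []
    guard = 0
    while len(out) < n and guard < 200:
        guard += 1
        m = max(2 * (n - len(out)), 64)
        ci = rng.choice(len(chroms), size=m, p=weights)
        strands = rng.choice(["+", "-"], size=m)
        for k in range(m):
            chrom = chroms[ci[k]]
            pos = int(rng.integers(1, genome.lengths[chrom] + 1))
            strand = strands[k]
            if (chrom, pos, strand) in called:
                continue
            if genome.base(chrom, pos, strand) != "A":
                continue
            out.append(genome.window(chrom, pos, flank, strand))
            if len(out) == n:
                break
    if len(out) < n:
        raise RuntimeError("could not sample enough background adenines")
    return FlankSet(out, flank=flank)


@dataclass
class MotifCandidate:
    consensus: str
    k: int
    offset: int  # index of the methylated A within the consensus
    fg_count: int
    bg_count: int
    fg_n: int
    bg_n: int
    p_value: float
    e_value: float
    fraction: float  # fg_count / fg_n
    members: list[str] = field(default_factory=list)


def _windows(flank: int, k_range: tuple[int, ...]) -> list[tuple[int, int]]:
    """(k, offset) placements keeping the methylated A inside a k-window
    that fits within the +-flank sequence."""
    out = []
    for k in k_range:
        for off in range(k):
            start = flank - off  # window start in flank coordinates
            if 0 <= start and start + k <= 2 * flank + 1:
                out.append((k, off))
    return out


def _consensus(members: list[tuple[str, int]], letter_freq: float) -> str:
    """IUPAC consensus over count-weighted member columns.  The first
    (seed) member's letters are always included so the consensus is
    guaranteed to match at least that k-mer."""
    seed = members[0][0]
    k = len(seed)
    cols = []
    total = sum(c for _, c in members)
    for i in range(k):
        col = Counter()
        for kmer, c in members:
            col[kmer[i]] += c
        letters = {b for b in BASES if col[b] / total >= letter_freq}
        letters.add(seed[i])
        cols.append(IUPAC[frozenset(letters)])
    return "".join(cols)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_motifs(
    flanks: FlankSet,
    background: FlankSet,
    *,
    k_range: tuple[int, ...] = (5, 6, 7),
    min_count: int = 5,
    merge_hamming: int = 2,
    letter_freq: float = 0.25,
) -> list[MotifCandidate]:
    """Enumerate, score, and collapse k-mers into ranked degenerate motifs.

    Scoring is a one-sided (over-representation) Fisher exact test of
    foreground vs background hit counts; clusters merge k-mers identical at
    >= k - merge_hamming positions within the same (k, offset) placement.
    E = Fisher p of the merged counts x total candidates tested.  Returns
    candidates ranked by ascending E.  N-containing windows are skipped.
    """
    if len(flanks) == 0 or len(background) == 0:
        raise ValueError("foreground and background flank sets must be nonempty")
    fg_n, bg_n = 0, 0
    placements = _windows(flanks.flank, tuple(k_range))
    fg_counts: dict[tuple[int, int], Counter] = {p: Counter() for p in placements}
    bg_counts: dict[tuple[int, int], Counter] = {p: Counter() for p in placements}

    def tally(fl: FlankSet, store) -> int:
        n = 0
        for f in fl:
            n += 1
            for (k, off) in placements:
                sub = f[fl.flank - off : fl.flank - off + k]
                if "N" not in sub:
                    store[(k, off)][sub] += 1
        return n

    fg_n = tally(flanks, fg_counts)
    bg_n = tally(background, bg_counts)

    scored: dict[tuple[int, int], list[tuple[str, int, int, float]]] = {}
    n_candidates = 0
    for p in placements:
        lst = []
        for kmer, a in fg_counts[p].items():
            if a < min_count:
                continue
            b = bg_counts[p].get(kmer, 0)
            pv = stats.fisher_exact(
                [[a, fg_n - a], [b, bg_n - b]], alternative="greater"
            ).pvalue
            lst.append((kmer, a, b, pv))
            n_candidates += 1
        scored[p] = sorted(lst, key=lambda t: (t[3], t[0]))

    if n_candidates == 0:
        logger.warning("no k-mer reached min_count=%d; empty motif set", min_count)
        return []

    candidates: list[MotifCandidate] = []
    for (k, off), lst in scored.items():
        used = [False] * len(lst)
        for i, (kmer, a, b, pv) in enumerate(lst):
            if used[i]:
                continue
            used[i] = True
            members = [(kmer, a)]
            fg_sum, bg_sum = a, b
            for j in range(i + 1, len(lst)):
                if used[j]:
                    continue
                km2, a2, b2, _ = lst[j]
                if _hamming(kmer, km2) <= merge_hamming:
                    used[j] = True
                    members.append((km2, a2))
                    fg_sum += a2
                    bg_sum += b2
            p_merged = stats.fisher_exact(
                [[fg_sum, fg_n - fg_sum], [bg_sum, bg_n - bg_sum]],
                alternative="greater",
            ).pvalue
            candidates.append(
                MotifCandidate(
                    consensus=_consensus(members, letter_freq),
                    k=k,
                    offset=off,
                    fg_count=fg_sum,
                    bg_count=bg_sum,
                    fg_n=fg_n,
                    bg_n=bg_n,
                    p_value=p_merged,
                    e_value=min(p_merged * n_candidates, np.inf),
                    fraction=fg_sum / fg_n,
                    members=[m for m, _ in members],
                )
            )
    candidates.sort(key=lambda c: (c.e_value, c.p_value, c.consensus))
    return candidates


def motif_table(candidates: list[MotifCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "consensus": c.consensus,
                "k": c.k,
                "offset": c.offset,
                "fg_count": c.fg_count,
                "bg_count": c.bg_count,
                "fg_n": c.fg_n,
                "bg_n": c.bg_n,
                "p_value": c.p_value,
                "e_value": c.e_value,
                "fraction": c.fraction,
            }
            for c in candidates
        ],
        columns=[
            "consensus", "k", "offset", "fg_count", "bg_count",
            "fg_n", "bg_n", "p_value", "e_value", "fraction",
        ],
    )


def matches(consensus: str, kmer: str) -> bool:
    """Whether an exact k-mer is matched by an IUPAC consensus."""
    return len(consensus) == len(kmer) and all(
        b in IUPAC_SETS[c] for c, b in zip(consensus, kmer)
    )


def write_pfm_meme(candidates: list[MotifCandidate], flanks: FlankSet, path) -> None:
    """Minimal MEME-format position frequency matrices for the candidates,
    built from the member k-mer counts."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for c in candidates:
            fh.write(f"MOTIF {c.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {c.k} nsites= {c.fg_count} E= {c.e_value:.3g}\n"
            )
            counts = np.zeros((c.k, 4))
            for m in c.members:
                for i, b in enumerate(m):
                    counts[i, BASES.index(b)] += 1
            freq = counts / counts.sum(axis=1, keepdims=True)
            for row in freq:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
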