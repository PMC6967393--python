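"""Seeded generator of a toy genome with planted 6mA structure.

The generator emits everything the pipeline consumes — genome FASTA, GFF3
annotation, a modification-call file in the ``modifications.gff`` dialect,
an expression TSV and a gene->GO map — with the statistical features the
analysis assumes: per-category methylation rates (CDS enriched over
intergenic by default), a planted AGG-context bias at a configurable
fraction of sites, multiplicative site depletion around TSSs, a
low/moderate/high mixture of methylated fractions, negative-binomial
coverage straddling the 25x cutoff, and log-linear coupling of expression
to per-gene 6mA density.  The planted truth is kept alongside so recovery
can be checked stage by stage.

Everything is driven by one ``numpy`` generator; the same seed yields
byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .features import CATEGORIES, FeaturePartition, GeneModel, build_partition
from .io import GenomeSequence, ModificationRecord

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults give a 1 Mb toy genome whose
    landscape statistics are stable but fast to compute."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    gc_fraction: float = 0.42
    n_coding_genes: int = 300
    n_lncrna_genes: int = 60
    exons_per_gene: tuple[int, int] = (1, 5)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 200)
    utr5_length: tuple[int, int] = (30, 120)
    utr3_length: tuple[int, int] = (30, 150)
    lnc_length: tuple[int, int] = (200, 800)
    intergenic_gap: int = 200
    # per-category adenine methylation rates (fraction of adenines)
    rate_cds: float = 0.003
    rate_utr: float = 0.002
    rate_intron: float = 0.0015
    rate_ncrna: float = 0.002
    rate_intergenic: float = 0.001
    #: fraction of sites relocated to adenines with GG at +1..+2 (AGG core)
    motif_bias: float = 0.5
    #: multiplicative rate factor within +-tss_window of a TSS (<1 = depleted)
    tss_depletion: float = 0.5
    tss_window: int = 200
    frac_weights: tuple[float, float, float] = (0.2, 0.3, 0.5)
    frac_params: tuple[tuple[float, float], ...] = ((2.5, 10.0), (20.0, 20.0), (10.0, 2.5))
    coverage_mean: float = 60.0
    coverage_shape: float = 10.0
    # expression model: log FPKM = alpha + beta * z(density) + N(0, sigma)
    expr_alpha: float = 1.0
    expr_beta: float = 0.5
    expr_sigma: float = 1.0
    expr_zero_fraction: float = 0.1
    n_go_terms: int = 50
    go_term_prob: float = 0.05

    def rates_by_category(self) -> dict[str, float]:
        return {
            "CDS": self.rate_cds,
            "fiveUTR": self.rate_utr,
            "threeUTR": self.rate_utr,
            "intron": self.rate_intron,
            "ncRNA": self.rate_ncrna,
            "intergenic": self.rate_intergenic,
        }


@dataclass
class SyntheticTruth:
    """Planted ground truth, consistent with the emitted files."""

    sites: pd.DataFrame  # chrom, position (1-based), strand, category
    category_adenines: dict[str, int]
    realized_rates: dict[str, float]
    motif_fraction: float  # realized fraction of sites with GG at +1..+2
    beta: float
    gene_density: pd.DataFrame  # gene_id, biotype, n_sites, n_adenines, density
    config: SyntheticConfig


@dataclass
class SyntheticBundle:
    genome: GenomeSequence
    models: list[GeneModel]
    partition: FeaturePartition
    records: list[ModificationRecord]
    expression: pd.DataFrame
    go_map: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every file the pipeline reads, plus the truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gff3",
            "modifications": outdir / "modifications.gff",
            "expression": outdir / "expression.tsv",
            "go_map": outdir / "go_map.tsv",
            "truth_sites": outdir / "truth_sites.tsv",
            "config": outdir / "config.txt",
            "truth_summary": outdir / "truth_summary.txt",
        }
        mio.write_genome(self.genome, paths["genome"])
        write_gff3(self.models, paths["annotation"])
        write_modifications(self.records, paths["modifications"])
        mio.write_expression(self.expression, paths["expression"])
        self.go_map.to_csv(paths["go_map"], sep="\t", index=False)
        self.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
        with open(paths["config"], "w") as fh:
            for k, v in asdict(self.truth.config).items():
                fh.write(f"{k}={v}\n")
        with open(paths["truth_summary"], "w") as fh:
            fh.write(f"n_sites={len(self.truth.sites)}\n")
            fh.write(f"motif_fraction={self.truth.motif_fraction:.6f}\n")
            fh.write(f"beta={self.truth.beta}\n")
            for c, r in self.truth.realized_rates.items():
                fh.write(f"rate_{c}={r:.8f}\n")
        return paths


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    """GFF3 with gene/mRNA/exon/CDS rows for coding genes and
    gene/lnc_RNA (or tRNA/rRNA)/exon rows for non-coding genes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id)):
            base = f"{m.chrom}\tm6atlas_sim"
            tail = f".\t{m.strand}\t"
            gid = m.gene_id
            bt = m.biotype
            fh.write(
                f"{base}\tgene\t{m.start + 1}\t{m.end}\t{tail}.\tID={gid};gene_biotype={bt}\n"
            )
            if bt == "protein_coding":
                tid = f"{gid}.t1"
                fh.write(
                    f"{base}\tmRNA\t{m.start + 1}\t{m.end}\t{tail}.\tID={tid};Parent={gid}\n"
                )
                for i, (s, e) in enumerate(m.exons, 1):
                    fh.write(
                        f"{base}\texon\t{s + 1}\t{e}\t{tail}.\tID={tid}.exon{i};Parent={tid}\n"
                    )
                for i, (s, e) in enumerate(m.cds, 1):
                    fh.write(
                        f"{base}\tCDS\t{s + 1}\t{e}\t{tail}0\tID={tid}.cds{i};Parent={tid}\n"
                    )
            else:
                ftype = {"lncRNA": "lnc_RNA", "tRNA": "tRNA", "rRNA": "rRNA"}[bt]
                tid = f"{gid}.t1"
                fh.write(
                    f"{base}\t{ftype}\t{m.start + 1}\t{m.end}\t{tail}.\tID={tid};Parent={gid}\n"
                )
                for i, (s, e) in enumerate(m.exons, 1):
                    fh.write(
                        f"{base}\texon\t{s + 1}\t{e}\t{tail}.\tID={tid}.exon{i};Parent={tid}\n"
                    )


def write_modifications(records: list[ModificationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("##source m6atlas synthetic kinetic-call emulation\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.position, r.strand)):
            attrs = f"coverage={r.coverage};IPDRatio={r.ipd_ratio:.2f}"
            if r.frac is not None:
                attrs += f";frac={r.frac:.4f}"
            if r.qv is not None:
                attrs += f";identificationQv={r.qv}"
            fh.write(
                f"{r.chrom}\tkinModCall\t{r.mod_type}\t{r.position}\t{r.position}\t"
                f"{int(20 + 10 * r.ipd_ratio)}\t{r.strand}\t.\t{attrs}\n"
            )


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def _build_gene(
    rng: np.random.Generator, cfg: SyntheticConfig, chrom: str, cursor: int, coding: bool, idx: int
) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    if not coding:
        length = int(rng.integers(cfg.lnc_length[0], cfg.lnc_length[1] + 1))
        start, end = cursor, cursor + length
        return GeneModel(
            gene_id=f"lnc{idx:04d}",
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            biotype="lncRNA",
            exons=[(start, end)],
        )
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    ex_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex)
    in_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=max(n_ex - 1, 0))
    utr5_len = int(rng.integers(cfg.utr5_length[0], cfg.utr5_length[1] + 1))
    utr3_len = int(rng.integers(cfg.utr3_length[0], cfg.utr3_length[1] + 1))
    left_len, right_len = (utr5_len, utr3_len) if strand == "+" else (utr3_len, utr5_len)
    cds, introns, exons = [], [], []
    pos = cursor
    start = cursor
    for i in range(n_ex):
        ex_start = pos
        ex_end = pos + int(ex_lens[i])
        cds_s, cds_e = ex_start, ex_end
        if i == 0:
            cds_s = ex_start + left_len
            ex_end = max(ex_end, cds_s + 10)
            cds_e = ex_end
        if i == n_ex - 1:
            cds_e = max(ex_end - right_len, cds_s + 10)
            ex_end = cds_e + right_len
        exons.append((ex_start, ex_end))
        cds.append((cds_s, cds_e))
        pos = ex_end
        if i < n_ex - 1:
            introns.append((pos, pos + int(in_lens[i])))
            pos += int(in_lens[i])
    end = pos
    left = [(start, start + left_len)]
    right = [(end - right_len, end)]
    utr5, utr3 = (left, right) if strand == "+" else (right, left)
    return GeneModel(
        gene_id=f"gene{idx:04d}",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        biotype="protein_coding",
        exons=exons,
        cds=cds,
        utr5=utr5,
        utr3=utr3,
        introns=introns,
    )


def _place_genes(
    rng: np.random.Generator, cfg: SyntheticConfig, chroms: list[str]
) -> list[GeneModel]:
    order = ["coding"] * cfg.n_coding_genes + ["lnc"] * cfg.n_lncrna_genes
    rng.shuffle(order)
    per_chrom = np.array_split(np.array(order), len(chroms))
    models: list[GeneModel] = []
    c_idx, l_idx = 0, 0
    for chrom, kinds in zip(chroms, per_chrom):
        cursor = cfg.intergenic_gap
        for kind in kinds:
            gap = int(rng.integers(cfg.intergenic_gap, 3 * cfg.intergenic_gap))
            cursor += gap
            if kind == "coding":
                g = _build_gene(rng, cfg, chrom, cursor, True, c_idx)
                c_idx += 1
            else:
                g = _build_gene(rng, cfg, chrom, cursor, False, l_idx)
                l_idx += 1
            if g.end + cfg.intergenic_gap > cfg.chrom_length:
                raise ValueError(
                    f"genes do not fit on {chrom}: need > {g.end} bp, have {cfg.chrom_length}"
                )
            models.append(g)
            cursor = g.end
    return models


def _gg_context_mask(seq: np.ndarray, positions: np.ndarray, strand: str) -> np.ndarray:
    """Which 0-based adenine positions have GG immediately 3' on *strand*."""
    n = len(seq)
    if strand == "+":
        ok = positions < n - 2
        out = np.zeros(len(positions), dtype=bool)
        p = positions[ok]
        out[ok] = (seq[p + 1] == b"G") & (seq[p + 2] == b"G")
    else:
        ok = positions >= 2
        out = np.zeros(len(positions), dtype=bool)
        p = positions[ok]
        out[ok] = (seq[p - 1] == b"C") & (seq[p - 2] == b"C")
    return out


def generate(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Build the full synthetic bundle in memory (see module docstring)."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    seq_arrays = {c: _random_sequence(rng, cfg.chrom_length, cfg.gc_fraction) for c in chroms}
    genome = GenomeSequence({c: a.tobytes().decode() for c, a in seq_arrays.items()})
    models = _place_genes(rng, cfg, chroms)
    partition = build_partition(models, genome)
    rates = cfg.rates_by_category()
    rate_by_code = np.array([rates[c] for c in CATEGORIES])

    # TSS depletion factor per position
    factors = {c: np.ones(cfg.chrom_length) for c in chroms}
    if cfg.tss_depletion != 1.0:
        for m in models:
            lo = max(m.tss - cfg.tss_window, 0)
            hi = min(m.tss + cfg.tss_window, cfg.chrom_length)
            factors[m.chrom][lo:hi] *= cfg.tss_depletion

    site_rows: list[tuple[str, int, str, int]] = []  # chrom, pos0, strand, code
    for chrom in chroms:
        seq = seq_arrays[chrom]
        codes = partition.codes[chrom]
        for strand, base in (("+", b"A"), ("-", b"T")):
            pos = np.flatnonzero(seq == base)
            p_meth = rate_by_code[codes[pos]] * factors[chrom][pos]
            drawn = pos[rng.random(len(pos)) < p_meth]
            for p in drawn:
                site_rows.append((chrom, int(p), strand, int(codes[p])))

    # motif bias: relocate a fraction of sites onto GG-context adenines of
    # the same chromosome/strand/category (preserves category counts)
    if cfg.motif_bias > 0 and site_rows:
        occupied = {(c, p, s) for c, p, s, _ in site_rows}
        pools: dict[tuple[str, str, int], list[int]] = {}
        for chrom in chroms:
            seq = seq_arrays[chrom]
            codes = partition.codes[chrom]
            for strand, base in (("+", b"A"), ("-", b"T")):
                pos = np.flatnonzero(seq == base)
                gg = pos[_gg_context_mask(seq, pos, strand)]
                for code in range(len(CATEGORIES)):
                    cand = gg[codes[gg] == code]
                    cand = cand[rng.permutation(len(cand))]
                    pools[(chrom, strand, code)] = [
                        int(p) for p in cand if (chrom, int(p), strand) not in occupied
                    ]
        n_bias = int(round(cfg.motif_bias * len(site_rows)))
        chosen = rng.choice(len(site_rows), size=n_bias, replace=False)
        for i in chosen:
            chrom, p, strand, code = site_rows[i]
            seq = seq_arrays[chrom]
            if _gg_context_mask(seq, np.array([p]), strand)[0]:
                continue  # already AGG-context
            pool = pools.get((chrom, strand, code), [])
            while pool:
                q = pool.pop()
                if (chrom, q, strand) not in occupied:
                    occupied.discard((chrom, p, strand))
                    occupied.add((chrom, q, strand))
                    site_rows[i] = (chrom, q, strand, code)
                    break

    site_rows.sort()
    n_sites = len(site_rows)

    # methylated fraction mixture, coverage, IPD ratio
    comp = rng.choice(len(cfg.frac_weights), size=n_sites, p=cfg.frac_weights)
    a = np.array([cfg.frac_params[c][0] for c in comp])
    b = np.array([cfg.frac_params[c][1] for c in comp])
    fracs = np.clip(rng.beta(a, b) if n_sites else np.array([]), 0.0, 1.0)
    shape = cfg.coverage_shape
    coverage = rng.negative_binomial(shape, shape / (shape + cfg.coverage_mean), size=n_sites)
    ipd = rng.lognormal(mean=np.log(4.0), sigma=0.3, size=n_sites)
    qv = rng.integers(20, 200, size=n_sites)

    records = [
        ModificationRecord(
            chrom=c,
            position=p + 1,
            strand=s,
            coverage=int(coverage[i]),
            ipd_ratio=float(ipd[i]),
            frac=float(round(fracs[i], 4)),
            qv=int(qv[i]),
        )
        for i, (c, p, s, _) in enumerate(site_rows)
    ]

    # realized statistics for the truth record
    cat_adenines = partition.adenines_by_category()
    planted_by_cat = pd.Series([CATEGORIES[code] for _, _, _, code in site_rows])
    realized = {
        c: (int((planted_by_cat == c).sum()) / cat_adenines[c] if cat_adenines[c] else np.nan)
        for c in CATEGORIES
    }
    n_gg = sum(
        bool(_gg_context_mask(seq_arrays[c], np.array([p]), s)[0])
        for c, p, s, _ in site_rows
    )
    motif_fraction = n_gg / n_sites if n_sites else 0.0

    # per-gene density and the expression model
    gene_rows = []
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom in chroms:
        pos_by_chrom[chrom] = np.array(
            sorted(p for c, p, _, _ in site_rows if c == chrom), dtype=np.int64
        )
    for m in models:
        seq = genome[m.chrom][m.start : m.end]
        n_a = seq.count("A") + seq.count("T")
        lo, hi = np.searchsorted(pos_by_chrom[m.chrom], [m.start, m.end])
        gene_rows.append(
            {
                "gene_id": m.gene_id,
                "biotype": m.biotype,
                "n_sites": int(hi - lo),
                "n_adenines": n_a,
                "density": (hi - lo) / n_a if n_a else np.nan,
            }
        )
    gene_density = pd.DataFrame(gene_rows)

    coding = gene_density[gene_density["biotype"] == "protein_coding"].reset_index(drop=True)
    d = coding["density"].to_numpy(dtype=float)
    z = (d - d.mean()) / d.std() if d.std() > 0 else np.zeros_like(d)
    log_fpkm = cfg.expr_alpha + cfg.expr_beta * z + rng.normal(0, cfg.expr_sigma, size=len(d))
    fpkm = np.exp(log_fpkm)
    zero = rng.random(len(d)) < cfg.expr_zero_fraction
    fpkm[zero] = 0.0
    expression = pd.DataFrame(
        {"gene_id": coding["gene_id"], "fpkm": np.round(fpkm, 4)}
    )

    terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_terms)]
    go_rows = []
    for gid in coding["gene_id"]:
        has = rng.random(cfg.n_go_terms) < cfg.go_term_prob
        for t in np.array(terms)[has]:
            go_rows.append({"gene_id": gid, "term": t})
    go_map = pd.DataFrame(go_rows, columns=["gene_id", "term"])

    truth = SyntheticTruth(
        sites=pd.DataFrame(
            {
                "chrom": [c for c, _, _, _ in site_rows],
                "position": [p + 1 for _, p, _, _ in site_rows],
                "strand": [s for _, _, s, _ in site_rows],
                "category": [CATEGORIES[code] for _, _, _, code in site_rows],
            }
        ),
        category_adenines=cat_adenines,
        realized_rates=realized,
        motif_fraction=motif_fraction,
        beta=cfg.expr_beta,
        gene_density=gene_density,
        config=cfg,
    )
    logger.info("synthetic bundle: %d sites, %d genes", n_sites, len(models))
    return SyntheticBundle(
        genome=genome,
        models=models,
        partition=partition,
        records=records,
        expression=expression,
        go_map=go_map,
        truth=truth,
    )


def simulate_expression_table(
    n_genes: int,
    beta: float,
    *,
    alpha: float = 1.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct draw from the expression model on lognormal gene densities:
    log FPKM = alpha + beta * z(density) + N(0, sigma).  Used for power and
    sign-recovery checks at sizes where building a full genome is wasteful."""
    rng = np.random.default_rng(seed)
    density = rng.lognormal(mean=np.log(1.5e-3), sigma=0.6, size=n_genes)
    z = (density - density.mean()) / density.std()
    fpkm = np.exp(alpha + beta * z + rng.normal(0, sigma, size=n_genes))
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "density": density,
            "fpkm": fpkm,
        }
    )


def truth_check(truth: SyntheticTruth, outputs: dict) -> pd.DataFrame:
    """Compare planted truth against pipeline outputs.

    *outputs* may contain ``density`` (per-category density table),
    ``motifs`` (ranked candidates), ``tss_profile`` (occupancy DataFrame),
    ``expression`` (GroupComparison of the density split) and
    ``gene_classes`` (gene_methylation DataFrame).  Missing keys yield FAIL
    rows, not exceptions.
    """
    from .motifs import IUPAC_SETS  # local import to avoid cycle at module load

    checks = []

    def add(name: str, ok: bool | None, detail: str) -> None:
        checks.append(
            {"check": name, "status": "PASS" if ok else ("FAIL" if ok is False else "MISSING"),
             "detail": detail}
        )

    dens = outputs.get("density")
    if dens is None:
        add("category_density", None, "no density table supplied")
    else:
        ok = True
        details = []
        for c, rate in truth.realized_rates.items():
            row = dens[dens["group"] == c]
            if row.empty or not np.isfinite(rate):
                continue
            n_a = int(row["n_adenines"].iloc[0])
            got = float(row["density"].iloc[0])
            se = np.sqrt(max(rate * (1 - rate), 1e-12) / max(n_a, 1))
            # coverage filtering thins sites, so allow a one-sided margin
            if got > rate + 3 * se:
                ok = False
            details.append(f"{c}: planted {rate:.2e}, recovered {got:.2e}")
        add("category_density", ok, "; ".join(details))

    mots = outputs.get("motifs")
    if mots is None:
        add("motif_recovery", None, "no motif candidates supplied")
    elif truth.config.motif_bias > 0:
        if len(mots) == 0:
            add("motif_recovery", False, "no candidates")
        else:
            top = mots[0]
            off = top.offset
            cons = top.consensus
            ok = (
                off + 2 < len(cons)
                and "A" in IUPAC_SETS[cons[off]]
                and "G" in IUPAC_SETS[cons[off + 1]]
                and "G" in IUPAC_SETS[cons[off + 2]]
            )
            add("motif_recovery", ok, f"rank-1 consensus {cons} (A at {off})")

    prof = outputs.get("tss_profile")
    if prof is None:
        add("tss_depletion", None, "no occupancy profile supplied")
    elif truth.config.tss_depletion < 1.0:
        central = prof[(prof.window_start >= -200) & (prof.window_end <= 200)]
        flank = prof[(prof.window_start < -200) | (prof.window_end > 200)]
        ok = central.occupancy.mean() < flank.occupancy.mean()
        add(
            "tss_depletion",
            ok,
            f"central {central.occupancy.mean():.4f} vs flank {flank.occupancy.mean():.4f}",
        )

    comp = outputs.get("expression")
    if comp is None:
        add("expression_effect", None, "no expression comparison supplied")
    elif truth.beta != 0:
        ok = comp.direction == int(np.sign(truth.beta))
        add(
            "expression_effect",
            ok,
            f"planted beta {truth.beta:+.2f}, recovered direction {comp.direction:+d} (p={comp.p_value:.2e})",
        )

    gm = outputs.get("gene_classes")
    if gm is None:
        add("k_classification", None, "no gene classification supplied")
    else:
        meth = gm[gm["n_sites"] > 0]
        mean_density = meth["density"].mean()
        expect = {"high": 0, "low": 0, "moderate": 0, "non": int((gm["n_sites"] == 0).sum())}
        for d in meth["density"]:
            K = np.log2(d / mean_density)
            expect["high" if K > 1 else ("low" if K < -1 else "moderate")] += 1
        got = gm["klass"].value_counts().to_dict()
        ok = all(got.get(k, 0) == v for k, v in expect.items())
        add("k_classification", ok, f"expected {expect}, got { {k: got.get(k, 0) for k in expect} }")

    return pd.DataFrame(checks)
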