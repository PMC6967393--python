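"""End-to-end orchestration: filter -> partition -> landscape -> motifs ->
TSS profiles -> expression association -> GO, with TSV reports and a
key=value run manifest."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import association, features, io, landscape, motifs, tss

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: Path
    annotation: Path
    modifications: Path
    outdir: Path
    expression: Path | None = None
    go_map: Path | None = None
    min_coverage: int = 25
    enrichment_test: str = "binomial"
    flank: int = 4
    motif_k: tuple[int, ...] = (5, 6, 7)
    motif_min_count: int = 5
    background_ratio: int = 10
    tss_span: int = 1000
    tss_window: int = 50
    seed: int = 0


def _write(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run every stage whose inputs are available; returns the in-memory
    results keyed by stage.  Optional inputs (expression, GO map) being
    absent skips the dependent stages with a logged notice."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = dict(asdict(config))
    results: dict[str, object] = {}

    genome = io.read_genome(config.genome)
    models = features.read_annotation(config.annotation, genome)
    raw, report = io.read_modifications(config.modifications, genome)
    table = io.filter_by_coverage(raw, config.min_coverage, source=str(config.modifications))
    manifest.update(
        n_records_parsed=report.n_parsed,
        n_records_malformed=report.n_malformed,
        n_records_out_of_bounds=report.n_out_of_bounds,
        n_records_not_adenine=report.n_not_adenine,
        n_sites_filtered=len(table),
        n_sites_removed=report.n_parsed - len(table),
        n_genes=len(models),
    )
    io.write_sites_bed(table, out / "sites.bed")
    results["table"] = table

    partition = features.build_partition(models, genome)
    features.write_partition_counts(partition, out / "partition_counts.tsv")
    annotated = features.annotate_sites(table, partition, models)
    _write(annotated, out / "site_annotation.tsv", "per-site category / gene / TSS distance")
    results["partition"] = partition
    results["annotation"] = annotated

    dens_chrom = landscape.density_table(table, genome, group_by="chromosome")
    _write(dens_chrom, out / "density_by_chromosome.tsv", "6mA density per chromosome")
    dens_cat = landscape.density_table(table, genome, partition=partition, group_by="category")
    _write(dens_cat, out / "density_by_category.tsv", "6mA density per feature category")
    enr = landscape.enrichment_test(table, partition, test=config.enrichment_test)
    _write(enr, out / "enrichment.tsv", f"observed vs expected ({config.enrichment_test})")
    bins = landscape.bin_levels(table)
    pd.DataFrame([asdict(bins)]).to_csv(out / "level_bins.tsv", sep="\t", index=False)
    track = landscape.level_track(table, genome)
    _write(track, out / "level_track.tsv", "per-window methylation-level counts")
    gene_meth = landscape.gene_methylation(table, models, genome)
    _write(gene_meth, out / "gene_methylation.tsv", "per-gene density, K and class")
    results.update(density_chromosome=dens_chrom, density_category=dens_cat,
                   enrichment=enr, level_bins=bins, gene_methylation=gene_meth)

    flanks = motifs.extract_flanks(table, genome, config.flank)
    comp = motifs.composition(flanks)
    _write(comp, out / "flank_composition.tsv", "base frequency by position (0 = 6mA)")
    background = motifs.sample_background_flanks(
        genome, table, config.background_ratio * len(flanks),
        flank=config.flank, seed=config.seed,
    )
    cands = motifs.find_motifs(
        flanks, background, k_range=config.motif_k, min_count=config.motif_min_count
    )
    _write(motifs.motif_table(cands), out / "motifs.tsv",
           f"ranked candidates; background seed={config.seed}")
    results.update(flanks=flanks, composition=comp, motifs=cands)

    biotypes = {m.biotype for m in models}
    profiles = []
    for bt in ("protein_coding", "lncRNA"):
        if bt in biotypes:
            profiles.append(
                tss.tss_occupancy(table, models, bt, span=config.tss_span,
                                  window=config.tss_window)
            )
    if profiles:
        _write(pd.concat(profiles, ignore_index=True), out / "tss_occupancy.tsv",
               "methylated-gene fraction per 50-bp window around the TSS")
        results["tss_occupancy"] = profiles
    if len(profiles) == 2:
        contrast = tss.central_occupancy_contrast(profiles[0], profiles[1])
        manifest.update(tss_central_t=contrast.t_statistic, tss_central_p=contrast.p_value)

    if config.expression is not None:
        expr = io.read_expression(config.expression)
        joined = association.join_and_filter(gene_meth, expr)
        comparisons = [
            association.mean_split_comparison(joined, split_on=s) for s in ("fpkm", "density")
        ]
        _write(pd.DataFrame([asdict(c) for c in comparisons]), out / "expression_association.tsv",
               "mean-split t tests (high vs low)")
        results["expression_comparisons"] = comparisons
        manifest["n_genes_joined"] = len(joined)
    else:
        logger.info("no expression table given: association stage skipped")

    if config.go_map is not None:
        go_map = pd.read_csv(config.go_map, sep="\t")
        enr_go = association.go_enrichment(gene_meth, go_map)
        _write(enr_go, out / "go_enrichment.tsv", "per-class GO over-representation (BH within class)")
        results["go_enrichment"] = enr_go
    else:
        logger.info("no GO map given: GO stage skipped")

    with open(out / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}={v}\n")
    return results
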