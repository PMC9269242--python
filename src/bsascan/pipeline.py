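"""End-to-end orchestration: simulate -> index/filter -> scan -> regions ->
effects -> gene priority -> enrichment -> haplotype.

Each stage writes its table under the output directory and logs counts, so
a run leaves a summary trail of variants in, variants filtered per rule,
windows, regions and ranked genes.  A single seed governs every stochastic
stage.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import bsa_index, candidate_genes, consequence, enrichment, synthetic_data, variant_io, window_scan
from .bsa_index import FilterConfig, FilterReport, IndexedVariant
from .synthetic_data import SimulationConfig, ToyGenome
from .window_scan import CandidateRegion, ScanConfig, WindowStat

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "simulate_inputs",
    "qc_rates",
    "effective_rate",
    "mapping_rate",
    "effects_to_frame",
]

log = logging.getLogger("bsascan")


def effective_rate(raw_bases: int, clean_bases: int) -> float:
    """Percentage of raw bases surviving read cleaning, 2 dp."""
    if raw_bases <= 0:
        raise ZeroDivisionError("raw base count must be positive")
    return round(100.0 * clean_bases / raw_bases, 2)


def mapping_rate(mapped_reads: int, total_reads: int) -> float:
    """Percentage of reads mapped to the reference, 2 dp."""
    if total_reads <= 0:
        raise ZeroDivisionError("total read count must be positive")
    return round(100.0 * mapped_reads / total_reads, 2)


def qc_rates(
    raw_bases: int | None = None,
    clean_bases: int | None = None,
    mapped_reads: int | None = None,
    total_reads: int | None = None,
) -> tuple[float | None, float | None]:
    """(effective %, mapping %) from whichever count pairs are supplied."""
    eff = effective_rate(raw_bases, clean_bases) if raw_bases is not None and clean_bases is not None else None
    mapped = mapping_rate(mapped_reads, total_reads) if mapped_reads is not None and total_reads is not None else None
    return eff, mapped


@dataclass
class PipelineConfig:
    """Composed configuration for a full run; one seed drives all stages."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    outdir: str = "bsascan_out"
    seed: int = 0
    high_sample_name: str = "VE-High"
    low_sample_name: str = "VE-Low"
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.get("simulation", {}))
        filt = FilterConfig(**raw.get("filters", {}))
        scan = ScanConfig(**raw.get("scan", {}))
        top = {k: v for k, v in raw.items() if k not in {"simulation", "filters", "scan"}}
        return cls(simulation=sim, filters=filt, scan=scan, **top)


@dataclass
class PipelineResult:
    """Bundle of everything a full run produces."""

    variants: list
    indexed: list[IndexedVariant]
    filter_report: FilterReport
    snp_windows: list[WindowStat]
    indel_windows: list[WindowStat]
    regions: list[CandidateRegion]
    effects: list
    priorities: list
    enrichment: list
    haplotype: object | None
    toy_genome: ToyGenome | None
    truth: pd.DataFrame | None
    outdir: str


def simulate_inputs(config: PipelineConfig) -> tuple[ToyGenome, synthetic_data.SyntheticCohort, pd.DataFrame, str]:
    """Stage 1: emit the toy genome and pooled VCF plus side tables."""
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rngs = [np.random.default_rng(s) for s in seeds]

    sim = config.simulation
    toy = synthetic_data.emit_toy_genome(sim, outdir, rng=rngs[0])
    chrom, pos, ref, alt = toy.causal_site
    effects = {c: e for c, _, e in sim.causal_sites}
    sim = dataclasses.replace(
        sim, causal_sites=((chrom, pos, effects.get(chrom, 40.0)),)
    )
    cohort = synthetic_data.simulate_cohort(sim, rng=rngs[1])
    pools = synthetic_data.select_pools(cohort, n_pool=sim.n_pool)
    variants, truth = synthetic_data.simulate_pooled_reads(
        cohort, pools, sim, rng=rngs[2], genome=toy.genome,
        site_alleles={(chrom, pos): (ref, alt)},
    )
    vcf_path = os.path.join(outdir, "pools.vcf")
    synthetic_data.write_pooled_vcf(
        variants, vcf_path, synthetic_data.chrom_lengths(sim),
        config.high_sample_name, config.low_sample_name,
    )
    truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    pheno = synthetic_data.cohort_phenotype_table(cohort, chrom, pos)
    pheno.to_csv(os.path.join(outdir, "phenotypes.tsv"), sep="\t", index=False)
    log.info("simulated %d accessions, %d sites -> %s", cohort.n_accessions, len(truth), vcf_path)
    return toy, cohort, truth, vcf_path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage on freshly simulated inputs."""
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    toy, cohort, truth, vcf_path = simulate_inputs(config)
    chrom, pos, _, _ = toy.causal_site

    # --- index & filter ---------------------------------------------------
    variants = variant_io.read_pooled_vcf(
        vcf_path, config.high_sample_name, config.low_sample_name
    )
    indexed, report = bsa_index.apply_filters(variants, config.filters)
    bsa_index.indexed_to_frame(indexed).to_csv(
        os.path.join(outdir, "indexed_variants.tsv"), sep="\t", index=False
    )
    pd.Series(report.as_dict()).to_csv(os.path.join(outdir, "filter_report.tsv"), sep="\t", header=False)
    log.info("filters: %s", report.as_dict())

    # --- windows & regions ------------------------------------------------
    scan_cfg = config.scan
    rng_scan = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[4])
    windows = window_scan.make_windows(synthetic_data.chrom_lengths(config.simulation), scan_cfg)
    snp_windows = window_scan.scan_track(windows, indexed, "SNP", scan_cfg, rng=rng_scan)
    indel_windows = window_scan.scan_track(windows, indexed, "InDel", scan_cfg, rng=rng_scan)
    window_scan.windows_to_frame(snp_windows).to_csv(
        os.path.join(outdir, "windows_snp.tsv"), sep="\t", index=False
    )
    window_scan.windows_to_frame(indel_windows).to_csv(
        os.path.join(outdir, "windows_indel.tsv"), sep="\t", index=False
    )
    regions = window_scan.call_regions(snp_windows, indel_windows, toy.genes, scan_cfg)
    variant_io.write_regions_bed(regions, os.path.join(outdir, "candidate_regions.bed"))
    log.info("%d candidate region(s)", len(regions))

    # --- effects within regions -------------------------------------------
    effects: list = []
    for iv in indexed:
        for r in regions:
            if iv.chrom == r.chrom and r.start <= iv.pos <= r.end and iv.chrom in toy.genome:
                effects.append((iv.variant, consequence.classify_variant(iv.variant, toy.genes, toy.genome)))
                break
    effects_to_frame(effects).to_csv(os.path.join(outdir, "region_effects.tsv"), sep="\t", index=False)

    priorities = candidate_genes.prioritize_genes(regions, effects, toy.genes)
    pd.DataFrame(
        [(p.gene_id, p.rank_class, p.region.chrom, p.region.start, p.region.end) for p in priorities],
        columns=["gene_id", "rank_class", "chrom", "region_start", "region_end"],
    ).to_csv(os.path.join(outdir, "gene_priorities.tsv"), sep="\t", index=False)

    # --- enrichment ---------------------------------------------------------
    annotation = variant_io.read_annotation_table(toy.go_path)
    study = sorted({g for r in regions for g in r.genes})
    enr = enrichment.enrich(study, annotation) if study else []
    enrichment.enrichment_to_frame(enr).to_csv(
        os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False
    )

    # --- haplotype ----------------------------------------------------------
    pheno = synthetic_data.cohort_phenotype_table(cohort, chrom, pos)
    hap = candidate_genes.haplotype_compare(pheno, site=f"{chrom}:{pos}")
    hap.per_environment.to_csv(os.path.join(outdir, "haplotype.tsv"), sep="\t", index=False)

    if config.make_plots:
        from .plotting import plot_delta_tracks

        plot_delta_tracks(
            snp_windows, indel_windows, regions, scan_cfg,
            os.path.join(outdir, "delta_scan.png"),
        )

    return PipelineResult(
        variants=variants, indexed=indexed, filter_report=report,
        snp_windows=snp_windows, indel_windows=indel_windows, regions=regions,
        effects=effects, priorities=priorities, enrichment=enr, haplotype=hap,
        toy_genome=toy, truth=truth, outdir=outdir,
    )


def effects_to_frame(
    pairs: list, ortholog_map: Mapping[str, tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Effect table in report column order; ortholog/description columns are
    pass-through annotations from a user-supplied mapping."""
    rows = []
    for variant, effect in pairs:
        gene = effect.gene_ids[0] if effect.gene_ids else ""
        ortho, desc = (ortholog_map or {}).get(gene, ("-", "-"))
        label = effect.exonic_subtype if effect.category == "exonic" else effect.category
        rows.append(
            (variant.pos, variant.chrom, variant.ref_allele, variant.alt_allele,
             label, gene, ortho, desc)
        )
    return pd.DataFrame(
        rows,
        columns=["Position", "Chromosome", "Ref", "Alt", "Effect", "Gene ID",
                 "Ortholog", "Description"],
    )
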