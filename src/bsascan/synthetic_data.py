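"""Synthetic inputs with the statistical structure the scan assumes.

The generator emulates an extreme-pool resequencing design on a natural
population: ``n_accessions`` unrelated diploid accessions genotyped at
independent biallelic sites (Hardy-Weinberg at site-wise allele
frequencies), a quantitative phenotype driven by one or more additive
causal loci plus location-year offsets and Gaussian noise, selection of
the top and bottom ``n_pool`` accessions into two DNA pools, and pooled
short-read counts at each site (Poisson depth, binomial allele sampling
with a symmetric sequencing-error rate).

An optional block-LD mode copies the causal genotype into flanking sites
with a probability decaying in distance, so the Δ(index) peak has
realistic width; without linkage a single marker would carry the whole
signal.  ``emit_toy_genome`` additionally writes a FASTA/GFF3/GO-table
trio with a designated candidate region hosting six genes, one of which
carries a designed non-synonymous variant — the substrate for consequence
classification, gene prioritization and enrichment downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import GeneModel, PooledVariant

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "ToyGenome",
    "simulate_cohort",
    "select_pools",
    "simulate_pooled_reads",
    "write_pooled_vcf",
    "emit_toy_genome",
    "cohort_phenotype_table",
    "chrom_lengths",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated design: 1525 accessions, two pools of 49,
    20 chromosomes, ~40x pooled depth.  The single default causal site has
    an additive effect of 40 ug/g at ALT frequency 0.4 against residual
    noise sigma_e = 35 ug/g, i.e. a per-environment heritability of ~0.38;
    averaging over the five location-year environments is what makes the
    extreme pools nearly fix for opposite alleles.
    """

    n_accessions: int = 1525
    n_pool: int = 49
    n_chromosomes: int = 20
    chrom_length: int = 10_000_000
    n_variants: int = 20_000
    indel_fraction: float = 0.15
    multiallelic_fraction: float = 0.01
    causal_sites: tuple[tuple[str, int, float], ...] = (("Chr05", 4_185_000, 40.0),)
    causal_alt_freq: float = 0.4
    mu: float = 230.0
    sigma_e: float = 35.0
    environments: tuple[str, ...] = ("A17", "B17", "B18", "H17", "H18")
    env_offset_sd: float = 10.0
    cultivar_fraction: float = 0.5
    freq_low: float = 0.05
    freq_high: float = 0.5
    mean_depth: float = 40.0
    seq_error: float = 0.001
    ld_mode: bool = True
    ld_scale: float = 2_500_000.0
    ld_max_dist: float = 6_000_000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.n_pool > self.n_accessions:
            raise ValueError("2 * n_pool must not exceed n_accessions")
        for p in (self.indel_fraction, self.multiallelic_fraction,
                  self.causal_alt_freq, self.cultivar_fraction, self.seq_error):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 < self.freq_low <= self.freq_high < 1:
            raise ValueError("allele-frequency law bounds must satisfy 0 < low <= high < 1")

    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1:02d}" for i in range(self.n_chromosomes)]


def chrom_lengths(config: SimulationConfig) -> dict[str, int]:
    return {c: config.chrom_length for c in config.chrom_names()}


@dataclass
class SyntheticCohort:
    """Simulated accessions: labels, genotype dosages and phenotypes."""

    accession_ids: np.ndarray          # (n_acc,) str
    accession_types: np.ndarray        # (n_acc,) "cultivar" | "landrace"
    sites: pd.DataFrame                # chrom, pos, vclass, alt_freq, is_causal, effect, ld_r, multiallelic
    genotypes: np.ndarray              # (n_acc, n_sites) int8 ALT dosage 0/1/2
    phenotypes: np.ndarray             # (n_acc, n_env) float
    environments: tuple[str, ...]
    env_offsets: np.ndarray

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def site_index(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero(
            (self.sites["chrom"].to_numpy() == chrom) & (self.sites["pos"].to_numpy() == pos)
        )
        if hit.size == 0:
            raise KeyError(f"no simulated site at {chrom}:{pos}")
        return int(hit[0])


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SyntheticCohort:
    """Draw the population: genotypes under Hardy-Weinberg, phenotypes
    additive in causal dosage plus environment offset and Gaussian noise."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    chroms = config.chrom_names()
    per_chrom = max(1, config.n_variants // config.n_chromosomes)

    causal_by_chrom: dict[str, list[tuple[int, float]]] = {}
    for chrom, pos, eff in config.causal_sites:
        if chrom not in chroms:
            raise ValueError(f"causal chromosome {chrom!r} outside the genome")
        causal_by_chrom.setdefault(chrom, []).append((pos, eff))

    rows = []
    for chrom in chroms:
        pos = np.unique(rng.integers(1, config.chrom_length + 1, size=int(per_chrom * 1.02) + 8))
        while pos.size < per_chrom:  # top up rare collisions
            extra = rng.integers(1, config.chrom_length + 1, size=per_chrom)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = rng.permutation(pos)[:per_chrom]
        causal_pos = {p for p, _ in causal_by_chrom.get(chrom, [])}
        pos = np.setdiff1d(pos, np.fromiter(causal_pos, dtype=np.int64, count=len(causal_pos)))
        for p in np.sort(pos):
            rows.append((chrom, int(p), False, 0.0))
        for p, eff in sorted(causal_by_chrom.get(chrom, [])):
            rows.append((chrom, int(p), True, eff))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "is_causal", "effect"])
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    n_sites = len(sites)

    freqs = rng.uniform(config.freq_low, config.freq_high, size=n_sites)
    causal_mask = sites["is_causal"].to_numpy()
    freqs[causal_mask] = config.causal_alt_freq

    vclass = np.where(rng.random(n_sites) < config.indel_fraction, "InDel", "SNP")
    vclass[causal_mask] = "SNP"
    multi = rng.random(n_sites) < config.multiallelic_fraction
    multi[causal_mask] = False

    # diploid Hardy-Weinberg dosage via one uniform draw against the
    # cumulative Binomial(2, p) thresholds: P(2)=p^2, P(>=1)=2p-p^2
    f32 = freqs.astype(np.float32)
    t_two = (f32 * f32)[None, :]
    t_one = (2 * f32 - f32 * f32)[None, :]
    u = rng.random((config.n_accessions, n_sites), dtype=np.float32)
    genotypes = (u < t_two).astype(np.int8) + (u < t_one).astype(np.int8)
    del u

    ld_r = np.zeros(n_sites)
    ld_r[causal_mask] = 1.0
    if config.ld_mode:
        chrom_arr = sites["chrom"].to_numpy()
        pos_arr = sites["pos"].to_numpy()
        for ci in np.flatnonzero(causal_mask):
            same = (chrom_arr == sites.at[ci, "chrom"]) & ~causal_mask
            dist = np.abs(pos_arr - sites.at[ci, "pos"])
            block = same & (dist <= config.ld_max_dist)
            cols = np.flatnonzero(block)
            if cols.size == 0:
                continue
            r = np.exp(-((dist[cols] / config.ld_scale) ** 2))
            copy = rng.random((config.n_accessions, cols.size)) < r[None, :]
            sub = genotypes[:, cols]
            sub[copy] = np.broadcast_to(
                genotypes[:, ci][:, None], sub.shape
            )[copy]
            genotypes[:, cols] = sub
            ld_r[cols] = np.maximum(ld_r[cols], r)

    sites["vclass"] = vclass
    sites["alt_freq"] = freqs
    sites["ld_r"] = ld_r
    sites["multiallelic"] = multi

    effects = sites["effect"].to_numpy()
    genetic = genotypes[:, causal_mask].astype(float) @ effects[causal_mask]
    env_offsets = rng.normal(0.0, config.env_offset_sd, size=len(config.environments))
    noise = rng.normal(0.0, config.sigma_e, size=(config.n_accessions, len(config.environments)))
    phenotypes = config.mu + env_offsets[None, :] + genetic[:, None] + noise

    ids = np.array([f"ACC{i + 1:05d}" for i in range(config.n_accessions)])
    types = np.where(
        rng.random(config.n_accessions) < config.cultivar_fraction, "cultivar", "landrace"
    )
    return SyntheticCohort(
        accession_ids=ids, accession_types=types, sites=sites,
        genotypes=genotypes, phenotypes=phenotypes,
        environments=tuple(config.environments), env_offsets=env_offsets,
    )


def select_pools(
    cohort: SyntheticCohort,
    environment: str | None = None,
    n_pool: int = 49,
) -> tuple[list[str], list[str]]:
    """Top-n and bottom-n accessions by phenotype (mean across environments
    by default, a single environment when named); ties break by id."""
    if 2 * n_pool > cohort.n_accessions:
        raise ValueError("pools would overlap: 2 * n_pool > n_accessions")
    if environment is None:
        values = cohort.phenotypes.mean(axis=1)
    else:
        values = cohort.phenotypes[:, cohort.environments.index(environment)]
    order = np.lexsort((cohort.accession_ids, values))
    low = [str(cohort.accession_ids[i]) for i in order[:n_pool]]
    high = [str(cohort.accession_ids[i]) for i in order[::-1][:n_pool]]
    return high, low


def simulate_pooled_reads(
    cohort: SyntheticCohort,
    pools: tuple[Sequence[str], Sequence[str]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    genome: Mapping[str, str] | None = None,
    site_alleles: Mapping[tuple[str, int], tuple[str, str]] | None = None,
) -> tuple[list[PooledVariant], pd.DataFrame]:
    """Draw pooled read counts per site per pool.

    Pool ALT frequency q is the mean dosage / 2 over the pool's members;
    depth ~ Poisson(mean_depth); ALT reads ~ Binomial(depth, q(1-e)+(1-q)e)
    with sequencing-error rate e.  REF alleles are taken from ``genome``
    when the chromosome is present (random otherwise); designated alleles
    can be forced via ``site_alleles``.  Returns the variants plus a truth
    table with the per-pool frequencies and causal/LD flags.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 1)
    high_ids, low_ids = pools
    if set(high_ids) & set(low_ids):
        raise ValueError("pools must be disjoint")
    idx = {str(a): i for i, a in enumerate(cohort.accession_ids)}
    hi = np.array([idx[str(a)] for a in high_ids])
    lo = np.array([idx[str(a)] for a in low_ids])

    n_sites = len(cohort.sites)
    q_high = cohort.genotypes[hi].mean(axis=0) / 2.0
    q_low = cohort.genotypes[lo].mean(axis=0) / 2.0
    eps = config.seq_error

    depth_h = rng.poisson(config.mean_depth, size=n_sites)
    depth_l = rng.poisson(config.mean_depth, size=n_sites)
    alt_h = rng.binomial(depth_h, q_high * (1 - eps) + (1 - q_high) * eps)
    alt_l = rng.binomial(depth_l, q_low * (1 - eps) + (1 - q_low) * eps)

    variants: list[PooledVariant] = []
    truth_rows = []
    chrom_arr = cohort.sites["chrom"].to_numpy()
    pos_arr = cohort.sites["pos"].to_numpy()
    class_arr = cohort.sites["vclass"].to_numpy()
    multi_arr = cohort.sites["multiallelic"].to_numpy()
    causal_arr = cohort.sites["is_causal"].to_numpy()
    ld_arr = cohort.sites["ld_r"].to_numpy()

    # pre-drawn allele randomness so the per-site loop stays cheap
    base_draw = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    is_insertion = rng.random(n_sites) < 0.5
    extra_len = rng.integers(1, 4, size=n_sites)
    extra_draw = rng.integers(0, 4, size=(n_sites, 3))
    bases = "ACGT"

    for i in range(n_sites):
        chrom, pos = str(chrom_arr[i]), int(pos_arr[i])
        forced = site_alleles.get((chrom, pos)) if site_alleles else None
        if forced is not None:
            ref, alt = forced
        else:
            in_genome = genome is not None and chrom in genome
            base = str(genome[chrom][pos - 1]).upper() if in_genome else bases[base_draw[i]]
            if class_arr[i] == "SNP":
                ref = base
                alt = bases[(bases.index(base) + alt_shift[i]) % 4]
            else:
                extra = "".join(bases[b] for b in extra_draw[i, : extra_len[i]])
                if is_insertion[i]:
                    ref, alt = base, base + extra
                else:
                    if in_genome:
                        tail = str(genome[chrom][pos:pos + len(extra)]).upper()
                        extra = tail if len(tail) == len(extra) else extra
                    ref, alt = base + extra, base
        variants.append(
            PooledVariant(
                chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                ad_high=(int(depth_h[i] - alt_h[i]), int(alt_h[i])),
                ad_low=(int(depth_l[i] - alt_l[i]), int(alt_l[i])),
                multiallelic=bool(multi_arr[i]),
            )
        )
        truth_rows.append(
            (chrom, pos, class_arr[i], float(q_high[i]), float(q_low[i]),
             float(q_high[i] - q_low[i]), bool(causal_arr[i]), float(ld_arr[i]))
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "vclass", "q_high", "q_low", "delta_true",
                 "is_causal", "ld_r"],
    )
    return variants, truth


def write_pooled_vcf(
    variants: Sequence[PooledVariant],
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int],
    high_sample_name: str = "VE-High",
    low_sample_name: str = "VE-Low",
) -> None:
    """Write a two-sample VCF 4.2 with per-sample FORMAT/AD depths.

    Flagged multi-allelic sites are emitted with a second ALT allele
    carrying one supporting read, so a reader sees a genuinely
    multi-allelic record.
    """
    import pysam

    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(high_sample_name)
    header.add_sample(low_sample_name)

    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            alleles = [v.ref_allele, v.alt_allele]
            if v.multiallelic:
                second = _second_alt(v)
                alleles.append(second)
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=tuple(alleles)
            )
            if v.multiallelic:
                rec.samples[high_sample_name]["AD"] = (v.ad_high[0], v.ad_high[1], 1)
                rec.samples[low_sample_name]["AD"] = (v.ad_low[0], v.ad_low[1], 1)
            else:
                rec.samples[high_sample_name]["AD"] = v.ad_high
                rec.samples[low_sample_name]["AD"] = v.ad_low
            out.write(rec)


def _second_alt(v: PooledVariant) -> str:
    for b in "ACGT":
        if b != v.ref_allele[0] and b != v.alt_allele[0]:
            cand = b + v.ref_allele[1:] if len(v.ref_allele) > 1 else b
            if cand not in (v.ref_allele, v.alt_allele):
                return cand
    raise AssertionError("unreachable")


@dataclass
class ToyGenome:
    """Emitted toy genome bundle: sequences, gene models and GO table."""

    fasta_path: str
    gff3_path: str
    go_path: str
    genome: dict[str, str]
    genes: list[GeneModel]
    causal_site: tuple[str, int, str, str]      # chrom, pos, ref, alt
    hotspot: tuple[str, int, int]
    enriched_term: str


_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE: dict[str, str] = {}


def _aa(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    c = b1 + b2 + b3
                    _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE[codon]


def emit_toy_genome(
    config: SimulationConfig,
    outdir: str | os.PathLike,
    rng: np.random.Generator | None = None,
    n_background_genes: int = 24,
) -> ToyGenome:
    """Write FASTA + GFF3 + GO TSV for the causal chromosome.

    A 10 kb designated candidate region centred on the (first) causal site
    hosts exactly six two-exon genes; one of them receives the causal
    variant at a CDS position chosen so the substitution is
    non-synonymous.  Background genes are scattered along the rest of the
    chromosome, and the GO table makes the region's genes enriched for one
    designated term against a synthetic genome-wide background.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 2)
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    chrom, anchor, _ = config.causal_sites[0]
    length = config.chrom_length
    seq_arr = rng.integers(0, 4, size=length)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[seq_arr].tobytes().decode("ascii")

    hotspot = (chrom, anchor - 5_000 + 1, anchor + 5_000)

    genes: list[GeneModel] = []
    gene_lines: list[str] = []

    def add_gene(gid: str, s: int, strand: str) -> GeneModel:
        cds1 = (s, s + 599)
        cds2 = (s + 900, s + 1499)
        model = GeneModel(
            gene_id=gid, chrom=chrom, strand=strand, tx_start=s, tx_end=s + 1499,
            cds_intervals=(cds1, cds2), phase=0, transcript_id=f"{gid}.1",
        )
        genes.append(model)
        gene_lines.append(f"{chrom}\ttoy\tgene\t{s}\t{s + 1499}\t.\t{strand}\t.\tID={gid}")
        gene_lines.append(
            f"{chrom}\ttoy\tmRNA\t{s}\t{s + 1499}\t.\t{strand}\t.\tID={gid}.1;Parent={gid}"
        )
        for cs, ce in (cds1, cds2):
            gene_lines.append(
                f"{chrom}\ttoy\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\tID=cds_{gid};Parent={gid}.1"
            )
        return model

    region_genes = []
    for i in range(6):
        s = hotspot[1] + 100 + i * 1_650
        gid = f"TOY.{chrom}G{i + 1:04d}"
        region_genes.append(add_gene(gid, s, "+" if i % 2 == 0 else "-"))

    occupied = [(g.tx_start - 30_000, g.tx_end + 30_000) for g in region_genes]
    placed = 0
    while placed < n_background_genes:
        s = int(rng.integers(10_000, length - 10_000))
        if any(a <= s + 1499 and s <= b for a, b in occupied):
            continue
        gid = f"TOY.{chrom}B{placed + 1:04d}"
        add_gene(gid, s, "+" if rng.random() < 0.5 else "-")
        occupied.append((s - 2_000, s + 3_500))
        placed += 1

    causal_gene = region_genes[2]
    causal_pos = ref = alt = None
    cds_positions = [p for s, e in causal_gene.cds_intervals for p in range(s, e + 1)]
    # walk codons until a clean non-synonymous single-base change is found
    for codon_i in range(len(cds_positions) // 3):
        gpos = cds_positions[3 * codon_i:3 * codon_i + 3]
        codon = "".join(seq[p - 1] for p in gpos)  # + strand gene
        if _aa(codon) == "*":
            continue
        p_mid = gpos[1]
        base = seq[p_mid - 1]
        for cand in "ACGT":
            if cand == base:
                continue
            mut = codon[0] + cand + codon[2]
            if _aa(mut) != _aa(codon) and _aa(mut) != "*":
                causal_pos, ref, alt = p_mid, base, cand
                break
        if causal_pos is not None:
            break
    assert causal_pos is not None and ref is not None and alt is not None

    fasta_path = os.path.join(outdir, "toy_genome.fa")
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, length, 60):
            fh.write(seq[i:i + 60] + "\n")

    gff3_path = os.path.join(outdir, "toy_genes.gff3")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom} 1 {length}\n")
        fh.write("\n".join(gene_lines) + "\n")

    enriched_term = "GO:9000001"
    terms = {
        enriched_term: ("BP", "response to designated stimulus (synthetic)"),
        "GO:9000002": ("BP", "synthetic housekeeping process"),
        "GO:9000003": ("BP", "synthetic stress response"),
        "GO:9000004": ("MF", "synthetic binding activity"),
        "GO:9000005": ("MF", "synthetic transporter activity"),
    }
    go_rows: list[tuple[str, str, str, str]] = []
    for g in region_genes[:5]:
        ont, name = terms[enriched_term]
        go_rows.append((g.gene_id, enriched_term, ont, name))
    other_terms = [t for t in terms if t != enriched_term]
    for g in genes:
        t = other_terms[int(rng.integers(0, len(other_terms)))]
        ont, name = terms[t]
        go_rows.append((g.gene_id, t, ont, name))
    n_bg = 2_000
    for i in range(n_bg):
        gid = f"BG{i + 1:05d}"
        if rng.random() < 0.01:
            t = enriched_term
        else:
            t = other_terms[int(rng.integers(0, len(other_terms)))]
        ont, name = terms[t]
        go_rows.append((gid, t, ont, name))

    go_path = os.path.join(outdir, "toy_go.tsv")
    pd.DataFrame(go_rows, columns=["gene_id", "go_id", "ontology", "term"]).to_csv(
        go_path, sep="\t", index=False
    )

    return ToyGenome(
        fasta_path=fasta_path, gff3_path=gff3_path, go_path=go_path,
        genome={chrom: seq}, genes=genes,
        causal_site=(chrom, int(causal_pos), ref, alt),
        hotspot=hotspot, enriched_term=enriched_term,
    )


def cohort_phenotype_table(
    cohort: SyntheticCohort, chrom: str, pos: int
) -> pd.DataFrame:
    """Long-format phenotype table with the allele call at one site.

    Diploid dosage is scored REF (0), het (1) or ALT (2); the haplotype
    comparison excludes het by default.
    """
    j = cohort.site_index(chrom, pos)
    call = np.array(["REF", "het", "ALT"])[cohort.genotypes[:, j]]
    frames = []
    for e, env in enumerate(cohort.environments):
        frames.append(
            pd.DataFrame(
                {
                    "accession_id": cohort.accession_ids,
                    "accession_type": cohort.accession_types,
                    "environment": env,
                    "phenotype": cohort.phenotypes[:, e],
                    "allele": call,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
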