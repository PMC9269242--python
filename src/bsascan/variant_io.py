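"""Readers and writers for the standard formats the scan touches.

External coordinates follow the source standards exactly: VCF and GFF3 are
1-based inclusive, BED is 0-based half-open (conversion happens only at BED
emission). Variants are read into :class:`PooledVariant`, the atom of the
index scan: one biallelic site with REF/ALT read depths in each of the two
extreme pools.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PooledVariant",
    "GeneModel",
    "AnnotationTable",
    "read_pooled_vcf",
    "read_gene_models",
    "read_annotation_table",
    "read_phenotype_table",
    "write_regions_bed",
    "variants_to_frame",
    "write_variant_table",
    "read_variant_table",
]

_BASES = frozenset("ACGT")


def _vclass(ref: str, alt: str) -> str:
    return "SNP" if len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES else "InDel"


@dataclass(frozen=True)
class PooledVariant:
    """One biallelic site with per-pool allele depths.

    ``ad_high`` / ``ad_low`` are ``(ref_reads, alt_reads)`` for the
    high-phenotype and low-phenotype pool respectively.  ``multiallelic``
    marks records that carried more than one ALT allele in the source VCF;
    they are kept (with the first ALT) so the filter stage can count them.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ad_high: tuple[int, int]
    ad_low: tuple[int, int]
    vclass: str = field(default="")
    multiallelic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos} REF equals ALT ({self.ref_allele})")
        if min(*self.ad_high, *self.ad_low) < 0:
            raise ValueError(f"{self.chrom}:{self.pos} negative read count")
        expected = _vclass(self.ref_allele, self.alt_allele)
        if not self.vclass:
            object.__setattr__(self, "vclass", expected)
        elif self.vclass != expected:
            raise ValueError(
                f"{self.chrom}:{self.pos} vclass {self.vclass!r} inconsistent with "
                f"alleles {self.ref_allele}>{self.alt_allele}"
            )

    @property
    def depth_high(self) -> int:
        return self.ad_high[0] + self.ad_high[1]

    @property
    def depth_low(self) -> int:
        return self.ad_low[0] + self.ad_low[1]


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene model: transcription bounds plus ordered CDS intervals.

    Coordinates are 1-based inclusive.  ``cds_intervals`` are stored in
    ascending genomic order regardless of strand; ``phase`` is the phase of
    the first coding base (first in translation order).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_intervals: tuple[tuple[int, int], ...]
    phase: int = 0
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.tx_start < 1 or self.tx_end < self.tx_start:
            raise ValueError(f"{self.gene_id}: bad transcription bounds")
        ivs = self.cds_intervals
        if not ivs:
            raise ValueError(f"{self.gene_id}: no CDS intervals")
        prev_end = 0
        for s, e in ivs:
            if s > e:
                raise ValueError(f"{self.gene_id}: CDS interval ({s},{e}) reversed")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap or unsorted")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: CDS outside transcription bounds")
            prev_end = e
        if self.cds_length < 3:
            raise ValueError(f"{self.gene_id}: total CDS length < 3")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"{self.gene_id}: phase must be 0, 1 or 2")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def overlaps(self, start: int, end: int) -> bool:
        return start <= self.tx_end and end >= self.tx_start


class AnnotationTable:
    """gene_id -> GO-term mapping with per-ontology background sizes.

    The background size of an ontology defaults to the number of annotated
    genes carrying at least one term of that ontology; explicit sizes can be
    supplied when the true background is larger than the table (e.g. a
    genome-wide annotation of which only a slice is loaded).
    """

    def __init__(
        self,
        gene_terms: Mapping[str, set[str]],
        term_names: Mapping[str, str] | None = None,
        term_ontology: Mapping[str, str] | None = None,
        background_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.gene_terms = {g: set(ts) for g, ts in gene_terms.items()}
        self.term_genes: dict[str, set[str]] = {}
        for g, ts in self.gene_terms.items():
            for t in ts:
                self.term_genes.setdefault(t, set()).add(g)
        self.term_names = dict(term_names or {})
        self.term_ontology = dict(term_ontology or {})
        self._background_sizes = dict(background_sizes or {})
        for ont, size in self._background_sizes.items():
            biggest = max(
                (len(gs) for t, gs in self.term_genes.items() if self.term_ontology.get(t) == ont),
                default=0,
            )
            if size < biggest:
                raise ValueError(f"background size {size} for {ont!r} smaller than a term's gene count")

    def background_size(self, ontology: str | None = None) -> int:
        if ontology is not None and ontology in self._background_sizes:
            return self._background_sizes[ontology]
        if ontology is None:
            if self._background_sizes:
                return max(self._background_sizes.values())
            return len(self.gene_terms)
        genes = {
            g
            for t, gs in self.term_genes.items()
            if self.term_ontology.get(t) == ontology
            for g in gs
        }
        return len(genes)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_terms)


def read_pooled_vcf(
    path: str | os.PathLike,
    high_sample_name: str = "VE-High",
    low_sample_name: str = "VE-Low",
) -> list[PooledVariant]:
    """Read a two-pool VCF into :class:`PooledVariant` records.

    Requires per-sample allele depths (FORMAT/AD).  Multi-allelic records
    are returned flagged (first ALT kept), not dropped, so the filter stage
    can report them.  Output is (chrom, pos) sorted.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    for name in (high_sample_name, low_sample_name):
        if name not in samples:
            raise ValueError(
                f"sample {name!r} not found in {path} (samples: {samples})"
            )
    hi = samples.index(high_sample_name)
    lo = samples.index(low_sample_name)

    out: list[PooledVariant] = []
    for rec in vcf:
        if not rec.ALT:
            continue
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(f"{rec.CHROM}:{rec.POS}: record has no FORMAT/AD field")
        multi = len(rec.ALT) > 1
        ad_high = (max(int(ad[hi][0]), 0), max(int(ad[hi][1]), 0))
        ad_low = (max(int(ad[lo][0]), 0), max(int(ad[lo][1]), 0))
        out.append(
            PooledVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                ad_high=ad_high,
                ad_low=ad_low,
                multiallelic=multi,
            )
        )
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


def read_gene_models(gff3_path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GFF3 into one :class:`GeneModel` per mRNA.

    The gene_id is the mRNA's parent gene ID when present, otherwise the
    mRNA's own ID.  A CDS feature without a parent mRNA is a fatal parse
    error.
    """
    import gffutils

    db = gffutils.create_db(
        os.fspath(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            raise ValueError(
                f"CDS at {cds.seqid}:{cds.start}-{cds.end} has no parent mRNA"
            )

    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else mrna.id
        first = cds[0] if mrna.strand == "+" else cds[-1]
        try:
            phase = int(first.frame)
        except (TypeError, ValueError):
            phase = 0
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                tx_start=mrna.start,
                tx_end=mrna.end,
                cds_intervals=tuple((f.start, f.end) for f in cds),
                phase=phase,
                transcript_id=mrna.id,
            )
        )
    models.sort(key=lambda g: (g.chrom, g.tx_start))
    return models


def read_annotation_table(path: str | os.PathLike, background_sizes: Mapping[str, int] | None = None) -> AnnotationTable:
    """Read a gene->GO TSV with columns gene_id, go_id, ontology, term."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "go_id"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    gene_terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    onts: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gene_terms.setdefault(row.gene_id, set()).add(row.go_id)
        if hasattr(row, "term") and isinstance(row.term, str):
            names[row.go_id] = row.term
        if hasattr(row, "ontology") and isinstance(row.ontology, str):
            onts[row.go_id] = row.ontology
    return AnnotationTable(gene_terms, names, onts, background_sizes)


def read_phenotype_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the accession phenotype table used for haplotype comparison.

    Columns: accession_id, accession_type, environment, phenotype, allele
    (allele in {REF, ALT, het, missing}).  Phenotypes must be finite and
    (accession, environment) pairs unique.
    """
    df = pd.read_csv(path, sep="\t", dtype={"accession_id": str})
    required = {"accession_id", "accession_type", "environment", "phenotype", "allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    if not pd.to_numeric(df["phenotype"], errors="coerce").notna().all():
        raise ValueError("phenotype column contains non-finite values")
    if df.duplicated(["accession_id", "environment"]).any():
        raise ValueError("duplicate accession x environment rows")
    return df


def write_regions_bed(regions: Iterable, path: str | os.PathLike) -> None:
    """Write regions as BED3: internal 1-based inclusive [s, e] -> (s-1, e)."""
    with open(path, "w") as fh:
        for r in regions:
            chrom, start, end = r.chrom, r.start, r.end
            if end < start:
                raise ValueError(f"{chrom}: region end {end} < start {start}")
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


_VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vclass", "multiallelic",
    "ref_reads_high", "alt_reads_high", "ref_reads_low", "alt_reads_low",
]


def variants_to_frame(variants: Sequence[PooledVariant]) -> pd.DataFrame:
    rows = [
        (v.chrom, v.pos, v.ref_allele, v.alt_allele, v.vclass, v.multiallelic,
         v.ad_high[0], v.ad_high[1], v.ad_low[0], v.ad_low[1])
        for v in variants
    ]
    return pd.DataFrame(rows, columns=_VARIANT_COLUMNS)


def write_variant_table(variants: Sequence[PooledVariant], path: str | os.PathLike) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | os.PathLike) -> list[PooledVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return [
        PooledVariant(
            chrom=row.chrom, pos=int(row.pos), ref_allele=row.ref, alt_allele=row.alt,
            ad_high=(int(row.ref_reads_high), int(row.alt_reads_high)),
            ad_low=(int(row.ref_reads_low), int(row.alt_reads_low)),
            multiallelic=bool(row.multiallelic),
        )
        for row in df.itertuples(index=False)
    ]
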