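"""Codon-aware variant consequence classification against gene models.

Each variant receives exactly one category, chosen by precedence when it
touches several regions of one or more genes:

    exonic > splicing > intronic > upstream/downstream (joint)
           > upstream > downstream > intergenic

Region definitions (all coordinates 1-based inclusive, strand-aware):

* upstream    — within 1 kb 5' of the transcription start site;
* downstream  — within 1 kb 3' of the transcription end site;
* upstream/downstream — upstream of one gene and simultaneously downstream
  of a different gene;
* intronic    — inside the transcription bounds but outside every CDS;
* splicing    — intronic and within 2 bp of a CDS/intron junction, on the
  intron side; only multi-exon transcripts have junctions;
* exonic      — overlapping a coding exon.  SNVs are resolved to
  synonymous / non-synonymous / stop-gain / stop-loss by rebuilding the
  affected codon from the genome on the coding strand and translating with
  the standard nuclear code; indels are frameshift iff the net length
  change is not a multiple of 3, with an immediate stop created or removed
  at the first affected codon reported as stop-gain / stop-loss.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .variant_io import GeneModel, PooledVariant

__all__ = [
    "VariantEffect",
    "classify_variant",
    "tabulate_effects",
    "tstv_counts",
    "effect_table",
    "FLANK_BP",
    "SPLICE_BP",
]

FLANK_BP = 1000   # up/downstream window around the transcript
SPLICE_BP = 2     # intron bases adjacent to a junction called splicing

CATEGORIES = (
    "intergenic", "upstream", "downstream", "upstream/downstream",
    "intronic", "splicing", "exonic",
)
EXONIC_SUBTYPES = (
    "synonymous", "non-synonymous", "stop-gain", "stop-loss",
    "frameshift-insertion", "frameshift-deletion",
    "non-frameshift-insertion", "non-frameshift-deletion",
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class VariantEffect:
    """Consequence call for one variant against its gene neighborhood."""

    category: str
    exonic_subtype: str = "none"
    gene_ids: tuple[str, ...] = ()
    aa_change: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.exonic_subtype != "none") != (self.category == "exonic"):
            raise ValueError("exonic_subtype set iff category is exonic")
        if self.exonic_subtype != "none" and self.exonic_subtype not in EXONIC_SUBTYPES:
            raise ValueError(f"unknown exonic subtype {self.exonic_subtype!r}")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce a variant to its minimal changed bases.

    Handles both anchored VCF style (``ATG > A``) and dash style
    (``TG > -``).  Returns (pos of first changed base, deleted bases,
    inserted bases); for a pure insertion the returned position is the base
    *before which* the inserted bases land.
    """
    ref = "" if ref == "-" else ref
    alt = "" if alt == "-" else alt
    # trim shared suffix then prefix
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _ref_span(pos: int, ref: str) -> tuple[int, int]:
    """Genomic span of reference bases affected; insertions anchor at pos."""
    if not ref:
        return pos, pos
    return pos, pos + len(ref) - 1


def _gene_site_category(gene: GeneModel, start: int, end: int) -> str | None:
    """Category of span [start, end] relative to a single gene, or None."""
    if gene.overlaps(start, end):
        for s, e in gene.cds_intervals:
            if start <= e and end >= s:
                return "exonic"
        if len(gene.cds_intervals) > 1:
            for (s1, e1), (s2, _) in zip(gene.cds_intervals, gene.cds_intervals[1:]):
                # intron between e1 and s2; 2 bp at each end are splice sites
                left = (e1 + 1, min(e1 + SPLICE_BP, s2 - 1))
                right = (max(s2 - SPLICE_BP, e1 + 1), s2 - 1)
                for ls, le in (left, right):
                    if start <= le and end >= ls:
                        return "splicing"
        return "intronic"
    if gene.strand == "+":
        up = (gene.tx_start - FLANK_BP, gene.tx_start - 1)
        down = (gene.tx_end + 1, gene.tx_end + FLANK_BP)
    else:
        up = (gene.tx_end + 1, gene.tx_end + FLANK_BP)
        down = (gene.tx_start - FLANK_BP, gene.tx_start - 1)
    if start <= up[1] and end >= up[0]:
        return "upstream"
    if start <= down[1] and end >= down[0]:
        return "downstream"
    return None


def _cds_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of genomic ``pos`` within the coding sequence (5'->3')."""
    off = 0
    intervals = gene.cds_intervals if gene.strand == "+" else tuple(reversed(gene.cds_intervals))
    for s, e in intervals:
        if s <= pos <= e:
            return off + (pos - s if gene.strand == "+" else e - pos)
        off += e - s + 1
    raise ValueError(f"position {pos} not in CDS of {gene.gene_id}")


def coding_sequence(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Spliced coding sequence on the coding strand (5'->3')."""
    seq = genome[gene.chrom]
    parts = [str(seq[s - 1:e]) for s, e in gene.cds_intervals]
    cds = "".join(parts).upper()
    return _revcomp(cds) if gene.strand == "-" else cds


def _snv_subtype(gene: GeneModel, genome: Mapping[str, str], pos: int,
                 alt: str) -> tuple[str, tuple[str, int, str] | None]:
    cds = coding_sequence(gene, genome)
    off = _cds_offset(gene, pos)
    base = alt.upper() if gene.strand == "+" else alt.upper().translate(_COMPLEMENT)
    rel = off - gene.phase
    if rel < 0 or rel >= (len(cds) - gene.phase) // 3 * 3:
        # partial leading/trailing codon: no full codon to translate
        return "non-synonymous", None
    codon_start = gene.phase + rel // 3 * 3
    ref_codon = cds[codon_start:codon_start + 3]
    alt_codon = ref_codon[: off - codon_start] + base + ref_codon[off - codon_start + 1:]
    ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
    codon_index = rel // 3 + 1
    aa_change = (ref_aa, codon_index, alt_aa)
    if ref_aa == alt_aa:
        return "synonymous", aa_change
    if alt_aa == "*":
        return "stop-gain", aa_change
    if ref_aa == "*":
        return "stop-loss", aa_change
    return "non-synonymous", aa_change


def _indel_subtype(gene: GeneModel, genome: Mapping[str, str], pos: int,
                   deleted: str, inserted: str) -> str:
    net = len(inserted) - len(deleted)
    if net == 0 and deleted:
        # same-length substitution block: treat like non-frameshift change
        kind = "non-frameshift-deletion"
    elif net > 0:
        kind = ("non-frameshift-insertion" if net % 3 == 0 else "frameshift-insertion")
    else:
        kind = ("non-frameshift-deletion" if net % 3 == 0 else "frameshift-deletion")

    # immediate stop creation/elimination at the first affected codon,
    # evaluated only for edits fully inside the CDS
    span_s, span_e = _ref_span(pos, deleted) if deleted else (pos, pos)
    inside = any(s <= span_s and span_e <= e for s, e in gene.cds_intervals)
    if not inside:
        return kind
    try:
        cds = coding_sequence(gene, genome)
        if deleted:
            offs = [_cds_offset(gene, p) for p in range(span_s, span_e + 1)]
            first = min(offs)
            ins = inserted.upper()
            if gene.strand == "-":
                ins = _revcomp(inserted.upper())
            mut = cds[:first] + ins + cds[first + len(deleted):]
        else:
            # normalized insertion: inserted bases land immediately before
            # the genomic base at ``pos``
            anchor = _cds_offset(gene, pos)
            if gene.strand == "+":
                ins, first = inserted.upper(), anchor
            else:
                ins, first = _revcomp(inserted.upper()), anchor + 1
            mut = cds[:first] + ins + cds[first:]
        rel = first - gene.phase
        if rel < 0:
            return kind
        codon_start = gene.phase + rel // 3 * 3
        ref_codon = cds[codon_start:codon_start + 3]
        mut_codon = mut[codon_start:codon_start + 3]
        if len(ref_codon) == 3 and len(mut_codon) == 3:
            ref_aa, mut_aa = _translate(ref_codon), _translate(mut_codon)
            if mut_aa == "*" and ref_aa != "*":
                return "stop-gain"
            if ref_aa == "*" and mut_aa != "*":
                return "stop-loss"
    except ValueError:
        pass
    return kind


def classify_variant(
    variant: PooledVariant,
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> VariantEffect:
    """Classify one variant against all genes on its chromosome.

    ``genome`` maps chromosome id to its full sequence (any str-indexable
    sequence store works, e.g. ``pyfaidx.Fasta`` records coerced to str).
    Raises if the variant's REF disagrees with the genome or lies beyond
    the chromosome end.
    """
    if variant.chrom not in genome:
        raise ValueError(f"chromosome {variant.chrom!r} not in genome")
    seq = genome[variant.chrom]
    pos, deleted, inserted = normalize_alleles(
        variant.pos, variant.ref_allele, variant.alt_allele
    )
    span_s, span_e = _ref_span(pos, deleted)
    if span_e > len(seq):
        raise ValueError(
            f"{variant.chrom}:{variant.pos} beyond chromosome end ({len(seq)} bp)"
        )
    if deleted:
        observed = str(seq[span_s - 1:span_e]).upper()
        if observed != deleted.upper():
            raise ValueError(
                f"{variant.chrom}:{span_s} REF {deleted!r} disagrees with genome {observed!r}"
            )

    is_snv = len(deleted) == 1 and len(inserted) == 1

    per_gene: list[tuple[str, GeneModel]] = []
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        cat = _gene_site_category(gene, span_s, span_e)
        if cat is not None:
            per_gene.append((cat, gene))

    if not per_gene:
        return VariantEffect(category="intergenic")

    exonic = [g for c, g in per_gene if c == "exonic"]
    if exonic:
        gene_ids = tuple(dict.fromkeys(g.gene_id for g in exonic))
        best: tuple[int, str, tuple | None] | None = None
        severity = {
            "stop-gain": 0, "stop-loss": 1, "frameshift-insertion": 2,
            "frameshift-deletion": 2, "non-synonymous": 3,
            "non-frameshift-insertion": 4, "non-frameshift-deletion": 4,
            "synonymous": 5,
        }
        for g in exonic:
            if is_snv:
                sub, aa = _snv_subtype(g, genome, pos, inserted)
            else:
                sub, aa = _indel_subtype(g, genome, pos, deleted, inserted), None
            rank = severity[sub]
            if best is None or rank < best[0]:
                best = (rank, sub, aa)
        assert best is not None
        return VariantEffect(
            category="exonic", exonic_subtype=best[1], gene_ids=gene_ids,
            aa_change=best[2],
        )

    for cat in ("splicing", "intronic"):
        hits = [g for c, g in per_gene if c == cat]
        if hits:
            return VariantEffect(
                category=cat,
                gene_ids=tuple(dict.fromkeys(g.gene_id for g in hits)),
            )

    up = {g.gene_id for c, g in per_gene if c == "upstream"}
    down = {g.gene_id for c, g in per_gene if c == "downstream"}
    if up and down:
        return VariantEffect(
            category="upstream/downstream", gene_ids=tuple(sorted(up | down))
        )
    if up:
        return VariantEffect(category="upstream", gene_ids=tuple(sorted(up)))
    return VariantEffect(category="downstream", gene_ids=tuple(sorted(down)))


def tabulate_effects(
    pairs: Iterable[tuple[PooledVariant, VariantEffect]],
) -> dict[tuple[str, str], int]:
    """Count effects per (variant class, label).

    The label is the exonic subtype for exonic variants and the category
    otherwise; counts per class sum to the number of classified variants of
    that class.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for variant, effect in pairs:
        label = effect.exonic_subtype if effect.category == "exonic" else effect.category
        counts[(variant.vclass, label)] += 1
    return dict(counts)


def tstv_counts(variants: Iterable[PooledVariant]) -> tuple[int, int]:
    """Transition / transversion counts over the SNVs of ``variants``."""
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    ts = tv = 0
    for v in variants:
        if v.vclass != "SNP":
            continue
        if (v.ref_allele.upper(), v.alt_allele.upper()) in transitions:
            ts += 1
        else:
            tv += 1
    return ts, tv


_TABLE_ROWS: tuple[tuple[str, bool, bool], ...] = (
    # label, possible for SNP, possible for InDel
    ("intergenic", True, True),
    ("upstream", True, True),
    ("downstream", True, True),
    ("upstream/downstream", True, True),
    ("intronic", True, True),
    ("stop-gain", True, True),
    ("stop-loss", True, True),
    ("frameshift-deletion", False, True),
    ("frameshift-insertion", False, True),
    ("non-frameshift-deletion", False, True),
    ("non-frameshift-insertion", False, True),
    ("synonymous", True, False),
    ("non-synonymous", True, False),
    ("splicing", True, True),
)


def tstv_summary(ts: int, tv: int) -> dict[str, float]:
    """Transition/transversion report row: the implied SNV total and ratio."""
    if ts < 0 or tv < 0:
        raise ValueError("counts must be non-negative")
    return {
        "transitions": ts,
        "transversions": tv,
        "total_snv": ts + tv,
        "tstv_ratio": ts / tv if tv else float("inf"),
    }


def effect_table(counts: Mapping[tuple[str, str], int]) -> pd.DataFrame:
    """Render tabulated counts as a two-column summary table.

    Labels impossible for a variant class are shown as '-', mirroring the
    dashes of a classical annotation summary; a Total row closes the table.
    """
    rows = []
    for label, snp_ok, indel_ok in _TABLE_ROWS:
        snp = counts.get(("SNP", label), 0) if snp_ok else "-"
        indel = counts.get(("InDel", label), 0) if indel_ok else "-"
        rows.append((label, snp, indel))
    snp_total = sum(v for (c, _), v in counts.items() if c == "SNP")
    indel_total = sum(v for (c, _), v in counts.items() if c == "InDel")
    rows.append(("Total", snp_total, indel_total))
    return pd.DataFrame(rows, columns=["Category", "SNP", "InDel"]).set_index("Category")
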