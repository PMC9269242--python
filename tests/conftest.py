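"""Shared fixtures: deterministic toy contigs with gene models, and an
independent brute-force consequence classifier used as the oracle."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from bsascan.variant_io import GeneModel, PooledVariant

FLANK = 1000
SPLICE = 2


def _random_seq(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def three_gene_contig() -> tuple[dict[str, str], list[GeneModel]]:
    """2 kb contig with three genes on both strands and 1-3 exons each.

    The 1-kb flanks tile the whole contig, so every positional category
    except intergenic occurs somewhere.
    """
    chrom = "ctgA"
    seq = _random_seq(2000, seed=7)
    genes = [
        GeneModel("GA", chrom, "+", 150, 330, ((150, 206), (250, 330))),
        GeneModel("GB", chrom, "-", 1150, 1420, ((1150, 1210), (1255, 1315), (1360, 1420))),
        GeneModel("GC", chrom, "+", 1650, 1850, ((1650, 1850),)),
    ]
    return {chrom: seq}, genes


@pytest.fixture(scope="session")
def single_gene_contig() -> tuple[dict[str, str], list[GeneModel]]:
    """2 kb contig with one two-exon gene; region sizes are round numbers:
    upstream 200 (clipped at the contig start), exonic 120, splicing 4,
    intronic 76, downstream 1000, intergenic 600."""
    chrom = "ctgB"
    seq = _random_seq(2000, seed=13)
    genes = [GeneModel("G1", chrom, "+", 201, 400, ((201, 260), (341, 400)))]
    return {chrom: seq}, genes


def make_snv(chrom: str, pos: int, ref: str, alt: str) -> PooledVariant:
    return PooledVariant(
        chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        ad_high=(10, 10), ad_low=(10, 10),
    )


# ---------------------------------------------------------------------------
# independent brute-force classifier (the oracle): every region definition
# is tested literally with plain loops, and exonic SNVs are resolved by
# rebuilding and translating the entire coding sequence
# ---------------------------------------------------------------------------

_SUBTYPE_SEVERITY = [
    "stop-gain", "stop-loss", "frameshift-insertion", "frameshift-deletion",
    "non-synonymous", "non-frameshift-insertion", "non-frameshift-deletion",
    "synonymous",
]


def _oracle_gene_category(gene: GeneModel, pos: int) -> str | None:
    if gene.tx_start <= pos <= gene.tx_end:
        for s, e in gene.cds_intervals:
            if s <= pos <= e:
                return "exonic"
        if len(gene.cds_intervals) > 1:
            for (s1, e1), (s2, e2) in zip(gene.cds_intervals, gene.cds_intervals[1:]):
                intron = range(e1 + 1, s2)
                near = {e1 + 1, e1 + 2, s2 - 1, s2 - 2}
                if pos in intron and pos in near:
                    return "splicing"
        return "intronic"
    if gene.strand == "+":
        upstream = range(gene.tx_start - FLANK, gene.tx_start)
        downstream = range(gene.tx_end + 1, gene.tx_end + FLANK + 1)
    else:
        upstream = range(gene.tx_end + 1, gene.tx_end + FLANK + 1)
        downstream = range(gene.tx_start - FLANK, gene.tx_start)
    if pos in upstream:
        return "upstream"
    if pos in downstream:
        return "downstream"
    return None


def _oracle_protein(gene: GeneModel, seq: str, substitute: tuple[int, str] | None) -> str:
    parts = []
    for s, e in gene.cds_intervals:
        part = seq[s - 1:e]
        if substitute is not None and s <= substitute[0] <= e:
            i = substitute[0] - s
            part = part[:i] + substitute[1] + part[i + 1:]
        parts.append(part)
    cds = "".join(parts).upper()
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return str(Seq(cds).translate())


def oracle_classify_snv(
    chrom: str, pos: int, alt: str,
    genes: list[GeneModel], genome: dict[str, str],
) -> tuple[str, str]:
    """Brute-force (category, exonic_subtype) for a single-base substitution."""
    seq = genome[chrom]
    cats = {}
    for gene in genes:
        if gene.chrom != chrom:
            continue
        c = _oracle_gene_category(gene, pos)
        if c is not None:
            cats.setdefault(c, []).append(gene)

    if "exonic" in cats:
        subtypes = []
        for gene in cats["exonic"]:
            ref_prot = _oracle_protein(gene, seq, None)
            mut_prot = _oracle_protein(gene, seq, (pos, alt))
            if mut_prot == ref_prot:
                subtypes.append("synonymous")
            else:
                changed = [i for i, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b]
                ra, ma = ref_prot[changed[0]], mut_prot[changed[0]]
                if ma == "*":
                    subtypes.append("stop-gain")
                elif ra == "*":
                    subtypes.append("stop-loss")
                else:
                    subtypes.append("non-synonymous")
        worst = min(subtypes, key=_SUBTYPE_SEVERITY.index)
        return "exonic", worst
    for c in ("splicing", "intronic"):
        if c in cats:
            return c, "none"
    if "upstream" in cats and "downstream" in cats:
        return "upstream/downstream", "none"
    if "upstream" in cats:
        return "upstream", "none"
    if "downstream" in cats:
        return "downstream", "none"
    return "intergenic", "none"
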