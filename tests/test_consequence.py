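"""Consequence classification: worked examples, exhaustive oracle
equivalence, strand symmetry and tabulation bookkeeping."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from bsascan.consequence import (
    classify_variant,
    effect_table,
    normalize_alleles,
    tabulate_effects,
    tstv_counts,
)
from bsascan.variant_io import GeneModel, PooledVariant

from conftest import make_snv, oracle_classify_snv


@pytest.fixture(scope="module")
def toy_orf():
    """ATG GAA TAA coding gene at positions 101-109 of a small contig."""
    chrom = "mini"
    seq = "T" * 100 + "ATGGAATAA" + "C" * 100
    gene = GeneModel("ORF1", chrom, "+", 101, 109, ((101, 109),))
    return {chrom: seq}, [gene]


class TestWorkedExamples:
    def test_synonymous_third_base(self, toy_orf):
        genome, genes = toy_orf
        # codon 2 GAA -> GAG, both glutamate
        eff = classify_variant(make_snv("mini", 106, "A", "G"), genes, genome)
        assert eff.category == "exonic"
        assert eff.exonic_subtype == "synonymous"
        assert eff.aa_change == ("E", 2, "E")

    def test_stop_loss(self, toy_orf):
        genome, genes = toy_orf
        # stop codon TAA -> CAA (glutamine)
        eff = classify_variant(make_snv("mini", 107, "T", "C"), genes, genome)
        assert eff.exonic_subtype == "stop-loss"

    def test_nonsynonymous_and_stop_gain(self, toy_orf):
        genome, genes = toy_orf
        eff = classify_variant(make_snv("mini", 104, "G", "C"), genes, genome)
        assert eff.exonic_subtype == "non-synonymous"  # GAA(E) -> CAA(Q)
        eff = classify_variant(make_snv("mini", 105, "A", "G"), genes, genome)
        # GAA -> GGA is Gly; craft a stop-gain instead: GAA -> TAA at base 1
        eff2 = classify_variant(make_snv("mini", 104, "G", "T"), genes, genome)
        assert eff2.exonic_subtype == "stop-gain"

    def test_upstream_500bp(self):
        chrom = "up"
        seq = "A" * 3000
        gene = GeneModel("G", chrom, "+", 2001, 2300, ((2001, 2300),))
        eff = classify_variant(make_snv(chrom, 1501, "A", "G"), [gene], {chrom: seq})
        assert eff.category == "upstream"

    def test_joint_upstream_downstream(self):
        chrom = "j"
        seq = "A" * 4000
        left = GeneModel("L", chrom, "+", 101, 400, ((101, 400),))
        right = GeneModel("R", chrom, "+", 1201, 1500, ((1201, 1500),))
        # position 800: downstream of L (401-1400) and upstream of R (201-1200)
        eff = classify_variant(make_snv(chrom, 800, "A", "G"), [left, right], {chrom: seq})
        assert eff.category == "upstream/downstream"
        assert set(eff.gene_ids) == {"L", "R"}

    def test_splicing_two_bases_into_intron(self, single_gene_contig):
        genome, genes = single_gene_contig
        seq = genome["ctgB"]
        # intron is 261-340; positions 261, 262, 339, 340 are splice sites
        for pos in (261, 262, 339, 340):
            ref = seq[pos - 1]
            alt = "A" if ref != "A" else "G"
            eff = classify_variant(make_snv("ctgB", pos, ref, alt), genes, genome)
            assert eff.category == "splicing", pos
        eff = classify_variant(make_snv("ctgB", 300, seq[299], "A" if seq[299] != "A" else "G"),
                               genes, genome)
        assert eff.category == "intronic"

    def test_frameshift_deletion_dash_style(self):
        chrom = "fs"
        seq = "T" * 100 + "ATGGCAGTAGAATGA" + "C" * 100
        gene = GeneModel("G", chrom, "+", 101, 115, ((101, 115),))
        v = PooledVariant(chrom=chrom, pos=104, ref_allele="GCAGT", alt_allele="-",
                          ad_high=(5, 5), ad_low=(5, 5))
        eff = classify_variant(v, [gene], {chrom: seq})
        assert eff.category == "exonic"
        assert eff.exonic_subtype == "frameshift-deletion"

    def test_nonframeshift_insertion(self):
        chrom = "nf"
        seq = "T" * 100 + "ATGGAAGAATAA" + "C" * 100
        gene = GeneModel("G", chrom, "+", 101, 112, ((101, 112),))
        v = PooledVariant(chrom=chrom, pos=106, ref_allele="A", alt_allele="AGAG",
                          ad_high=(5, 5), ad_low=(5, 5))
        eff = classify_variant(v, [gene], {chrom: seq})
        assert eff.exonic_subtype == "non-frameshift-insertion"

    def test_ref_mismatch_and_out_of_range_raise(self, toy_orf):
        genome, genes = toy_orf
        with pytest.raises(ValueError, match="disagrees"):
            classify_variant(make_snv("mini", 104, "C", "T"), genes, genome)
        with pytest.raises(ValueError, match="beyond"):
            classify_variant(make_snv("mini", 10_000, "A", "T"), genes, genome)
        with pytest.raises(ValueError, match="chromosome"):
            classify_variant(make_snv("nope", 1, "A", "T"), genes, genome)


def test_normalize_alleles_trims_and_anchors():
    assert normalize_alleles(100, "ATG", "A") == (101, "TG", "")
    assert normalize_alleles(100, "A", "AC") == (101, "", "C")
    assert normalize_alleles(100, "GCAGT", "-") == (100, "GCAGT", "")
    assert normalize_alleles(100, "CAT", "CGT") == (101, "A", "G")


def _every_snv(genome: dict[str, str]):
    chrom, seq = next(iter(genome.items()))
    for pos in range(1, len(seq) + 1):
        ref = seq[pos - 1]
        for alt in "ACGT":
            if alt != ref:
                yield chrom, pos, ref, alt


def test_oracle_equivalence_every_position_every_substitution(three_gene_contig):
    """The classifier agrees with the literal brute-force oracle at every
    position x substitution of the three-gene contig."""
    genome, genes = three_gene_contig
    mismatches = []
    for chrom, pos, ref, alt in _every_snv(genome):
        eff = classify_variant(make_snv(chrom, pos, ref, alt), genes, genome)
        expect = oracle_classify_snv(chrom, pos, alt, genes, genome)
        if (eff.category, eff.exonic_subtype) != expect:
            mismatches.append((pos, ref, alt, (eff.category, eff.exonic_subtype), expect))
    assert not mismatches, mismatches[:10]


def test_strand_flip_invariance(three_gene_contig):
    """Reverse-complementing the contig and flipping the gene coordinates
    leaves every effect class unchanged."""
    genome, genes = three_gene_contig
    chrom, seq = next(iter(genome.items()))
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    comp = str.maketrans("ACGT", "TGCA")
    flipped = [
        GeneModel(
            g.gene_id, chrom, "-" if g.strand == "+" else "+",
            L - g.tx_end + 1, L - g.tx_start + 1,
            tuple(sorted((L - e + 1, L - s + 1) for s, e in g.cds_intervals)),
        )
        for g in genes
    ]
    rng = np.random.default_rng(3)
    positions = rng.choice(np.arange(1, L + 1), size=400, replace=False)
    for pos in positions:
        ref = seq[pos - 1]
        alt = "ACGT"[(("ACGT".index(ref)) + 1) % 4]
        eff = classify_variant(make_snv(chrom, int(pos), ref, alt), genes, genome)
        mpos = L - int(pos) + 1
        eff2 = classify_variant(
            make_snv(chrom, mpos, ref.translate(comp), alt.translate(comp)),
            flipped, {chrom: rc},
        )
        assert (eff.category, eff.exonic_subtype) == (eff2.category, eff2.exonic_subtype), pos


def test_tabulation_matches_geometric_region_sizes(single_gene_contig):
    """Exhaustively classifying one substitution per position reproduces the
    geometric sizes of the gene's regions."""
    genome, genes = single_gene_contig
    chrom, seq = next(iter(genome.items()))
    counts: dict[str, int] = {}
    for pos in range(1, len(seq) + 1):
        ref = seq[pos - 1]
        alt = "A" if ref != "A" else "C"
        eff = classify_variant(make_snv(chrom, pos, ref, alt), genes, genome)
        counts[eff.category] = counts.get(eff.category, 0) + 1
    assert counts == {
        "upstream": 200, "exonic": 120, "splicing": 4, "intronic": 76,
        "downstream": 1000, "intergenic": 600,
    }
    assert sum(counts.values()) == len(seq)


def test_tabulate_effects_counts_and_table(toy_orf=None):
    from bsascan.consequence import VariantEffect

    pairs = [
        (make_snv("c", 1 + i, "A", "G"), VariantEffect(category="intergenic"))
        for i in range(3)
    ]
    pairs.append(
        (make_snv("c", 50, "A", "G"),
         VariantEffect(category="exonic", exonic_subtype="non-synonymous", gene_ids=("g",)))
    )
    counts = tabulate_effects(pairs)
    assert counts == {("SNP", "intergenic"): 3, ("SNP", "non-synonymous"): 1}
    table = effect_table(counts)
    assert table.loc["intergenic", "SNP"] == 3
    assert table.loc["Total", "SNP"] == 4
    assert table.loc["frameshift-deletion", "SNP"] == "-"  # impossible for SNVs
    assert tabulate_effects([]) == {}


def test_tstv_partition():
    variants = [
        make_snv("c", 1, "A", "G"),   # transition
        make_snv("c", 2, "C", "T"),   # transition
        make_snv("c", 3, "A", "T"),   # transversion
        PooledVariant(chrom="c", pos=4, ref_allele="A", alt_allele="AT",
                      ad_high=(1, 1), ad_low=(1, 1)),  # indel, excluded
    ]
    ts, tv = tstv_counts(variants)
    assert (ts, tv) == (2, 1)
    assert ts + tv == sum(1 for v in variants if v.vclass == "SNP")
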