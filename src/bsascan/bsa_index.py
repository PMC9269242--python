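"""Per-variant pool indices, Δ(index), and the pre-association filters.

The SNP/InDel-index of a pool is the alternate-allele read fraction
``alt / (ref + alt)`` — an allele-frequency estimate from pooled reads.
Δ(index) is the difference between the high- and low-phenotype pools; a
site tightly linked to the trait locus drives the two pools toward opposite
allele classes and hence |Δ| toward 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .variant_io import PooledVariant

__all__ = [
    "IndexedVariant",
    "FilterConfig",
    "FilterReport",
    "compute_index",
    "compute_delta",
    "apply_filters",
    "indexed_to_frame",
]


def compute_index(ad: tuple[int, int]) -> float:
    """Pool index: alt reads over total reads at one site in one pool."""
    ref, alt = ad
    total = ref + alt
    if total <= 0:
        raise ZeroDivisionError("pool index undefined at zero total depth")
    return alt / total


def compute_delta(index_high: float, index_low: float) -> float:
    """Δ(index) = high-pool index minus low-pool index."""
    return index_high - index_low


@dataclass(frozen=True)
class IndexedVariant:
    """A retained variant with its pool indices and Δ."""

    variant: PooledVariant
    index_high: float
    index_low: float
    delta: float
    depth_high: int
    depth_low: int

    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos

    @property
    def vclass(self) -> str:
        return self.variant.vclass

    @classmethod
    def from_variant(cls, v: PooledVariant) -> "IndexedVariant":
        ih = compute_index(v.ad_high)
        il = compute_index(v.ad_low)
        return cls(
            variant=v, index_high=ih, index_low=il, delta=compute_delta(ih, il),
            depth_high=v.depth_high, depth_low=v.depth_low,
        )


@dataclass
class FilterConfig:
    """Pre-association variant filters.

    ``min_index`` removes sites whose index is below the cutoff (default:
    in *both* pools — shared sequencing error or a rare allele; switch
    ``low_index_mode`` to ``"either"`` for the stricter per-pool reading).
    ``min_depth`` removes sites with total depth below the cutoff in either
    pool.  ``equal_genotype_band`` defines the homozygous bands (< band or
    > 1-band in both pools) used by the same-genotype filter.  The parental
    recessive filter only applies to cross-derived pools and needs a
    parental ALT-frequency map; it is off by default because a natural
    population has no parents.
    """

    min_index: float = 0.3
    min_depth: int = 4
    drop_multiallelic: bool = True
    drop_equal_genotypes: bool = True
    equal_genotype_band: float = 0.1
    low_index_mode: str = "both"
    parental_recessive_filter: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.min_index < 1:
            raise ValueError("min_index must be in [0, 1)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.low_index_mode not in {"both", "either"}:
            raise ValueError("low_index_mode must be 'both' or 'either'")


@dataclass
class FilterReport:
    """Per-rule removal counts; removed + retained == input."""

    multiallelic: int = 0
    depth: int = 0
    low_index: int = 0
    equal_genotype: int = 0
    parental: int = 0
    retained: int = 0

    @property
    def removed(self) -> int:
        return self.multiallelic + self.depth + self.low_index + self.equal_genotype + self.parental

    @property
    def total(self) -> int:
        return self.removed + self.retained

    def as_dict(self) -> dict[str, int]:
        return {
            "multiallelic": self.multiallelic,
            "depth": self.depth,
            "low_index": self.low_index,
            "equal_genotype": self.equal_genotype,
            "parental": self.parental,
            "retained": self.retained,
        }


def apply_filters(
    variants: Sequence[PooledVariant],
    config: FilterConfig | None = None,
    parent_alt_index: dict[tuple[str, int], float] | None = None,
) -> tuple[list[IndexedVariant], FilterReport]:
    """Apply the pre-association filters in fixed order.

    Order (first matching rule claims the removal): multi-allelic sites;
    total depth below ``min_depth`` in either pool; index below
    ``min_index`` (both pools by default); identical inferred genotype
    class in both pools (both indices in the same homozygous band); and,
    when enabled, low-pool alleles inconsistent with the recessive parent.
    """
    cfg = config or FilterConfig()
    report = FilterReport()
    retained: list[IndexedVariant] = []
    band = cfg.equal_genotype_band
    for v in variants:
        if cfg.drop_multiallelic and v.multiallelic:
            report.multiallelic += 1
            continue
        if v.depth_high < cfg.min_depth or v.depth_low < cfg.min_depth:
            report.depth += 1
            continue
        iv = IndexedVariant.from_variant(v)
        low_high = iv.index_high < cfg.min_index
        low_low = iv.index_low < cfg.min_index
        dropped_low = (low_high and low_low) if cfg.low_index_mode == "both" else (low_high or low_low)
        if cfg.min_index > 0 and dropped_low:
            report.low_index += 1
            continue
        if cfg.drop_equal_genotypes:
            both_ref = iv.index_high < band and iv.index_low < band
            both_alt = iv.index_high > 1 - band and iv.index_low > 1 - band
            if both_ref or both_alt:
                report.equal_genotype += 1
                continue
        if cfg.parental_recessive_filter and parent_alt_index is not None:
            parent = parent_alt_index.get((v.chrom, v.pos))
            if parent is not None and (parent > 0.5) != (iv.index_low > 0.5):
                report.parental += 1
                continue
        retained.append(iv)
    report.retained = len(retained)
    return retained, report


def indexed_to_frame(indexed: Sequence[IndexedVariant]) -> pd.DataFrame:
    """Filtered-variant table: one row per retained site."""
    rows = [
        (iv.chrom, iv.pos, iv.variant.ref_allele, iv.variant.alt_allele, iv.vclass,
         iv.depth_high, iv.depth_low, iv.index_high, iv.index_low, iv.delta)
        for iv in indexed
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "class",
                 "depth_high", "depth_low", "index_high", "index_low", "delta"],
    )
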