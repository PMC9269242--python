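"""Gene prioritization within candidate regions and haplotype-phenotype
comparison at a query site.

Genes are ranked by the severity of the worst variant effect they carry:
frameshift or stop variants first, then non-synonymous, then other genic
(synonymous / splicing / intronic), then regulatory (up/downstream), then
genes with no associated variant.  The haplotype comparison contrasts the
phenotype of reference-allele versus alternate-allele carriers per
environment with Welch's unequal-variance two-sample t-test; heterozygous
and missing calls are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consequence import VariantEffect
from .variant_io import GeneModel, PooledVariant
from .window_scan import CandidateRegion

__all__ = [
    "GenePriority",
    "HaplotypeResult",
    "RANK_CLASSES",
    "prioritize_genes",
    "haplotype_compare",
    "permutation_pvalue",
]

RANK_CLASSES = ("frameshift/stop", "non-synonymous", "other-genic", "regulatory", "none")

_SEVERE = {"stop-gain", "stop-loss", "frameshift-insertion", "frameshift-deletion"}
_GENIC = {"intronic", "splicing"}
_REGULATORY = {"upstream", "downstream", "upstream/downstream"}


def rank_class(effect: VariantEffect | None) -> str:
    if effect is None:
        return "none"
    if effect.category == "exonic":
        if effect.exonic_subtype in _SEVERE:
            return "frameshift/stop"
        if effect.exonic_subtype == "non-synonymous":
            return "non-synonymous"
        return "other-genic"
    if effect.category in _GENIC:
        return "other-genic"
    if effect.category in _REGULATORY:
        return "regulatory"
    return "none"


@dataclass(frozen=True)
class GenePriority:
    gene_id: str
    region: CandidateRegion
    best_effect: VariantEffect | None
    rank_class: str


def prioritize_genes(
    regions: Sequence[CandidateRegion],
    effects: Iterable[tuple[PooledVariant, VariantEffect]],
    gene_models: Sequence[GeneModel],
) -> list[GenePriority]:
    """Rank the genes of each candidate region by worst effect severity.

    Ties within a rank class break by gene position; the top gene of a
    region is its headline candidate.
    """
    order = {c: i for i, c in enumerate(RANK_CLASSES)}
    gene_pos = {g.gene_id: (g.chrom, g.tx_start) for g in gene_models}
    effects = list(effects)

    out: list[GenePriority] = []
    for region in regions:
        best: dict[str, VariantEffect | None] = {g: None for g in region.genes}
        for variant, effect in effects:
            if variant.chrom != region.chrom or not region.start <= variant.pos <= region.end:
                continue
            for gid in effect.gene_ids:
                if gid not in best:
                    continue
                if best[gid] is None or order[rank_class(effect)] < order[rank_class(best[gid])]:
                    best[gid] = effect
        ranked = sorted(
            (GenePriority(g, region, e, rank_class(e)) for g, e in best.items()),
            key=lambda p: (order[p.rank_class], gene_pos.get(p.gene_id, ("", 0))),
        )
        out.extend(ranked)
    return out


@dataclass(frozen=True)
class HaplotypeResult:
    """Per-environment REF vs ALT phenotype comparison at one site."""

    site: str
    per_environment: pd.DataFrame
    ref_fraction_by_type: dict[str, float]


def haplotype_compare(
    phenotypes: pd.DataFrame,
    site: str = "",
    include_het: bool = False,
    min_group: int = 2,
) -> HaplotypeResult:
    """Welch two-sample comparison of REF vs ALT carriers per environment.

    ``phenotypes`` needs columns accession_id, accession_type, environment,
    phenotype, allele (REF/ALT/het/missing).  Environments where either
    group has fewer than ``min_group`` accessions are reported untested.
    REF allele fractions per accession type are computed over non-missing
    calls (het calls count half REF when included).
    """
    df = phenotypes.copy()
    keep = {"REF", "ALT"} | ({"het"} if include_het else set())
    df = df[df["allele"].isin(keep)]

    rows = []
    for env, grp in df.groupby("environment", sort=True):
        ref = grp.loc[grp["allele"] == "REF", "phenotype"].to_numpy(dtype=float)
        alt = grp.loc[grp["allele"] != "REF", "phenotype"].to_numpy(dtype=float)
        tested = len(ref) >= min_group and len(alt) >= min_group
        if tested:
            t, p = stats.ttest_ind(ref, alt, equal_var=False)
            t, p = float(t), float(p)
        else:
            t = p = float("nan")
        rows.append(
            (env, len(ref), len(alt),
             float(np.mean(ref)) if len(ref) else float("nan"),
             float(np.mean(alt)) if len(alt) else float("nan"),
             t, p, tested)
        )
    per_env = pd.DataFrame(
        rows,
        columns=["environment", "n_ref", "n_alt", "mean_ref", "mean_alt",
                 "t_stat", "p_value", "tested"],
    )

    fractions: dict[str, float] = {}
    calls = phenotypes.drop_duplicates("accession_id")
    calls = calls[calls["allele"].isin({"REF", "ALT", "het"})]
    for atype, grp in calls.groupby("accession_type", sort=True):
        weights = grp["allele"].map({"REF": 1.0, "ALT": 0.0, "het": 0.5})
        if not include_het:
            grp2 = grp[grp["allele"] != "het"]
            weights = grp2["allele"].map({"REF": 1.0, "ALT": 0.0})
        if len(weights):
            fractions[str(atype)] = float(weights.mean())
    return HaplotypeResult(site=site, per_environment=per_env, ref_fraction_by_type=fractions)


def permutation_pvalue(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value for a difference in group means.

    Cross-check for the Welch test: labels are permuted ``n_perm`` times
    and the absolute mean difference compared with the observed one (with
    the add-one correction for an unbiased estimate).
    """
    rng = rng if rng is not None else np.random.default_rng()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    n_a = len(a)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)
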