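"""GO term over-representation by the one-sided hypergeometric test.

For a term annotating K of N background genes, observed in k of the n
annotated study genes, the enrichment p-value is the upper tail
P(X >= k) of Hypergeometric(N, K, n) and the expected count is K*n/N.
No multiple-testing correction is applied by default (raw p < alpha);
Benjamini-Hochberg q-values are available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .variant_io import AnnotationTable

__all__ = [
    "EnrichmentResult",
    "enrich",
    "expected_count",
    "hypergeom_upper_tail",
    "backsolve_background",
]


def expected_count(K: int, n: int, N: int) -> float:
    """Expected study-set count of a term under random draws: K*n/N."""
    if N <= 0:
        raise ZeroDivisionError("background size N must be positive")
    return K * n / N


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def backsolve_background(K: int, n: int, expected: float) -> int:
    """Recover the background size from a reported expected count."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return round(K * n / expected)


@dataclass(frozen=True)
class EnrichmentResult:
    go_id: str
    term: str
    K: int           # annotated background genes for the term
    k: int           # study genes carrying the term
    n: int           # annotated study-set size
    N: int           # annotated background size
    expected: float
    p: float
    gene_ids: tuple[str, ...]
    significant: bool
    q: float | None = None


def enrich(
    study_genes: Iterable[str],
    annotation: AnnotationTable,
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Test every term observed in the study set for over-representation.

    Study genes absent from the annotation are excluded from n with a
    warning.  Terms with k = 0 are skipped (their upper tail is 1).
    Results are sorted by p; ``significant`` flags raw p < alpha (or
    BH q < alpha when ``fdr`` is on).
    """
    study = set(study_genes)
    annotated = study & annotation.genes
    dropped = study - annotated
    if dropped:
        warnings.warn(
            f"{len(dropped)} study gene(s) missing from the annotation background: "
            f"{sorted(dropped)[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    n = len(annotated)
    results: list[EnrichmentResult] = []
    terms = sorted({t for g in annotated for t in annotation.gene_terms[g]})
    for term_id in terms:
        hits = tuple(sorted(annotation.term_genes[term_id] & annotated))
        k = len(hits)
        if k == 0:
            continue
        K = len(annotation.term_genes[term_id])
        N = annotation.background_size(annotation.term_ontology.get(term_id))
        p = hypergeom_upper_tail(k, N, K, n)
        results.append(
            EnrichmentResult(
                go_id=term_id,
                term=annotation.term_names.get(term_id, ""),
                K=K, k=k, n=n, N=N,
                expected=expected_count(K, n, N),
                p=p,
                gene_ids=hits,
                significant=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.p, r.go_id))
    if fdr and results:
        m = len(results)
        qs = [r.p * m / (i + 1) for i, r in enumerate(results)]
        for i in range(m - 2, -1, -1):
            qs[i] = min(qs[i], qs[i + 1])
        results = [
            EnrichmentResult(
                **{**r.__dict__, "q": min(q, 1.0), "significant": q < alpha}
            )
            for r, q in zip(results, qs)
        ]
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment table in GO-report column order."""
    return pd.DataFrame(
        [
            (r.go_id, r.term, r.K, r.k, round(r.expected, 2), r.p, ", ".join(r.gene_ids))
            for r in results
        ],
        columns=["GO ID", "Term", "Annotated", "Count", "Expected", "p-Value", "Genes"],
    )
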