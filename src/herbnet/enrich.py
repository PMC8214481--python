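"""Hypergeometric over-representation analysis and the core-pathway rule.

For a query of n genes drawn from a universe of M genes, a term annotating K
genes and overlapping the query in k, the enrichment p-value is the upper tail

    p = P(X >= k),  X ~ Hypergeometric(M, K, n),

Benjamini–Hochberg corrected across all terms with k >= 1; a term is called
significant at q < 0.05 by default. The core-pathway rule then keeps, per
herb, the disease-significant terms whose per-herb enriched-gene count k
strictly exceeds the upper quartile of that herb's k distribution over the
candidate terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = ["EnrichmentResult", "enrich", "core_pathways"]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # overlap
    K: int  # term size
    n: int  # query size
    M: int  # universe size
    p: float
    q: float
    enriched_genes: frozenset[str]
    significant: bool

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError(f"{self.term_id}: overlap exceeds a margin")


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    q_max: float = 0.05,
) -> list[EnrichmentResult]:
    """Test ``query`` against every set in ``collection``; BH-correct; sort by p.

    Query genes outside the universe are dropped with a warning. Terms with no
    overlap are excluded before correction so q-values are comparable across
    queries. ``significant`` is q < ``q_max``.
    """
    q_genes = frozenset(query)
    stray = q_genes - collection.universe
    if stray:
        warnings.warn(
            f"{len(stray)} query genes outside the universe were dropped: "
            f"{sorted(stray)[:5]}...",
            stacklevel=2,
        )
        q_genes = q_genes & collection.universe
    if not q_genes:
        raise ValueError("query is empty after universe filtering")
    M = len(collection.universe)
    n = len(q_genes)
    rows: list[tuple[str, int, int, frozenset[str], float]] = []
    for term in sorted(collection.sets):
        genes = collection.genes_of(term)
        overlap = genes & q_genes
        k = len(overlap)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), n))
        rows.append((term, k, len(genes), frozenset(overlap), p))
    if not rows:
        return []
    pvals = [r[4] for r in rows]
    _, qvals, *_ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term_id=term, k=k, K=K, n=n, M=M, p=p, q=float(q),
            enriched_genes=overlap, significant=bool(q < q_max),
        )
        for (term, k, K, overlap, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def core_pathways(
    per_herb_results: Mapping[str, list[EnrichmentResult]],
    disease_results: list[EnrichmentResult],
) -> dict[str, frozenset[str]]:
    """Per-herb core terms: disease-significant terms with k above the herb's Q3.

    Candidate terms are those significant for the disease gene list. For each
    herb, its enriched-gene count k over the candidates (0 where the herb has
    no overlap) defines a distribution; candidates strictly above its linearly
    interpolated upper quartile are that herb's core terms. A herb overlapping
    no candidate gets an empty set, as does a herb whose counts are all tied.
    """
    candidates = sorted(r.term_id for r in disease_results if r.significant)
    out: dict[str, frozenset[str]] = {}
    for herb, results in per_herb_results.items():
        k_of = {r.term_id: r.k for r in results}
        ks = np.array([k_of.get(t, 0) for t in candidates], dtype=float)
        if ks.size == 0 or ks.max() == 0:
            out[herb] = frozenset()
            continue
        q3 = float(np.quantile(ks, 0.75))
        out[herb] = frozenset(t for t, k in zip(candidates, ks) if k > q3)
    return out
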