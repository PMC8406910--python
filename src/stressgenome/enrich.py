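"""Term enrichment with the asymmetric Fisher contract.

The test set (for instance a DE gene list) is compared with a genome-wide
reference, but genes occurring in both are removed from the *reference
only*. This makes the test sensitive in the direction of the test set and
can legitimately produce zero annotated genes in the reference; with a test
set disjoint from the reference the asymmetry is inert and the test reduces
to the ordinary one-sided Fisher exact test.

For each term the 2x2 table is::

                    annotated   not annotated
    test set            a             b
    reference R'        c             d

with R' = reference \\ test. The over-representation p-value is the upper
hypergeometric tail P(X >= a). Multiple testing is controlled by
Benjamini-Hochberg; significant terms can be reduced to the most specific
ones — a significant term is dropped when any of its descendants is also
significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .model import TermMap


@dataclass
class EnrichmentResult:
    term_id: str
    a: int  # test genes with the term
    b: int  # test genes without the term
    c: int  # reference (after removal) genes with the term
    d: int  # reference genes without the term
    p_value: float
    fdr: float = float("nan")
    direction: str = "over"
    name: str = ""
    namespace: str = ""


def _tail_p(a: int, b: int, c: int, d: int, direction: str) -> float:
    # population M, successes n (term-annotated), draws N (test set)
    M, n, N = a + b + c + d, a + c, a + b
    if M == 0 or n == 0 or N == 0:
        return 1.0
    if direction == "over":
        return float(hypergeom.sf(a - 1, M, n, N))
    return float(hypergeom.cdf(a, M, n, N))


def fisher_asymmetric(test_ids: Iterable[str], reference_ids: Iterable[str],
                      term_map: TermMap, propagate: bool = True,
                      direction: str = "over") -> list[EnrichmentResult]:
    """One-sided term enrichment of ``test_ids`` against ``reference_ids``.

    Genes in both sets are removed from the reference only. When
    ``propagate`` is set, gene->term annotations are first closed upward
    under the parent relation (true-path rule) — appropriate for GO-style
    DAGs, not for flat pathway maps. Test genes without any annotation stay
    in the table margins as unannotated.
    """
    test = set(test_ids)
    if not test:
        raise ValueError("empty test set")
    reference = set(reference_ids)
    effective_ref = reference - test

    tm = term_map.propagated() if propagate else term_map
    term_genes: dict[str, set[str]] = {}
    universe = test | effective_ref
    for gene in universe:
        for term in tm.gene_terms.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    terms = sorted(set(term_genes) | tm.all_terms())

    n_test, n_ref = len(test), len(effective_ref)
    results: list[EnrichmentResult] = []
    for term in terms:
        annotated = term_genes.get(term, set())
        a = len(annotated & test)
        c = len(annotated & effective_ref)
        b, d = n_test - a, n_ref - c
        p = _tail_p(a, b, c, d, direction)
        results.append(
            EnrichmentResult(term, a, b, c, d, p, direction=direction,
                             name=tm.names.get(term, ""),
                             namespace=tm.namespaces.get(term, ""))
        )
    fdrs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = q
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted p-values are scaled by ``m/i``, monotonicity is enforced from the
    largest rank down, values are capped at 1, and ties share the same
    adjusted value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def reduce_most_specific(results: Sequence[EnrichmentResult], term_map: TermMap,
                         alpha: float = 0.05) -> list[EnrichmentResult]:
    """Keep each significant term only if no descendant term is also significant."""
    significant = {r.term_id for r in results if r.fdr <= alpha}
    kept: list[EnrichmentResult] = []
    for r in results:
        if r.term_id not in significant:
            continue
        if term_map.descendants(r.term_id) & significant:
            continue
        kept.append(r)
    return kept


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular layout: term, name, category, FDR, p, and the 2x2 counts."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "category": r.namespace,
                "fdr": r.fdr,
                "p_value": r.p_value,
                "n_test_with_term": r.a,
                "n_test_without_term": r.b,
                "n_reference_with_term": r.c,
                "n_reference_without_term": r.d,
                "direction": r.direction,
            }
            for r in sorted(results, key=lambda r: (r.p_value, r.term_id))
        ]
    )
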