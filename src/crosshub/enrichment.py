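"""Over-representation analysis on supplied gene sets.

The tail probability is computed from first principles in log space:
``P(X >= k)`` for a hypergeometric draw, i.e. ``1 - sum_{i<k} pmf(i)``
evaluated as the complementary (upper) sum so small p-values keep full
relative precision. The Fisher one-sided test is the same tail; the EASE
variant decrements the observed overlap by one before taking the tail,
which makes it uniformly more conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "CC", "MF", "pathway")
DEFAULT_ALPHA = 0.05

METHOD_HYPERGEOM = "hypergeom"
METHOD_FISHER = "fisher"
METHOD_EASE = "ease"
METHODS = (METHOD_HYPERGEOM, METHOD_FISHER, METHOD_EASE)


@dataclass(frozen=True)
class AnnotationTerm:
    term: str
    namespace: str
    description: str
    genes: frozenset[str]


@dataclass(frozen=True)
class AnnotationTable:
    """Immutable term -> gene-set catalogue grouped by namespace."""

    terms: tuple[AnnotationTerm, ...]

    def __post_init__(self) -> None:
        ids = [t.term for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate term identifiers in annotation")

    def __len__(self) -> int:
        return len(self.terms)

    def by_term(self) -> dict[str, AnnotationTerm]:
        return {t.term: t for t in self.terms}

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.genes
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentQuery:
    """Counts for one term: universe N, annotated M, query n, overlap k."""

    N: int
    M: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid counts: {self}")
        if not 0 <= self.k <= min(self.M, self.n):
            raise ValueError(f"overlap k out of range: {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    namespace: str
    p: float
    adj_p: float
    q_value: float
    fold_enrichment: float
    k: int
    M: int
    n: int
    N: int

    @property
    def significant(self) -> bool:
        return self.p < DEFAULT_ALPHA


def _log_hypergeom_pmf(i: np.ndarray, N: int, M: int, n: int) -> np.ndarray:
    i = np.asarray(i, dtype=float)
    return (
        gammaln(M + 1)
        - gammaln(i + 1)
        - gammaln(M - i + 1)
        + gammaln(N - M + 1)
        - gammaln(n - i + 1)
        - gammaln(N - M - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_tail(query: EnrichmentQuery) -> float:
    """Exact upper-tail probability P(X >= k).

    Equals ``1 - sum_{i=0}^{k-1} C(M,i) C(N-M,n-i) / C(N,n)``; evaluated
    by log-space summation of the upper tail for numerical stability.
    ``k = 0`` gives 1 by the empty-sum convention.
    """
    N, M, n, k = query.N, query.M, query.n, query.k
    k_min = max(0, n - (N - M))
    if k <= k_min:
        return 1.0
    k_max = min(M, n)
    i = np.arange(k, k_max + 1)
    log_p = logsumexp(_log_hypergeom_pmf(i, N, M, n))
    return float(min(1.0, np.exp(log_p)))


def fisher_enrich(query: EnrichmentQuery, ease: bool = False) -> float:
    """One-sided Fisher exact p (the hypergeometric tail at k).

    With ``ease=True`` the overlap is reduced to ``max(k - 1, 0)`` first,
    so the returned p-value is never smaller than the plain Fisher p.
    """
    if ease:
        query = EnrichmentQuery(query.N, query.M, query.n, max(query.k - 1, 0))
    return hypergeom_tail(query)


def enrich_gene_set(
    genes: Iterable[str],
    annotation: AnnotationTable,
    background: Iterable[str],
    method: str = METHOD_HYPERGEOM,
) -> list[EnrichmentResult]:
    """Test every term with at least one query hit.

    Query genes absent from the background are dropped with a logged
    warning. Results carry BH-adjusted p-values (also exposed as the
    q-value; see package docs) and are sorted by ascending p with a
    lexicographic term tie-break.
    """
    if method not in METHODS:
        raise ValueError(f"unknown enrichment method {method!r}")
    from .dge import bh_adjust  # local import avoids a cycle

    background = frozenset(background)
    query = set(genes)
    outside = query - background
    if outside:
        logger.warning(
            "dropping %d query genes outside the background: %s",
            len(outside),
            ", ".join(sorted(outside)[:10]),
        )
        query &= background
    N = len(background)
    n = len(query)
    rows: list[tuple[AnnotationTerm, EnrichmentQuery]] = []
    for term in annotation.terms:
        annotated = term.genes & background
        k = len(query & annotated)
        if k == 0:
            continue
        rows.append((term, EnrichmentQuery(N=N, M=len(annotated), n=n, k=k)))
    if not rows:
        return []
    p_values = [
        fisher_enrich(q, ease=True) if method == METHOD_EASE else hypergeom_tail(q)
        for _, q in rows
    ]
    adj = bh_adjust(p_values)
    results = [
        EnrichmentResult(
            term=term.term,
            namespace=term.namespace,
            p=float(p),
            adj_p=float(a),
            q_value=float(a),
            fold_enrichment=(q.k / q.n) / (q.M / q.N),
            k=q.k,
            M=q.M,
            n=q.n,
            N=q.N,
        )
        for (term, q), p, a in zip(rows, p_values, adj)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def common_terms(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, frozenset[str]]:
    """Per-namespace intersection of significant terms (p < alpha)."""
    sig_a = {(r.namespace, r.term) for r in results_a if r.p < alpha}
    sig_b = {(r.namespace, r.term) for r in results_b if r.p < alpha}
    shared = sig_a & sig_b
    out: dict[str, set[str]] = {}
    for namespace, term in shared:
        out.setdefault(namespace, set()).add(term)
    return {ns: frozenset(terms) for ns, terms in out.items()}


def genes_from_common_terms(
    common: Mapping[str, frozenset[str]] | Iterable[str],
    annotation: AnnotationTable,
    deg_union: Iterable[str],
) -> frozenset[str]:
    """DEGs annotated to at least one of the shared terms."""
    if isinstance(common, Mapping):
        wanted = {t for terms in common.values() for t in terms}
    else:
        wanted = set(common)
    deg_union = frozenset(deg_union)
    selected: set[str] = set()
    for term in annotation.terms:
        if term.term in wanted:
            selected |= term.genes & deg_union
    return frozenset(selected)
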