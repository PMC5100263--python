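"""Gene-set overrepresentation testing (binomial upper tail + Bonferroni).

This is the classic PANTHER-style overrepresentation test: for a gene list
of size n drawn against a reference universe of N genes, a category of K
genes has success probability q = K/N; the raw p-value is the exact
one-sided binomial upper tail P(X >= k) with X ~ Binomial(n, q), and the
corrected p-value is Bonferroni over all m categories tested. The expected
count is n*K/N and fold enrichment is observed/expected.

The tail is computed by exact rational summation (converted to float at the
end), so it is reliable far into the tail where naive floating-point
summation loses precision. A hypergeometric alternative (sampling without
replacement) is available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from scipy import stats

__all__ = ["AnnotationSet", "EnrichmentResult", "binomial_upper_tail",
           "overrepresentation", "filter_results"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSet:
    """A gene universe and the categories (gene subsets) to test."""

    universe: frozenset[str]
    categories: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        for cid, genes in self.categories.items():
            if not genes:
                raise ValueError(f"category {cid!r} is empty")
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"category {cid!r} has genes outside the universe: "
                    f"{sorted(stray)[:3]}"
                )

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def universe_size(self) -> int:
        return len(self.universe)


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    K: int              # category size in the universe
    k: int              # observed list genes in the category
    n: int              # list size
    N: int              # universe size
    expected: float     # n*K/N
    fold: float         # k/expected (inf when expected == 0)
    p_raw: float
    p_adj: float


def binomial_upper_tail(k: int, n: int, q: Fraction | float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, q), by rational summation."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    qf = Fraction(q).limit_denominator(10 ** 12) if not isinstance(q, Fraction) else q
    if not (0 <= qf <= 1):
        raise ValueError(f"probability q must be in [0, 1], got {q}")
    if k == 0:
        return 1.0
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * qf ** i * (1 - qf) ** (n - i)
    return float(total)


def overrepresentation(list_genes: Iterable[str], annotation: AnnotationSet,
                       statistic: str = "binomial"
                       ) -> list[EnrichmentResult]:
    """Test every category for overrepresentation in ``list_genes``.

    Genes absent from the universe are dropped with a warning. Results are
    Bonferroni-corrected over all tested categories and sorted by corrected
    p-value (ties by raw p, then category id).
    """
    if statistic not in ("binomial", "hypergeometric"):
        raise ValueError(f"unknown statistic {statistic!r}")
    genes = set(list_genes)
    stray = genes - annotation.universe
    if stray:
        logger.warning("dropping %d gene(s) absent from the universe: %s",
                       len(stray), sorted(stray)[:5])
        genes -= stray
    if not genes:
        raise ValueError("gene list is empty after dropping unknown genes")
    n = len(genes)
    N = annotation.universe_size
    m = annotation.n_categories
    results = []
    for cid, members in annotation.categories.items():
        K = len(members)
        k = len(genes & members)
        expected = n * K / N
        if statistic == "binomial":
            p_raw = binomial_upper_tail(k, n, Fraction(K, N))
        else:
            # upper tail of the hypergeometric: P(X >= k)
            p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_raw = min(1.0, max(p_raw, 0.0)) or math.ulp(0.0)
        fold = (k / expected) if expected > 0 else math.inf
        results.append(EnrichmentResult(
            category=cid, K=K, k=k, n=n, N=N, expected=expected, fold=fold,
            p_raw=p_raw, p_adj=min(1.0, m * p_raw),
        ))
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.category))
    return results


def filter_results(results: Sequence[EnrichmentResult],
                   max_p: float | None = 0.05,
                   min_fold: float | None = 5.0) -> list[EnrichmentResult]:
    """Keep results with p_adj < max_p and fold > min_fold.

    Either criterion may be disabled by passing None.
    """
    if max_p is not None and max_p <= 0:
        raise ValueError("max_p must be positive")
    if min_fold is not None and min_fold <= 0:
        raise ValueError("min_fold must be positive")
    out = []
    for r in results:
        if max_p is not None and not (r.p_adj < max_p):
            continue
        if min_fold is not None and not (r.fold > min_fold):
            continue
        out.append(r)
    return out
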