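"""Hypergeometric over-representation analysis (ORA) with BH adjustment.

For a query gene set of size n drawn against a background of N genes of
which M carry a given annotation, the raw P value of observing an
overlap of at least m is the hypergeometric upper tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n),

computed here as the complement of the lower CDF with log-space terms
(lgamma-based log binomials) and compensated summation, so the result is
stable far beyond where direct factorials overflow.  Raw P values are
adjusted across the whole tested family by Benjamini-Hochberg step-up,
and a set is called significant when p_raw < 0.01 and p_adj <= 0.05
(both cutoffs tunable).  Sets that do not intersect the query (m = 0)
are excluded from the output but still count toward the BH family size,
the convention of DAVID-style annotation tools.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import (
    AnnotationCollection,
    DataError,
    DomainError,
    EnrichmentQuery,
    EnrichmentRow,
    GeneSet,
)

logger = logging.getLogger("phytonet.enrichment")

__all__ = [
    "EnrichmentThresholds",
    "hypergeom_upper_p",
    "adjust_bh",
    "enrich",
    "rows_to_frame",
]


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Significance cutoffs: raw P strictly below ``p_max`` AND adjusted
    P at most ``adj_max``."""

    p_max: float = 0.01
    adj_max: float = 0.05
    adj_method: str = "benjamini_hochberg"

    def __post_init__(self) -> None:
        for name in ("p_max", "adj_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise DomainError(f"{name} must be in (0, 1], got {v}")
        if self.adj_method != "benjamini_hochberg":
            raise DomainError(f"unsupported adjustment method {self.adj_method!r}")


def _log_binom(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeom_upper_p(q: EnrichmentQuery) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n).

    Probability terms are exponentiated from log-space binomials and
    accumulated with ``math.fsum``.  The shorter of the two tails is
    summed: the lower CDF P(X <= m-1) is complemented when m sits below
    the distribution mean, and the upper tail is summed directly when m
    is above it, which keeps full relative precision on the tiny P
    values significance calls depend on.  The result is clamped to
    [0, 1]; ``m = 0`` returns exactly 1.
    """
    N, M, n, m = q.N, q.M, q.n, q.m
    if m == 0:
        return 1.0
    log_denom = _log_binom(N, n)

    def pmf(i: int) -> float:
        return math.exp(_log_binom(M, i) + _log_binom(N - M, n - i) - log_denom)

    lo = max(0, n + M - N)
    hi = min(M, n)
    if m > n * M / N:  # upper tail is the small one: sum it directly
        p = math.fsum(pmf(i) for i in range(m, hi + 1))
    else:
        p = 1.0 - math.fsum(pmf(i) for i in range(lo, m))
    return min(1.0, max(0.0, p))


def adjust_bh(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P values, in input order."""
    for p in pvalues:
        if not 0 <= p <= 1:
            raise DomainError(f"P value outside [0, 1]: {p}")
    if len(pvalues) == 0:
        return []
    _, adj, _, _ = multipletests(list(pvalues), method="fdr_bh")
    return [float(p) for p in adj]


def enrich(
    query_genes: GeneSet,
    collection: AnnotationCollection,
    thresholds: EnrichmentThresholds | None = None,
) -> list[EnrichmentRow]:
    """Test every annotation set for over-representation in the query.

    The background is the collection's explicit background when given,
    else the union of all annotated genes.  Query genes outside the
    background are dropped (count logged) before testing.  Returns one
    row per set with m >= 1, sorted by ascending raw P (ties by set id);
    the BH family spans all tested sets including those with m = 0.
    """
    thresholds = thresholds or EnrichmentThresholds()
    background = collection.effective_background()
    N = len(background)
    query = query_genes.genes & background
    dropped = len(query_genes.genes) - len(query)
    if dropped:
        logger.info("dropped %d query gene(s) outside the background", dropped)
    n = len(query)
    if n == 0:
        raise DataError("empty effective query: no query genes in the background")

    set_ids = sorted(collection.sets)
    queries: dict[str, EnrichmentQuery] = {}
    p_raw: dict[str, float] = {}
    for sid in set_ids:
        annotated = collection.sets[sid].genes & background
        M = len(annotated)
        m = len(query & annotated)
        q = EnrichmentQuery(N=N, M=M, n=n, m=m)
        queries[sid] = q
        p_raw[sid] = hypergeom_upper_p(q)

    adj = adjust_bh([p_raw[sid] for sid in set_ids])
    p_adj = dict(zip(set_ids, adj))

    rows: list[EnrichmentRow] = []
    for sid in set_ids:
        q = queries[sid]
        if q.m == 0:
            continue
        fold = (q.m / q.n) / (q.M / q.N) if q.M > 0 else 0.0
        rows.append(
            EnrichmentRow(
                set_id=sid,
                query=q,
                p_raw=p_raw[sid],
                p_adj=p_adj[sid],
                fold=fold,
                significant=(
                    p_raw[sid] < thresholds.p_max and p_adj[sid] <= thresholds.adj_max
                ),
            )
        )
    rows.sort(key=lambda r: (r.p_raw, r.set_id))
    return rows


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tabulate enrichment rows (set_id, N, M, n, m, p_raw, p_adj, fold,
    significant)."""
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "N": r.query.N,
                "M": r.query.M,
                "n": r.query.n,
                "m": r.query.m,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "fold": r.fold,
                "significant": r.significant,
            }
            for r in rows
        ],
        columns=["set_id", "N", "M", "n", "m", "p_raw", "p_adj", "fold", "significant"],
    )
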