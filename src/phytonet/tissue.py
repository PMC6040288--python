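"""Tissue localization of targets from an expression matrix.

Two rules are supported.  Under the above-mean rule a gene is "located"
in every tissue whose expression strictly exceeds that gene's arithmetic
mean across all tissues (a constant gene locates nowhere).  Under the
argmax rule a gene is positioned in the single tissue where it is most
expressed, ties broken by tissue input order (first wins, tie logged).
Both rules are invariant to positive rescaling of a gene's row, and for
a non-constant gene the argmax tissue always belongs to its above-mean
set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, ExpressionMatrix, normalize_symbol

logger = logging.getLogger("phytonet.tissue")

__all__ = [
    "RULE_ABOVE_MEAN",
    "RULE_ARGMAX",
    "LocationResult",
    "locate_above_mean",
    "locate_argmax",
    "organ_counts",
]

RULE_ABOVE_MEAN = "above_mean"
RULE_ARGMAX = "argmax"


@dataclass
class LocationResult:
    """Per-gene localization plus per-tissue located-gene counts.

    ``located_tissues`` follows the above-mean rule; ``primary_tissue``
    the argmax rule (None for constant genes); ``counts`` holds one entry
    per tissue under the rule requested; ``unprofiled`` lists query genes
    absent from the matrix.
    """

    rule: str
    mean_expression: dict[str, float] = field(default_factory=dict)
    located_tissues: dict[str, set[str]] = field(default_factory=dict)
    primary_tissue: dict[str, str | None] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    profiled: list[str] = field(default_factory=list)
    unprofiled: list[str] = field(default_factory=list)


def locate_above_mean(expr: ExpressionMatrix, gene: str) -> set[str]:
    """Tissues where ``gene`` is expressed strictly above its own mean."""
    row = expr.row(gene)
    mean = float(row.mean())
    return set(row.index[row.to_numpy() > mean])


def locate_argmax(expr: ExpressionMatrix, gene: str) -> str:
    """The tissue of maximum expression; first tissue wins ties (logged)."""
    row = expr.row(gene)
    values = row.to_numpy()
    best = int(np.argmax(values))
    n_tied = int((values == values[best]).sum())
    if n_tied > 1:
        logger.info(
            "gene %s: %d tissues tie at the maximum; keeping first (%s)",
            gene, n_tied, row.index[best],
        )
    return str(row.index[best])


def organ_counts(
    expr: ExpressionMatrix,
    genes: set[str] | list[str],
    rule: str = RULE_ABOVE_MEAN,
) -> LocationResult:
    """Count located genes per tissue under ``rule``.

    Genes missing from the matrix are reported as unprofiled rather than
    raising; the result carries the full per-gene localization so the
    same pass serves both the counts table and a location network.
    """
    if rule not in (RULE_ABOVE_MEAN, RULE_ARGMAX):
        raise ConfigurationError(f"unknown tissue rule {rule!r}")
    res = LocationResult(rule=rule)
    res.counts = {t: 0 for t in expr.tissues}
    for gene in sorted(normalize_symbol(g) for g in set(genes)):
        if gene not in expr:
            res.unprofiled.append(gene)
            continue
        res.profiled.append(gene)
        row = expr.row(gene)
        mean = float(row.mean())
        res.mean_expression[gene] = mean
        above = set(row.index[row.to_numpy() > mean])
        res.located_tissues[gene] = above
        res.primary_tissue[gene] = locate_argmax(expr, gene) if above else None
        if rule == RULE_ABOVE_MEAN:
            for t in above:
                res.counts[t] += 1
        else:
            if res.primary_tissue[gene] is not None:
                res.counts[res.primary_tissue[gene]] += 1
    if res.unprofiled:
        logger.info(
            "%d of %d genes had no expression profile",
            len(res.unprofiled), len(res.profiled) + len(res.unprofiled),
        )
    return res
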