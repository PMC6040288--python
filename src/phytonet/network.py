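"""Compound-target bipartite network construction and degree analysis.

A compound-target (C-T) network links screened compounds to the proteins
they are predicted or known to bind.  Restricting the target side to a
disease gene set and pruning compounds left without edges yields the
compound-target-disease (e.g. C-T-AD) subnetwork.  Degree centrality is
the sole hub statistic: a compound's degree counts how many targets it
hits, a target's degree how many compounds hit it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .core import (
    BipartiteNetwork,
    CompoundTable,
    DataError,
    GeneSet,
    InteractionTable,
)

logger = logging.getLogger("phytonet.network")

__all__ = [
    "NetworkSummary",
    "round_half_up",
    "build_ct_network",
    "summarize",
    "degree_table",
    "restrict_to_disease",
    "top_hubs",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up at ``ndigits`` places (0.5 always rounds away)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class NetworkSummary:
    """Headline bookkeeping of a bipartite network.

    ``mean_edges_per_compound`` is |edges| / |compounds| rounded half-up
    to 2 decimals; ``mean_targets_per_compound`` is |targets| /
    |compounds| rounded half-up to 1 decimal; ``mean_edges_per_target``
    is |edges| / |targets| rounded half-up to 2 decimals.
    """

    n_nodes: int
    n_compounds: int
    n_targets: int
    n_edges: int
    mean_edges_per_compound: float
    mean_targets_per_compound: float
    mean_edges_per_target: float


def build_ct_network(
    compounds: CompoundTable, interactions: InteractionTable
) -> BipartiteNetwork:
    """Assemble the C-T network from a compound table and an edge list.

    Interactions whose compound id is absent from ``compounds`` are
    dropped with a warning count; compounds and targets touching no
    retained edge do not appear as nodes.
    """
    known = set(compounds.ids)
    kept: list[tuple[str, str]] = []
    unknown = 0
    for c, t in interactions:
        if c in known:
            kept.append((c, t))
        else:
            unknown += 1
    if unknown:
        logger.warning(
            "dropped %d interaction(s) referencing compound ids not in the table",
            unknown,
        )
    net = BipartiteNetwork(
        compound_nodes={c for c, _ in kept},
        target_nodes={t for _, t in kept},
        edges=kept,
    )
    if net.n_edges == 0:
        logger.warning("constructed network is empty")
    return net


def summarize(net: BipartiteNetwork) -> NetworkSummary:
    """Node/edge counts and per-compound means of a network."""
    n_c = len(net.compound_nodes)
    n_t = len(net.target_nodes)
    if n_c == 0:
        raise DataError("cannot summarize a network with no compound nodes")
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_compounds=n_c,
        n_targets=n_t,
        n_edges=net.n_edges,
        mean_edges_per_compound=round_half_up(net.n_edges / n_c, 2),
        mean_targets_per_compound=round_half_up(n_t / n_c, 1),
        mean_edges_per_target=round_half_up(net.n_edges / n_t, 2) if n_t else 0.0,
    )


def degree_table(net: BipartiteNetwork) -> pd.DataFrame:
    """Per-node degrees, sorted by descending degree then id.

    Columns: ``node``, ``type``, ``degree``.  Every node in the network
    appears (degree >= 1 by construction).
    """
    deg: dict[str, int] = {n: 0 for n in net.compound_nodes | net.target_nodes}
    for c, t in net.edges:
        deg[c] += 1
        deg[t] += 1
    rows = [
        {
            "node": n,
            "type": "compound" if n in net.compound_nodes else "target",
            "degree": d,
        }
        for n, d in deg.items()
    ]
    df = pd.DataFrame(rows, columns=["node", "type", "degree"])
    df = df.sort_values(
        ["degree", "node"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def restrict_to_disease(net: BipartiteNetwork, disease: GeneSet) -> BipartiteNetwork:
    """Keep only disease-set targets; prune compounds left edgeless.

    Idempotent: restricting the result again with the same set is a
    no-op.  A disease set disjoint from the targets yields an empty
    network with a warning.
    """
    keep_targets = net.target_nodes & disease.genes
    edges = {(c, t) for c, t in net.edges if t in keep_targets}
    compounds = {c for c, _ in edges}
    targets = {t for _, t in edges}
    if not edges:
        logger.warning("disease restriction produced an empty network")
    dropped = len(net.compound_nodes) - len(compounds)
    if dropped:
        logger.info(
            "disease restriction dropped %d compound(s) left without targets", dropped
        )
    return BipartiteNetwork(compounds, targets, edges)


def top_hubs(dt: pd.DataFrame, k: int, node_type: str) -> list[str]:
    """First ``k`` nodes of ``node_type`` in a degree table's ordering."""
    if k < 1:
        raise DataError(f"k must be >= 1, got {k}")
    if node_type not in ("compound", "target"):
        raise DataError(f"node_type must be 'compound' or 'target', got {node_type!r}")
    sub = dt[dt["type"] == node_type]
    if k > len(sub):
        logger.warning(
            "requested %d hubs but only %d %s node(s) available", k, len(sub), node_type
        )
    return sub["node"].head(k).tolist()
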