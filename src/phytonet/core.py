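"""Shared domain types and file I/O for the herb-to-disease pipeline.

The pipeline moves five kinds of data around: compound property tables
(oral bioavailability, blood-brain-barrier score, drug-likeness),
compound-target interaction edge lists, gene sets (disease genes,
annotation collections in GMT), gene x tissue expression matrices, and
bipartite compound-target networks.  Everything tabular is TSV/UTF-8;
networks export to SIF and GraphML for downstream viewers such as
Cytoscape.

Gene/target symbols are normalized (whitespace-trimmed, upper-cased) on
ingestion, approximating the symbol standardization that merged target
databases require.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("phytonet")

__all__ = [
    "PhytonetError",
    "ConfigurationError",
    "DataError",
    "DomainError",
    "CompoundRecord",
    "CompoundTable",
    "InteractionTable",
    "GeneSet",
    "AnnotationCollection",
    "BipartiteNetwork",
    "ExpressionMatrix",
    "EnrichmentQuery",
    "EnrichmentRow",
    "normalize_symbol",
    "read_compound_table",
    "write_compound_table",
    "load_reference_compounds",
    "read_interaction_table",
    "write_interaction_table",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_network",
    "read_network_graphml",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PhytonetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhytonetError):
    """A config/dialect/parameter problem the user must fix."""


class DataError(PhytonetError):
    """Malformed or inconsistent input data."""


class DomainError(PhytonetError, ValueError):
    """A quantity outside its mathematically valid domain."""


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_symbol(symbol: str) -> str:
    """Trim and upper-case a gene/target symbol (idempotent)."""
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Compounds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    """One compound with its ADME screening properties.

    ``ob`` is predicted oral bioavailability in percent, ``bbb`` the
    blood-brain-barrier penetration score (may be negative), ``dl`` the
    Tanimoto-based drug-likeness index.  ``whitelisted`` marks compounds
    retained on literature evidence despite failing thresholds.
    """

    compound_id: str
    name: str
    ob: float
    bbb: float
    dl: float
    whitelisted: bool = False

    def __post_init__(self) -> None:
        for attr in ("ob", "bbb", "dl"):
            v = getattr(self, attr)
            if not math.isfinite(v):
                raise DataError(
                    f"compound {self.compound_id!r}: {attr} must be finite, got {v!r}"
                )


class CompoundTable:
    """Ordered, id-unique collection of :class:`CompoundRecord`."""

    def __init__(self, records: Iterable[CompoundRecord]):
        self._records: list[CompoundRecord] = list(records)
        seen: set[str] = set()
        for r in self._records:
            if r.compound_id in seen:
                raise DataError(f"duplicate compound id {r.compound_id!r}")
            seen.add(r.compound_id)
        self._by_id = {r.compound_id: r for r in self._records}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self._records)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._by_id

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        return self._by_id[compound_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompoundTable):
            return NotImplemented
        return self._records == other._records

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self._records]

    def subset(self, ids: Iterable[str]) -> "CompoundTable":
        """Input-order subset restricted to ``ids``."""
        keep = set(ids)
        return CompoundTable(r for r in self._records if r.compound_id in keep)

    def with_whitelisted(self, ids: Iterable[str]) -> "CompoundTable":
        mark = set(ids)
        return CompoundTable(
            replace(r, whitelisted=True) if r.compound_id in mark else r
            for r in self._records
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.compound_id for r in self._records],
                "name": [r.name for r in self._records],
                "ob": [r.ob for r in self._records],
                "bbb": [r.bbb for r in self._records],
                "dl": [r.dl for r in self._records],
                "whitelisted": [r.whitelisted for r in self._records],
            }
        )

    def __repr__(self) -> str:
        return f"CompoundTable({len(self)} compounds)"


DEFAULT_COMPOUND_DIALECT: Mapping[str, str] = {
    "id": "id",
    "name": "name",
    "ob": "ob",
    "bbb": "bbb",
    "dl": "dl",
}


def read_compound_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> CompoundTable:
    """Read a compound property TSV.

    ``dialect`` maps the logical column names (``id``, ``name``, ``ob``,
    ``bbb``, ``dl``) to the column headers actually present in the file;
    unmapped names default to themselves.  Row order is preserved.
    """
    dia = dict(DEFAULT_COMPOUND_DIALECT)
    if dialect:
        dia.update(dialect)
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical, column in dia.items():
        if column not in df.columns:
            raise ConfigurationError(
                f"{path}: missing column {column!r} (mapped from {logical!r})"
            )
    records: list[CompoundRecord] = []
    for i, row in df.iterrows():
        values: dict[str, float] = {}
        for logical in ("ob", "bbb", "dl"):
            raw = row[dia[logical]]
            try:
                values[logical] = float(raw)
            except ValueError:
                raise DataError(
                    f"{path}: row {i + 2}, column {dia[logical]!r}: "
                    f"cannot parse {raw!r} as a number"
                ) from None
        records.append(
            CompoundRecord(
                compound_id=row[dia["id"]].strip(),
                name=row[dia["name"]].strip(),
                **values,
            )
        )
    return CompoundTable(records)


def write_compound_table(table: CompoundTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def load_reference_compounds() -> CompoundTable:
    """The packaged 32-compound Acori Tatarinowii Rhizoma property table."""
    ref = resources.files("phytonet.data") / "atr_compounds.tsv"
    with resources.as_file(ref) as p:
        return read_compound_table(p)


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

class InteractionTable:
    """Deduplicated, order-preserving compound -> target edge list."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        self._edges: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        dropped = 0
        for compound_id, target in edges:
            pair = (compound_id.strip(), normalize_symbol(target))
            if not pair[1]:
                raise DataError(f"empty target symbol for compound {pair[0]!r}")
            if pair in seen:
                dropped += 1
                continue
            seen.add(pair)
            self._edges.append(pair)
        if dropped:
            logger.info("collapsed %d duplicate interaction pair(s)", dropped)

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionTable):
            return NotImplemented
        return self._edges == other._edges

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._edges)

    @property
    def compound_ids(self) -> set[str]:
        return {c for c, _ in self._edges}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self._edges}

    def __repr__(self) -> str:
        return f"InteractionTable({len(self)} edges)"


_INTERACTION_HEADERS = {"compound", "compound_id", "id", "source"}


def read_interaction_table(path: str | Path) -> InteractionTable:
    """Read a two-column (compound_id, target_symbol) TSV; header optional.

    Target symbols are whitespace-trimmed and upper-cased; exact duplicate
    pairs after normalization collapse to one edge (count logged).
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}: row {lineno}: expected 2 tab-separated columns")
            compound, target = parts[0].strip(), parts[1].strip()
            if lineno == 1 and compound.lower() in _INTERACTION_HEADERS:
                continue
            if not target:
                raise DataError(f"{path}: row {lineno}: empty target symbol")
            if not compound:
                raise DataError(f"{path}: row {lineno}: empty compound id")
            rows.append((compound, target))
    return InteractionTable(rows)


def write_interaction_table(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound_id\ttarget\n")
        for c, t in table:
            fh.write(f"{c}\t{t}\n")


# ---------------------------------------------------------------------------
# Gene sets and annotation collections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A labelled set of (normalized) gene symbols."""

    set_id: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataError(f"gene set {self.set_id!r} is empty")
        object.__setattr__(
            self, "genes", frozenset(normalize_symbol(g) for g in self.genes)
        )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class AnnotationCollection:
    """A family of annotation gene sets plus an optional explicit background."""

    sets: dict[str, GeneSet]
    background: GeneSet | None = None

    def effective_background(self) -> frozenset[str]:
        """Explicit background, else the union of all annotated genes."""
        if self.background is not None:
            return self.background.genes
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


def read_gene_list(path: str | Path, set_id: str | None = None) -> GeneSet:
    """Read a plain one-symbol-per-line gene list."""
    path = Path(path)
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                genes.append(sym)
    if not genes:
        raise DataError(f"{path}: no gene symbols found")
    return GeneSet(set_id or path.stem, frozenset(genes))


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file (set_id <TAB> description <TAB> gene ...)."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields"
                )
            set_id, desc, *genes = fields
            if set_id in sets:
                raise DataError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            if any(not g.strip() for g in genes):
                raise DataError(f"{path}: line {lineno}: empty gene symbol")
            sets[set_id] = GeneSet(set_id, frozenset(genes), description=desc)
    return AnnotationCollection(sets=sets)


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, gs in collection.sets.items():
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{set_id}\t{gs.description or set_id}\t{genes}\n")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Gene x tissue matrix of non-negative expression values.

    Backed by a pandas DataFrame (genes on the index, tissues on the
    columns).  Multiple probes mapping to the same gene are collapsed by
    arithmetic mean on construction; missing cells are an error, never
    silently imputed.
    """

    def __init__(self, values: pd.DataFrame):
        df = values.copy()
        df.index = [normalize_symbol(str(g)) for g in df.index]
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise DataError(f"duplicate tissue labels: {dupes}")
        if df.index.duplicated().any():
            n_probes = len(df)
            df = df.groupby(level=0, sort=False).mean()
            logger.info(
                "collapsed %d probe rows to %d genes by mean", n_probes, len(df)
            )
        if df.isna().any().any():
            raise DataError("expression matrix contains missing cells")
        arr = df.to_numpy(dtype=float)
        if (arr < 0).any():
            raise DataError("expression values must be non-negative")
        self._df = df.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def tissues(self) -> list[str]:
        return list(self._df.columns)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self._df.index

    def row(self, gene: str) -> pd.Series:
        key = normalize_symbol(gene)
        if key not in self._df.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        return self._df.loc[key]

    def __repr__(self) -> str:
        return f"ExpressionMatrix({len(self.genes)} genes x {len(self.tissues)} tissues)"


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with gene symbols in the first column, tissues as headers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.frame.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Bipartite compound-target network
# ---------------------------------------------------------------------------

class BipartiteNetwork:
    """Compound-target bipartite graph with typed nodes.

    Invariants enforced on construction: compound and target node sets are
    disjoint, every edge endpoint belongs to its side, and no isolated
    nodes exist (degree sums on both sides therefore equal the edge count).
    """

    def __init__(
        self,
        compound_nodes: Iterable[str],
        target_nodes: Iterable[str],
        edges: Iterable[tuple[str, str]],
    ):
        self.compound_nodes = frozenset(compound_nodes)
        self.target_nodes = frozenset(target_nodes)
        self.edges = frozenset((c, t) for c, t in edges)
        overlap = self.compound_nodes & self.target_nodes
        if overlap:
            raise DataError(f"node sets not disjoint: {sorted(overlap)[:5]}")
        for c, t in self.edges:
            if c not in self.compound_nodes:
                raise DataError(f"edge references unknown compound {c!r}")
            if t not in self.target_nodes:
                raise DataError(f"edge references unknown target {t!r}")
        touched_c = {c for c, _ in self.edges}
        touched_t = {t for _, t in self.edges}
        if touched_c != self.compound_nodes or touched_t != self.target_nodes:
            raise DataError("isolated nodes are not allowed in a BipartiteNetwork")

    @property
    def n_nodes(self) -> int:
        return len(self.compound_nodes) + len(self.target_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        if node in self.compound_nodes:
            return sum(1 for c, _ in self.edges if c == node)
        if node in self.target_nodes:
            return sum(1 for _, t in self.edges if t == node)
        raise KeyError(node)

    def to_graph(self) -> nx.Graph:
        """Materialize as a networkx graph with 'type' and 'degree' attributes."""
        g = nx.Graph()
        for c in self.compound_nodes:
            g.add_node(c, type="compound")
        for t in self.target_nodes:
            g.add_node(t, type="target")
        g.add_edges_from(self.edges)
        nx.set_node_attributes(g, dict(g.degree()), "degree")
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (
            self.compound_nodes == other.compound_nodes
            and self.target_nodes == other.target_nodes
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return (
            f"BipartiteNetwork({len(self.compound_nodes)} compounds, "
            f"{len(self.target_nodes)} targets, {self.n_edges} edges)"
        )


def write_network(net: BipartiteNetwork, path: str | Path, format: str = "graphml") -> None:
    """Export a network as SIF ('compound  targets  target') or GraphML."""
    path = Path(path)
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for c, t in sorted(net.edges):
                fh.write(f"{c}\ttargets\t{t}\n")
    elif format == "graphml":
        nx.write_graphml(net.to_graph(), path)
    else:
        raise ConfigurationError(f"unknown network format {format!r}")


def read_network_graphml(path: str | Path) -> BipartiteNetwork:
    g = nx.read_graphml(path)
    compounds = {n for n, d in g.nodes(data=True) if d.get("type") == "compound"}
    targets = {n for n, d in g.nodes(data=True) if d.get("type") == "target"}
    edges = set()
    for u, v in g.edges():
        if u in compounds:
            edges.add((u, v))
        else:
            edges.add((v, u))
    return BipartiteNetwork(compounds, targets, edges)


# ---------------------------------------------------------------------------
# Enrichment bookkeeping types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentQuery:
    """The four counts of a hypergeometric over-representation test.

    ``N`` background genes, ``M`` of them annotated to the set, ``n`` in
    the query, ``m`` in the overlap.
    """

    N: int
    M: int
    n: int
    m: int

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise DomainError(f"background size N must be > 0, got {self.N}")
        if not 0 <= self.M <= self.N:
            raise DomainError(f"need 0 <= M <= N, got M={self.M}, N={self.N}")
        if not 0 <= self.n <= self.N:
            raise DomainError(f"need 0 <= n <= N, got n={self.n}, N={self.N}")
        if not 0 <= self.m <= min(self.M, self.n):
            raise DomainError(
                f"need 0 <= m <= min(M, n), got m={self.m}, M={self.M}, n={self.n}"
            )
        if self.m < max(0, self.n + self.M - self.N):
            raise DomainError(
                f"overlap m={self.m} below hypergeometric support floor "
                f"max(0, n + M - N) = {max(0, self.n + self.M - self.N)}"
            )


@dataclass(frozen=True)
class EnrichmentRow:
    """One annotation set's over-representation result."""

    set_id: str
    query: EnrichmentQuery
    p_raw: float
    p_adj: float
    fold: float
    significant: bool
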