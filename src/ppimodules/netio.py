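"""Read scored interaction tables, filter them, and build the PPI graph.

Interaction tables are TSV files with a header row; a *dialect* mapping
names the columns that hold the two interactors, the confidence score,
the evidence sources and the interaction type.  Filtering follows the
multi-database evidence rule: an interaction is kept only when it is
reported by at least ``min_sources`` databases and its normalized
confidence score reaches ``min_score``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Default dialect for the package's own edge/interaction TSV output.
DEFAULT_DIALECT = {
    "protein_a": "protein_a",
    "protein_b": "protein_b",
    "score": "score",
    "sources": "sources",
    "source_delimiter": ";",
    "type": "interaction_type",
}


class DialectError(KeyError):
    """A required column named in the dialect is absent from the table."""


@dataclass(frozen=True)
class InteractionRecord:
    """One scored protein-protein interaction with database evidence.

    Attributes
    ----------
    protein_a, protein_b
        Interactor identifiers (case-sensitive, no alias resolution).
    confidence
        Normalized confidence score in [0, 1].
    sources
        Names of the databases reporting the interaction.
    interaction_type
        Free-text interaction category, e.g. ``"direct physical"``.
    """

    protein_a: str
    protein_b: str
    confidence: float
    sources: frozenset[str]
    interaction_type: str = ""

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("protein identifiers must be non-empty")
        if not self.sources:
            raise ValueError("sources must be non-empty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class ProteinNetwork:
    """Undirected simple graph of proteins.

    Thin wrapper over :class:`networkx.Graph` guaranteeing no self-loops
    and unique unordered edges.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinNetwork):
            return NotImplemented
        return self.proteins == other.proteins and self.edges == other.edges


def read_interactions(path, dialect: dict | None = None) -> list[InteractionRecord]:
    """Read a scored interaction TSV into records.

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        Column mapping with keys ``protein_a``, ``protein_b``, ``score``,
        ``sources``, ``source_delimiter`` and ``type``.  Defaults to the
        package's own column names.

    Rows with a missing protein identifier are dropped and counted in the
    log.  Source strings are split on the delimiter and whitespace-trimmed.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    table = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("protein_a", "protein_b", "score", "sources"):
        if dialect[key] not in table.columns:
            raise DialectError(
                f"dialect column {dialect[key]!r} (for {key!r}) not found in {path}"
            )
    type_col = dialect.get("type")
    has_type = type_col in table.columns
    delim = dialect["source_delimiter"]

    records: list[InteractionRecord] = []
    n_dropped = 0
    for row in table.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(table.columns, row))
        a = r.get(dialect["protein_a"])
        b = r.get(dialect["protein_b"])
        if pd.isna(a) or pd.isna(b) or not str(a).strip() or not str(b).strip():
            n_dropped += 1
            continue
        sources = frozenset(
            s.strip() for s in str(r[dialect["sources"]]).split(delim) if s.strip()
        )
        itype = str(r[type_col]) if has_type and not pd.isna(r.get(type_col)) else ""
        records.append(
            InteractionRecord(
                protein_a=str(a).strip(),
                protein_b=str(b).strip(),
                confidence=float(r[dialect["score"]]),
                sources=sources,
                interaction_type=itype,
            )
        )
    if n_dropped:
        logger.info("dropped %d rows with missing protein identifiers", n_dropped)
    return records


def filter_high_confidence(
    records: list[InteractionRecord],
    min_score: float = 0.73,
    min_sources: int = 2,
    required_type: str | None = None,
) -> list[InteractionRecord]:
    """Keep interactions passing the evidence filters.

    A record survives iff its confidence is at least ``min_score``, it is
    reported by at least ``min_sources`` databases (default 2, the
    multi-database rule), and — when ``required_type`` is given — its
    interaction type matches exactly.
    """
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must be in [0, 1]")
    return [
        r
        for r in records
        if r.confidence >= min_score
        and len(r.sources) >= min_sources
        and (required_type is None or r.interaction_type == required_type)
    ]


def build_network(records: list[InteractionRecord]) -> ProteinNetwork:
    """Build an undirected simple graph from (already filtered) records.

    Duplicate pairs in either order collapse to one edge; self-interactions
    are dropped and logged.  The node set is the union of endpoints of the
    surviving edges, so proteins appearing only in self-interactions are
    excluded.
    """
    g = nx.Graph()
    n_self = 0
    for r in records:
        if r.protein_a == r.protein_b:
            n_self += 1
            continue
        g.add_edge(r.protein_a, r.protein_b)
    if n_self:
        logger.info("dropped %d self-interactions", n_self)
    return ProteinNetwork(graph=g)


def write_edgelist(network: ProteinNetwork, path) -> None:
    """Write the network as a two-column edge-list TSV (sorted, stable)."""
    rows = sorted(tuple(sorted((u, v))) for u, v in network.graph.edges)
    pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_edgelist(path) -> ProteinNetwork:
    """Read a two-column edge-list TSV back into a network."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.Graph()
    for a, b in zip(table.iloc[:, 0], table.iloc[:, 1]):
        if a != b:
            g.add_edge(str(a), str(b))
    return ProteinNetwork(graph=g)


def write_graphml(network: ProteinNetwork, path) -> None:
    """Write the network in GraphML for interoperability."""
    nx.write_graphml(network.graph, path)
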