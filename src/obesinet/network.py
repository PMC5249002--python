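"""Association-network construction: edge filtering, merging, summaries.

Three undirected simple networks are built from per-source weighted edge
lists: *Experimental* (physical protein-protein interactions, merged from a
STRING-like and a GeneMANIA-like extract), *Knowledge* (pathway partners)
and *Homology*.  Edges pass strict score filters (> 0.4 for STRING-like
scores, > 0.01 for GeneMANIA-like weights); merging drops duplicate edges,
keeping the maximum score seen for a pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

from .core import ValidationError, normalize_symbol

ASSOC_TYPES = ("Experimental", "Knowledge", "Homology")
EDGE_SOURCES = ("STRING_like", "GeneMANIA_like")

#: Strict per-source score thresholds (edges with score > threshold kept).
DEFAULT_MIN_SCORES = {"STRING_like": 0.4, "GeneMANIA_like": 0.01}


@dataclass(frozen=True)
class EdgeRecord:
    a: str
    b: str
    score: float
    source: str = "STRING_like"
    assoc_type: str = "Experimental"

    def __post_init__(self):
        a, b = normalize_symbol(self.a), normalize_symbol(self.b)
        if a == b:
            raise ValidationError(f"self-loop on {a}")
        if a > b:  # canonical lexicographic order
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


class Network:
    """Simple undirected graph of one association type with edge scores."""

    def __init__(self, assoc_type: str, graph: nx.Graph | None = None) -> None:
        if assoc_type not in ASSOC_TYPES:
            raise ValidationError(f"unknown association type {assoc_type!r}")
        self.assoc_type = assoc_type
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def neighbors(self, symbol: str) -> set[str]:
        symbol = normalize_symbol(symbol)
        return set(self.graph.neighbors(symbol)) if symbol in self.graph else set()

    def degree(self, symbol: str) -> int:
        symbol = normalize_symbol(symbol)
        return self.graph.degree(symbol) if symbol in self.graph else 0

    def add_edge(self, a: str, b: str, score: float) -> None:
        rec = EdgeRecord(a, b, score)
        prev = self.graph.get_edge_data(*rec.pair)
        if prev is None or prev["score"] < score:
            self.graph.add_edge(*rec.pair, score=float(score))

    def edge_scores(self) -> dict[tuple[str, str], float]:
        return {
            tuple(sorted((a, b))): d["score"] for a, b, d in self.graph.edges(data=True)
        }

    def copy(self) -> "Network":
        return Network(self.assoc_type, self.graph.copy())

    def write_tsv(self, path) -> None:
        rows = [
            {"gene_a": a, "gene_b": b, "score": s}
            for (a, b), s in sorted(self.edge_scores().items())
        ]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
            path, sep="\t", index=False
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


# ---------------------------------------------------------------------------
# ingestion and filtering
# ---------------------------------------------------------------------------


def read_edge_list(
    path, source: str = "STRING_like", assoc_type: str = "Experimental"
) -> list[EdgeRecord]:
    """Read a `gene_a  gene_b  score [source]` TSV, dropping self-loops."""
    table = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b", "score"):
        if col not in table.columns:
            raise ValidationError(f"missing column {col!r} in {path}")
    edges = []
    n_loops = 0
    for row in table.itertuples(index=False):
        row_source = getattr(row, "source", source) or source
        try:
            edges.append(
                EdgeRecord(row.gene_a, row.gene_b, float(row.score), row_source, assoc_type)
            )
        except ValidationError:
            n_loops += 1
    if n_loops:
        warnings.warn(f"dropped {n_loops} self-loop(s) while reading {path}")
    return edges


def filter_edges(
    edges: Iterable[EdgeRecord],
    min_score: float | None = None,
    strict: bool = True,
) -> list[EdgeRecord]:
    """Keep edges above the score threshold (strictly, by default).

    Without an explicit ``min_score`` each edge uses its source's default
    threshold (STRING-like 0.4, GeneMANIA-like 0.01).
    """
    kept = []
    for e in edges:
        cut = min_score if min_score is not None else DEFAULT_MIN_SCORES.get(e.source, 0.0)
        if cut < 0:
            raise ValidationError("min_score must be >= 0")
        if (e.score > cut) if strict else (e.score >= cut):
            kept.append(e)
    return kept


def build_network(edges: Iterable[EdgeRecord], assoc_type: str) -> Network:
    """Assemble a simple network; duplicate pairs keep the maximum score."""
    net = Network(assoc_type)
    for e in edges:
        net.add_edge(e.a, e.b, e.score)
    return net


def merge_networks(n1: Network, n2: Network) -> Network:
    """Union of node and canonical edge sets; duplicates keep max score."""
    if n1.assoc_type != n2.assoc_type:
        raise ValidationError("cannot merge networks of different association types")
    merged = n1.copy()
    merged.graph.add_nodes_from(n2.graph.nodes)
    for (a, b), score in n2.edge_scores().items():
        merged.add_edge(a, b, score)
    return merged


def restrict_to(network: Network, symbols: Iterable[str]) -> Network:
    """Induced subgraph on the given symbols (present in the network)."""
    symbols = {normalize_symbol(s) for s in symbols}
    sub = network.graph.subgraph(symbols & set(network.graph.nodes)).copy()
    return Network(network.assoc_type, sub)


# ---------------------------------------------------------------------------
# summaries and rankings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkSummary:
    assoc_type: str
    n_nodes: int
    n_edges: int
    mean_degree: float
    coverage: float  # fraction of the compendium with >= 1 edge


def network_summary(network: Network, compendium_size: int) -> NetworkSummary:
    """Node/edge counts over nodes with degree >= 1, mean degree 2E/N."""
    connected = [v for v, d in network.graph.degree if d >= 1]
    n_nodes, n_edges = len(connected), network.n_edges
    if compendium_size < n_nodes:
        raise ValidationError("compendium_size smaller than the node count")
    mean_degree = 2 * n_edges / n_nodes if n_nodes else 0.0
    coverage = n_nodes / compendium_size if compendium_size else 0.0
    return NetworkSummary(network.assoc_type, n_nodes, n_edges, mean_degree, coverage)


def dense_ranks(values: list[int]) -> list[int]:
    """Dense ranking of descending values already sorted: ties share a rank,
    the next distinct value takes the next consecutive rank."""
    ranks, rank = [], 0
    prev = None
    for v in values:
        if v != prev:
            rank += 1
            prev = v
        ranks.append(rank)
    return ranks


def degree_rank(network: Network, top_k: int = 20) -> list[tuple[str, int, int]]:
    """(symbol, degree, dense rank), degree-descending, ties alphabetical.

    The list includes every symbol whose dense rank is <= the rank of the
    k-th distinct entry, so tied tails are never cut mid-rank.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    items = sorted(network.graph.degree, key=lambda kv: (-kv[1], kv[0]))
    items = [(sym, deg) for sym, deg in items if deg >= 1]
    if not items:
        return []
    ranks = dense_ranks([deg for _, deg in items])
    cutoff = ranks[top_k - 1] if top_k <= len(ranks) else ranks[-1]
    return [
        (sym, deg, rank)
        for (sym, deg), rank in zip(items, ranks)
        if rank <= cutoff
    ]


def degree_rank_all(network: Network) -> dict[str, tuple[int, int]]:
    """symbol -> (degree, dense rank) over every non-isolated node."""
    items = sorted(network.graph.degree, key=lambda kv: (-kv[1], kv[0]))
    items = [(sym, deg) for sym, deg in items if deg >= 1]
    ranks = dense_ranks([deg for _, deg in items])
    return {sym: (deg, rank) for (sym, deg), rank in zip(items, ranks)}


def connected_components(network: Network) -> list[set[str]]:
    """Maximal connected sets of non-isolated nodes, largest first; ties by
    smallest member symbol."""
    comps = [
        set(c) for c in nx.connected_components(network.graph) if len(c) >= 2
    ]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
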