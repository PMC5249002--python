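"""Molecular complex detection (MCODE-style k-core clustering).

The procedure has three stages:

1. *Vertex weighting.*  Each vertex is weighted by the core-clustering
   coefficient of its closed neighborhood: the highest core number k found
   there multiplied by the density of that highest k-core subgraph.  Dense,
   locally clique-like neighborhoods weigh high.
2. *Complex prediction.*  Starting from the highest-weighted unvisited
   vertex, the complex grows outward, recursively including neighbors whose
   weight exceeds seed_weight x (1 - VWP), up to a depth limit.  Visited
   vertices never join later complexes, so complexes are disjoint.
3. *Post-processing.*  Haircut trims members with fewer than two
   within-complex edges (the 2-core of the complex); optional fluff adds
   boundary neighbors with dense enough neighborhoods.  A complex is scored
   density x size; the screening filter keeps complexes with at least
   ``min_size`` members and score at least ``min_score`` (size 4 / score 3.3
   here), and clusters may be expanded by all members' first neighbors.

Ties in vertex weight break alphabetically so output is deterministic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .core import ValidationError
from .network import Network


@dataclass(frozen=True)
class McodeParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2  # VWP
    k_core_min: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    max_depth: int = 100

    def __post_init__(self):
        if not 0 <= self.node_score_cutoff < 1:
            raise ValidationError("VWP must lie in [0, 1)")
        if self.degree_cutoff < 0 or self.k_core_min < 0 or self.max_depth < 0:
            raise ValidationError("cutoffs must be >= 0")


@dataclass
class Cluster:
    members: set[str]
    seed: str
    density: float
    score: float
    expanded_members: set[str] | None = field(default=None)

    @property
    def size(self) -> int:
        return len(self.members)


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2 * graph.number_of_edges() / (n * (n - 1))


def core_decomposition(network: Network) -> dict[str, int]:
    """Core number per vertex (largest k surviving degree-<k peeling)."""
    return dict(nx.core_number(network.graph))


def vertex_weight(network: Network, v: str) -> float:
    """Core-clustering coefficient of v's closed neighborhood.

    weight = k_max x density(highest k-core of N[v]); 0 for isolated v.
    """
    graph = network.graph
    if v not in graph:
        raise ValidationError(f"unknown vertex {v!r}")
    closed = set(graph.neighbors(v)) | {v}
    if len(closed) < 2:
        return 0.0
    sub = graph.subgraph(closed)
    cores = nx.core_number(sub)
    k_max = max(cores.values())
    if k_max == 0:
        return 0.0
    highest = sub.subgraph([u for u, c in cores.items() if c >= k_max])
    return k_max * _density(highest)


def _haircut(graph: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively drop members with < 2 within-cluster edges (the 2-core)."""
    members = set(members)
    changed = True
    while changed and members:
        sub = graph.subgraph(members)
        drop = {u for u in members if sub.degree(u) < 2}
        members -= drop
        changed = bool(drop)
    return members


def predict_complexes(network: Network, params: McodeParams = McodeParams()) -> list[Cluster]:
    """Seeded complex prediction over the whole network.

    Emitted clusters are pairwise disjoint (with fluff off), contain at
    least two members, and contain a ``k_core_min``-core.
    """
    graph = network.graph
    # vertices below the degree cutoff neither seed nor join complexes
    weights = {
        v: (vertex_weight(network, v) if graph.degree(v) >= params.degree_cutoff else 0.0)
        for v in graph.nodes
    }
    order = sorted(graph.nodes, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    clusters: list[Cluster] = []

    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1 - params.node_score_cutoff)
        members = {seed}
        queue = deque([(seed, 0)])
        seen_local = {seed}
        while queue:
            u, depth = queue.popleft()
            if depth >= params.max_depth:
                continue
            for w in sorted(graph.neighbors(u)):
                if w in seen_local or w in visited:
                    continue
                seen_local.add(w)
                if weights[w] > threshold:
                    members.add(w)
                    queue.append((w, depth + 1))
        visited |= members

        if params.haircut:
            members = _haircut(graph, members)
        if len(members) < 2:
            continue
        sub = graph.subgraph(members)
        cores = nx.core_number(sub)
        if max(cores.values()) < params.k_core_min:
            continue
        if params.fluff:
            fringe = set()
            for u in members:
                for w in graph.neighbors(u):
                    if w in members or w in fringe:
                        continue
                    closed = set(graph.neighbors(w)) | {w}
                    if _density(graph.subgraph(closed)) > params.fluff_density:
                        fringe.add(w)
            members = members | fringe
            sub = graph.subgraph(members)
        density = _density(sub)
        clusters.append(
            Cluster(members=set(members), seed=seed, density=density,
                    score=density * len(members))
        )
    clusters.sort(key=lambda c: (-c.score, c.seed))
    return clusters


def filter_clusters(
    clusters: list[Cluster], min_size: int = 4, min_score: float = 3.3
) -> list[Cluster]:
    """Screening filter: size >= min_size and score >= min_score."""
    kept = [c for c in clusters if c.size >= min_size and c.score >= min_score]
    return sorted(kept, key=lambda c: (-c.score, c.seed))


def expand_first_neighbors(cluster: Cluster, network: Network) -> Cluster:
    """Attach members' first neighbors as ``expanded_members``."""
    if not cluster.members <= network.nodes():
        raise ValidationError("cluster members must belong to the network")
    expanded = set(cluster.members)
    for u in cluster.members:
        expanded |= network.neighbors(u)
    return Cluster(
        members=set(cluster.members),
        seed=cluster.seed,
        density=cluster.density,
        score=cluster.score,
        expanded_members=expanded,
    )
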