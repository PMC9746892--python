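"""Building cleaned simple undirected PPI networks from interaction records.

Interaction databases frequently store the same physical interaction several
times: literally repeated rows, the same pair recorded in both orientations
(A,B) and (B,A), and self-loops arising when distinct molecular variants
share one accession.  A network analysis needs a *simple* undirected graph,
so construction collapses every record onto an unordered canonical pair,
drops self-pairs, and keeps an exact accounting of what was removed.
Disconnected fragments are split off afterwards with
:func:`largest_component`, mirroring the usual pre-processing of PPI graphs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx

from .mitab import InteractionRecord

__all__ = [
    "CanonicalPair",
    "SelfPair",
    "PPINetwork",
    "BuildLog",
    "ComponentDecomposition",
    "canonical_pair",
    "build_network",
    "connected_components",
    "largest_component",
    "compare_datasets",
]

CanonicalPair = tuple[str, str]


@dataclass(frozen=True)
class SelfPair:
    """Marker for a self-interaction; never stored as a network edge."""

    node: str


def canonical_pair(a: str, b: str) -> Union[CanonicalPair, SelfPair]:
    """Unordered canonical form of an interactor pair.

    ``(B, A)`` and ``(A, B)`` map to the same ``(A, B)`` tuple (lexicographic
    order); ``a == b`` returns a :class:`SelfPair` marker instead of an edge.
    """
    if not a or not b:
        raise ValueError("interactor identifiers must be non-empty")
    if a == b:
        return SelfPair(a)
    return (a, b) if a < b else (b, a)


class PPINetwork:
    """A simple undirected network of protein accessions.

    Thin wrapper around a :class:`networkx.Graph` that guarantees the simple
    undirected contract (no parallel edges, no self-loops) and exposes the
    conventional N (node count), L (edge count) and adjacency queries.
    """

    def __init__(self, graph: nx.Graph):
        if graph.is_directed() or graph.is_multigraph():
            raise ValueError("PPINetwork requires a simple undirected graph")
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise ValueError(f"graph contains {len(loops)} self-loop(s)")
        self.graph = graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PPINetwork":
        g = nx.Graph()
        for a, b in edges:
            pair = canonical_pair(str(a), str(b))
            if isinstance(pair, SelfPair):
                raise ValueError(f"self-pair {pair.node!r} is not a valid edge")
            g.add_edge(*pair)
        return cls(g)

    # -- basic queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[CanonicalPair]:
        out: set[CanonicalPair] = set()
        for u, v in self.graph.edges:
            out.add((u, v) if u < v else (v, u))
        return out

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def neighbors(self, node: str) -> list[str]:
        return list(self.graph.neighbors(node))

    def subnetwork(self, nodes: Iterable[str]) -> "PPINetwork":
        """Induced subnetwork on ``nodes`` (copied, independent graph)."""
        return PPINetwork(self.graph.subgraph(nodes).copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"PPINetwork(N={self.n_nodes}, L={self.n_edges})"

    # -- export -------------------------------------------------------------
    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for a, b in sorted(self.edges):
                handle.write(f"{a}\t{b}\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class BuildLog:
    """Exact accounting of what network construction collapsed or dropped."""

    n_records: int
    n_duplicate_records: int
    n_reversed_repetitions: int
    n_self_loop_records: int
    n_nodes: int
    n_edges: int
    self_loop_nodes: list[str] = field(default_factory=list)

    @property
    def n_distinct_records(self) -> int:
        """Records remaining after repetition (duplicate + reversed) removal."""
        return self.n_records - self.n_duplicate_records - self.n_reversed_repetitions

    def to_json(self, path: str | Path) -> None:
        payload = dict(self.__dict__, n_distinct_records=self.n_distinct_records)
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2)


RecordLike = Union[InteractionRecord, tuple[str, str], Sequence[str]]


def _pair_of(record: RecordLike) -> tuple[str, str]:
    if isinstance(record, InteractionRecord):
        return record.id_a, record.id_b
    a, b = record[0], record[1]
    return str(a), str(b)


def build_network(records: Iterable[RecordLike]) -> tuple[PPINetwork, BuildLog]:
    """Collapse interaction records onto a simple undirected network.

    Each record contributes one canonical pair.  The first record seen for a
    pair creates the edge; later records of the same pair are logged as
    duplicates (same orientation) or reversed repetitions (opposite
    orientation).  Self-pairs never become edges but their node is kept, and
    every self-loop record is counted.

    Returns the network and a :class:`BuildLog`.  Raises ``ValueError`` when
    no usable (non-self) pair exists.
    """
    graph = nx.Graph()
    first_orientation: dict[CanonicalPair, tuple[str, str]] = {}
    n_records = n_dup = n_rev = n_self = 0
    self_loop_nodes: set[str] = set()

    for record in records:
        a, b = _pair_of(record)
        n_records += 1
        pair = canonical_pair(a, b)
        if isinstance(pair, SelfPair):
            n_self += 1
            self_loop_nodes.add(pair.node)
            graph.add_node(pair.node)
            continue
        seen = first_orientation.get(pair)
        if seen is None:
            first_orientation[pair] = (a, b)
            graph.add_edge(*pair)
        elif (a, b) == seen:
            n_dup += 1
        else:
            n_rev += 1

    if graph.number_of_edges() == 0:
        raise ValueError("no usable edges: every record was a self-pair or input was empty")

    net = PPINetwork(graph)
    log = BuildLog(
        n_records=n_records,
        n_duplicate_records=n_dup,
        n_reversed_repetitions=n_rev,
        n_self_loop_records=n_self,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        self_loop_nodes=sorted(self_loop_nodes),
    )
    return net, log


@dataclass
class ComponentDecomposition:
    """Connected components ordered by decreasing size.

    Ties in size are ordered by the lexicographically smallest member, so the
    decomposition is deterministic.  ``edge_counts[i]`` is the number of edges
    inside ``components[i]``.
    """

    components: list[frozenset[str]]
    edge_counts: list[int]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    def largest_node_share(self) -> float:
        return len(self.components[0]) / sum(self.sizes)

    def largest_edge_share(self) -> float:
        total = sum(self.edge_counts)
        return self.edge_counts[0] / total if total else 0.0


def connected_components(net: PPINetwork) -> ComponentDecomposition:
    """Exact partition of the node set into connected components."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    comps = [frozenset(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    edge_counts = [net.graph.subgraph(c).number_of_edges() for c in comps]
    return ComponentDecomposition(components=comps, edge_counts=edge_counts)


def largest_component(net: PPINetwork) -> PPINetwork:
    """Induced subnetwork on the largest connected component.

    Size ties are broken by keeping the component containing the
    lexicographically smallest node id, for reproducibility.
    """
    decomposition = connected_components(net)
    return net.subnetwork(decomposition.components[0])


def compare_datasets(nets: Mapping[str, PPINetwork]) -> dict[tuple[str, ...], dict[str, int]]:
    """Venn-region counts of shared proteins and shared interactions.

    For every non-empty subset of the named networks, counts the protein ids
    and the canonical edges found in *exactly* that subset.  Region keys are
    sorted name tuples; counts over all regions sum to the union sizes.
    """
    if len(nets) < 2:
        raise ValueError("need at least two networks to compare")
    names = sorted(nets)
    node_sets = {n: nets[n].nodes for n in names}
    edge_sets = {n: nets[n].edges for n in names}

    regions: dict[tuple[str, ...], dict[str, int]] = {}
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            inside = set(subset)
            outside = [n for n in names if n not in inside]

            def _exclusive(sets: Mapping[str, set]) -> int:
                common = set.intersection(*(sets[n] for n in subset))
                for n in outside:
                    common -= sets[n]
                return len(common)

            regions[subset] = {
                "nodes": _exclusive(node_sets),
                "edges": _exclusive(edge_sets),
            }
    return regions
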