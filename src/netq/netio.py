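"""Data model and file I/O for networks, node similarities and mappings.

Networks are simple undirected graphs with opaque string node identifiers
(protein IDs are case-sensitive; no normalization is applied). Node
similarities are sparse non-negative score tables between the node sets of
two networks. Mappings are partial functions from one node set to the
other, optionally one-to-one.

File dialects (this package's canonical formats):

* network: whitespace-separated edge list, ``#`` comments, UTF-8;
* similarity: ``u v score`` triplets;
* mapping: two tab-separated columns, one pair per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping as TMapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NodeSimilarity",
    "Mapping",
    "read_network",
    "write_network",
    "read_similarity",
    "write_similarity",
    "read_mapping",
    "write_mapping",
    "bounded_distances",
]


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class Network:
    """A simple undirected graph with string node identifiers.

    Self-loops and duplicate edges are rejected by construction; the edge
    (u, v) is identical to (v, u).
    """

    name: str = ""
    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        name: str = "",
    ) -> "Network":
        net = cls(name=name)
        for u in nodes:
            net.graph.add_node(str(u))
        for u, v in edges:
            net.add_edge(str(u), str(v))
        return net

    def add_edge(self, u: str, v: str) -> bool:
        """Add an undirected edge; self-loops/duplicates are ignored.

        Returns True if the edge was actually added.
        """
        if u == v:
            logger.warning("network %r: dropping self-loop on %r", self.name, u)
            return False
        if self.graph.has_edge(u, v):
            logger.warning("network %r: dropping duplicate edge %r-%r", self.name, u, v)
            return False
        self.graph.add_edge(u, v)
        return True

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges as canonically ordered (min, max) pairs."""
        return {_edge_key(u, v) for u, v in self.graph.edges}

    def sorted_nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def neighbors(self, u: str) -> set[str]:
        return set(self.graph.neighbors(u))

    def degree(self, u: str) -> int:
        return self.graph.degree(u)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def copy(self) -> "Network":
        return Network(name=self.name, graph=self.graph.copy())


@dataclass
class NodeSimilarity:
    """Sparse non-negative node similarity between two networks.

    ``scores[(u, v)]`` holds S(u, v) for u in the left network and v in the
    right one; absent pairs score 0.
    """

    left: str = ""
    right: str = ""
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, u: str, v: str) -> float:
        return self.scores.get((u, v), 0.0)

    def set(self, u: str, v: str, score: float) -> None:
        if score < 0:
            raise ValueError(f"negative similarity score {score} for ({u!r}, {v!r})")
        self.scores[(u, v)] = float(score)
        self._row_cache = None

    def row(self, u: str) -> dict[str, float]:
        """All positive scores of query node ``u`` (built lazily, cached)."""
        return self._rows().get(u, {})

    def _rows(self) -> dict[str, dict[str, float]]:
        rows = getattr(self, "_row_cache", None)
        if rows is None:
            rows = {}
            for (u, v), s in self.scores.items():
                rows.setdefault(u, {})[v] = s
            self._row_cache = rows
        return rows

    def transpose(self) -> "NodeSimilarity":
        return NodeSimilarity(
            left=self.right,
            right=self.left,
            scores={(v, u): s for (u, v), s in self.scores.items()},
        )

    def max_score(self) -> float:
        return max(self.scores.values(), default=0.0)

    def copy(self) -> "NodeSimilarity":
        return NodeSimilarity(self.left, self.right, dict(self.scores))

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class Mapping:
    """A partial node correspondence from a left to a right network.

    Each query (left) node appears at most once; a one-to-one mapping
    additionally uses each target node at most once.
    """

    direction: tuple[str, str] = ("", "")
    assignment: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], direction: tuple[str, str] = ("", "")
    ) -> "Mapping":
        m = cls(direction=direction)
        for u, v in pairs:
            m.add(u, v)
        return m

    def add(self, u: str, v: str) -> None:
        if u in self.assignment and self.assignment[u] != v:
            raise ValueError(
                f"query node {u!r} mapped twice ({self.assignment[u]!r} and {v!r})"
            )
        self.assignment[u] = v

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.assignment.items())

    def get(self, u: str) -> str | None:
        return self.assignment.get(u)

    def image(self) -> set[str]:
        return set(self.assignment.values())

    def is_one_to_one(self) -> bool:
        return len(self.image()) == len(self.assignment)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.assignment.items())

    def __len__(self) -> int:
        return len(self.assignment)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.sorted_pairs())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Mapping):
            return NotImplemented
        return self.assignment == other.assignment


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_network(path: str | Path, name: str | None = None) -> Network:
    """Read a whitespace-separated edge-list file.

    Lines starting with ``#`` are comments; tokens beyond the first two are
    ignored. Self-loops and repeated edges are dropped with a warning. A
    line with a single token is a parse error.
    """
    net = Network(name=name if name is not None else Path(path).stem)
    for lineno, tokens in _data_lines(path):
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected two node identifiers")
        net.add_edge(tokens[0], tokens[1])
    return net


def write_network(net: Network, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in net.sorted_edges():
            fh.write(f"{u}\t{v}\n")


def read_similarity(path: str | Path, left: Network, right: Network) -> NodeSimilarity:
    """Read ``u v score`` triplets, keeping entries valid in both networks.

    Entries whose endpoints are unknown are dropped with a warning.
    Repeated (u, v) pairs keep the maximum score (best-hit semantics).
    """
    sim = NodeSimilarity(left=left.name, right=right.name)
    for lineno, tokens in _data_lines(path):
        if len(tokens) < 3:
            raise ParseError(f"{path}:{lineno}: expected 'u v score'")
        u, v, raw = tokens[0], tokens[1], tokens[2]
        try:
            score = float(raw)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score {raw!r}") from exc
        if score < 0:
            raise ValueError(f"{path}:{lineno}: negative score {score}")
        if u not in left or v not in right:
            logger.warning(
                "%s:%d: dropping similarity (%r, %r): unknown node", path, lineno, u, v
            )
            continue
        if score > sim.get(u, v) or (u, v) not in sim.scores:
            sim.set(u, v, max(score, sim.get(u, v)))
    return sim


def write_similarity(sim: NodeSimilarity, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (u, v), s in sorted(sim.scores.items()):
            fh.write(f"{u}\t{v}\t{s:g}\n")


def read_mapping(path: str | Path, left: str = "", right: str = "") -> Mapping:
    """Read a two-column tab/whitespace separated mapping file.

    A query node appearing twice violates the partial-function invariant
    and raises ``ValueError``.
    """
    m = Mapping(direction=(left, right))
    for lineno, tokens in _data_lines(path):
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'query target'")
        try:
            m.add(tokens[0], tokens[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return m


def write_mapping(m: Mapping, path: str | Path) -> None:
    """Write one ``u<TAB>v`` line per pair, sorted by query node."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in m.sorted_pairs():
            fh.write(f"{u}\t{v}\n")


def bounded_distances(net: Network, source: str, dmax: int) -> dict[str, int]:
    """Unweighted shortest-path (BFS) distances from ``source``, <= ``dmax``.

    The source maps to 0; nodes farther than ``dmax`` hops are absent.
    """
    if source not in net:
        raise KeyError(f"unknown source node {source!r}")
    if dmax < 1:
        raise ValueError("dmax must be >= 1")
    return dict(nx.single_source_shortest_path_length(net.graph, source, cutoff=dmax))
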