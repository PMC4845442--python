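"""Core data model: named undirected simple graphs and ordered collections of them.

A :class:`Network` is the unit everything else operates on — a name, a set of
string node identifiers and a set of canonical (lexicographically sorted)
unordered edges. Graphs are undirected and simple: direction in the input is
ignored, duplicate edges collapse, self-loops are rejected at construction.
This matches the protein–protein-interaction setting the package targets,
where metrics such as density, transitivity and communities are defined on
undirected simple graphs.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import networkx as nx

Edge = tuple[str, str]

__all__ = ["Edge", "canonical_edge", "Network", "NetworkCollection"]


def canonical_edge(u: str, v: str) -> Edge:
    """Return the unordered pair (u, v) in canonical (sorted) order.

    Raises ``ValueError`` on self-loops: the data model has none.
    """
    u, v = str(u), str(v)
    if u == v:
        raise ValueError(f"self-loop edge ({u!r}, {v!r}) is not allowed")
    return (u, v) if u < v else (v, u)


class Network:
    """A named undirected simple graph over string node identifiers.

    Invariants enforced at construction:

    * every endpoint of every edge is a node,
    * edges are stored canonically (sorted pairs), so at most one edge exists
      per unordered pair,
    * no self-loops.

    Equality compares node and edge sets only — the name is a label, so two
    differently named networks with identical topology compare equal (this is
    what makes "union of one network equals that network" a meaningful law).
    Node identifiers are case-sensitive and never coerced.
    """

    __slots__ = ("name", "_nodes", "_edges")

    def __init__(
        self,
        name: str,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.name = str(name)
        canon = {canonical_edge(u, v) for u, v in edges}
        node_set = {str(n) for n in nodes}
        for u, v in canon:
            node_set.add(u)
            node_set.add(v)
        self._nodes: frozenset[str] = frozenset(node_set)
        self._edges: frozenset[Edge] = frozenset(canon)

    @property
    def nodes(self) -> frozenset[str]:
        return self._nodes

    @property
    def edges(self) -> frozenset[Edge]:
        return self._edges

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, u: str, v: str) -> bool:
        if u == v:
            return False
        return canonical_edge(u, v) in self._edges

    def neighbors(self, node: str) -> frozenset[str]:
        """First neighbors of ``node``; empty if the node is absent."""
        if node not in self._nodes:
            return frozenset()
        return frozenset(
            (v if u == node else u) for u, v in self._edges if node in (u, v)
        )

    def degree(self, node: str) -> int:
        return len(self.neighbors(node))

    def induced_subgraph(self, nodes: Iterable[str], name: str | None = None) -> "Network":
        """Subgraph on ``nodes ∩ self.nodes`` with all edges between them."""
        keep = set(nodes) & self._nodes
        edges = [e for e in self._edges if e[0] in keep and e[1] in keep]
        return Network(name or f"{self.name}|induced", keep, edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self._nodes))
        g.add_edges_from(sorted(self._edges))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, name: str) -> "Network":
        return cls(name, (str(n) for n in g.nodes), ((str(u), str(v)) for u, v in g.edges if u != v))

    def renamed(self, name: str) -> "Network":
        net = Network.__new__(Network)
        net.name = str(name)
        net._nodes = self._nodes
        net._edges = self._edges
        return net

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._nodes, self._edges))

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node: object) -> bool:
        return node in self._nodes

    def __repr__(self) -> str:
        return f"Network({self.name!r}, {self.n_nodes} nodes, {self.n_edges} edges)"


class NetworkCollection:
    """An ordered set of uniquely named networks — the unit of comparison."""

    def __init__(self, networks: Iterable[Network]) -> None:
        self._networks: list[Network] = list(networks)
        if not self._networks:
            raise ValueError("a NetworkCollection needs at least one network")
        names = [n.name for n in self._networks]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate network names: {sorted(dup)}")
        self._by_name = {n.name: n for n in self._networks}

    @property
    def names(self) -> list[str]:
        return [n.name for n in self._networks]

    def __getitem__(self, name: str) -> Network:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(
                f"unknown network {name!r}; valid names: {self.names}"
            ) from None

    def __iter__(self) -> Iterator[Network]:
        return iter(self._networks)

    def __len__(self) -> int:
        return len(self._networks)

    def __contains__(self, name: object) -> bool:
        return name in self._by_name

    def select(self, selection: Iterable[str] | None = None) -> list[Network]:
        """Resolve a list of names to networks, preserving collection order.

        ``None`` selects every network. Unknown names raise ``KeyError``
        listing the valid names.
        """
        if selection is None:
            return list(self._networks)
        wanted = list(selection)
        if not wanted:
            raise ValueError("selection must name at least one network")
        for name in wanted:
            if name not in self._by_name:
                raise KeyError(
                    f"unknown network {name!r}; valid names: {self.names}"
                )
        chosen = set(wanted)
        return [n for n in self._networks if n.name in chosen]

    def __repr__(self) -> str:
        return f"NetworkCollection({self.names})"
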