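"""Set algebra over a selection of networks, with per-network affiliation.

Union, intersection and exclusive regions are the primitive comparisons:
which nodes and edges occur in *any*, *all*, or *only* the selected
networks. Alongside the union, an :class:`AffiliationTable` records, for
every union node and edge, the boolean membership vector across the selected
networks — the data behind per-node "pie" charts and the union-edges ×
networks "edge-pie" membership matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import Edge, Network, NetworkCollection

__all__ = [
    "AffiliationTable",
    "union_networks",
    "intersect_networks",
    "exclusive_networks",
    "exclusive_node_set",
    "edge_pie_matrix",
]


@dataclass(frozen=True)
class AffiliationTable:
    """Membership bit-vectors of union nodes and edges across networks.

    ``node_membership[v][i]`` is True iff node ``v`` belongs to
    ``network_names[i]``; likewise for canonical edges. Every vector has at
    least one True entry (the element came from somewhere).
    """

    network_names: tuple[str, ...]
    node_membership: dict[str, tuple[bool, ...]]
    edge_membership: dict[Edge, tuple[bool, ...]]

    def node_frame(self) -> pd.DataFrame:
        """Nodes × networks 0/1 table, rows sorted by node id."""
        idx = sorted(self.node_membership)
        data = [[int(b) for b in self.node_membership[v]] for v in idx]
        return pd.DataFrame(data, index=pd.Index(idx, name="node"),
                            columns=list(self.network_names))

    def edge_frame(self) -> pd.DataFrame:
        """Union edges × networks 0/1 table (the edge-pie matrix)."""
        idx = sorted(self.edge_membership)
        data = [[int(b) for b in self.edge_membership[e]] for e in idx]
        frame = pd.DataFrame(data, columns=list(self.network_names))
        frame.insert(0, "node1", [e[0] for e in idx])
        frame.insert(1, "node2", [e[1] for e in idx])
        return frame

    def write_tsv(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        self.node_frame().to_csv(nodes_path, sep="\t")
        self.edge_frame().to_csv(edges_path, sep="\t", index=False)


def _resolve(
    collection: NetworkCollection, selection: Sequence[str] | None
) -> list[Network]:
    return collection.select(selection)


def union_networks(
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
    name: str = "union",
) -> tuple[Network, AffiliationTable]:
    """Union of the selected networks plus the affiliation table.

    The union contains every node and edge present in *any* selected
    network; the affiliation table covers all of them.
    """
    nets = _resolve(collection, selection)
    names = tuple(n.name for n in nets)
    all_nodes: set[str] = set()
    all_edges: set[Edge] = set()
    for net in nets:
        all_nodes |= net.nodes
        all_edges |= net.edges
    node_membership = {
        v: tuple(v in net.nodes for net in nets) for v in all_nodes
    }
    edge_membership = {
        e: tuple(e in net.edges for net in nets) for e in all_edges
    }
    union = Network(name, all_nodes, all_edges)
    return union, AffiliationTable(names, node_membership, edge_membership)


def intersect_networks(
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
    name: str = "intersection",
) -> Network:
    """Edges and nodes present in **all** selected networks.

    The node set is the endpoints of the common edges plus any node common
    to all selected networks (isolates can legitimately be shared when
    overlays were built with ``keep_isolates``).
    """
    nets = _resolve(collection, selection)
    common_edges = set(nets[0].edges)
    common_nodes = set(nets[0].nodes)
    for net in nets[1:]:
        common_edges &= net.edges
        common_nodes &= net.nodes
    nodes = common_nodes | {n for e in common_edges for n in e}
    return Network(name, nodes, common_edges)


def exclusive_networks(
    collection: NetworkCollection,
    selection: Sequence[str],
    name: str = "exclusive",
) -> Network:
    """Edges and nodes specific to the selected networks.

    An edge qualifies if it occurs in at least one selected network and in
    no unselected one; a node qualifies analogously. The selection must be
    a proper non-empty subset of the collection — exclusivity against an
    empty complement is undefined.
    """
    nets = _resolve(collection, selection)
    selected = {n.name for n in nets}
    others = [n for n in collection if n.name not in selected]
    if not others:
        raise ValueError(
            "selection covers the whole collection; the exclusive region "
            "is undefined without unselected networks"
        )
    sel_edges: set[Edge] = set()
    sel_nodes: set[str] = set()
    for net in nets:
        sel_edges |= net.edges
        sel_nodes |= net.nodes
    for net in others:
        sel_edges -= net.edges
        sel_nodes -= net.nodes
    # endpoints of an exclusive edge may themselves be shared with an
    # unselected network; they stay in the graph so edges remain valid,
    # while exclusive_node_set() reports node-granularity exclusivity
    nodes = sel_nodes | {n for e in sel_edges for n in e}
    return Network(name, nodes, sel_edges)


def exclusive_node_set(
    collection: NetworkCollection, selection: Sequence[str]
) -> set[str]:
    """Nodes present in a selected network and absent from every unselected one."""
    nets = _resolve(collection, selection)
    selected = {n.name for n in nets}
    others = [n for n in collection if n.name not in selected]
    if not others:
        raise ValueError("selection covers the whole collection")
    nodes: set[str] = set()
    for net in nets:
        nodes |= net.nodes
    for net in others:
        nodes -= net.nodes
    return nodes


def edge_pie_matrix(
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Union-edges × networks 0/1 membership matrix.

    Row count equals the union edge count; every row sum is ≥ 1; each
    column sums to that network's edge count.
    """
    _union, table = union_networks(collection, selection)
    return table.edge_frame()
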