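"""Global and node-level graph properties, and cross-network rankings.

Global properties are the six summary numbers used when eyeballing a set of
networks side by side: node and edge counts, density, clustering
coefficient, average path length and diameter. Node properties are the
standard centrality family (degree, betweenness, closeness, eccentricity,
coreness, eigenvector centrality). ``top_k_report`` ranks union nodes by a
metric and annotates each with its presence across the compared networks —
the tabular form of the stacked top-k bar plots.

Conventions on disconnected graphs: average path length and diameter are
computed over *reachable* ordered pairs only (always finite); closeness and
eccentricity are computed within each node's reachable set. The clustering
coefficient defaults to global transitivity, 3·triangles / connected
triples, with mean local clustering available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .algebra import union_networks
from .core import Network, NetworkCollection

__all__ = [
    "GlobalProps",
    "GLOBAL_PROPERTY_NAMES",
    "NODE_METRICS",
    "global_properties",
    "node_properties",
    "top_k_report",
    "global_properties_table",
]

GLOBAL_PROPERTY_NAMES = (
    "n_nodes",
    "n_edges",
    "density",
    "clustering_coefficient",
    "average_path_length",
    "diameter",
)

NODE_METRICS = (
    "degree",
    "betweenness",
    "closeness",
    "eccentricity",
    "coreness",
    "eigenvector_centrality",
)


@dataclass(frozen=True)
class GlobalProps:
    """Global summary of one network. ``degenerate`` flags the empty graph,
    for which every value is reported as zero."""

    n_nodes: int
    n_edges: int
    density: float
    clustering_coefficient: float
    average_path_length: float
    diameter: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in GLOBAL_PROPERTY_NAMES}


def _path_length_stats(g: nx.Graph) -> tuple[float, float]:
    """(average path length, diameter) over reachable ordered pairs."""
    total = 0
    count = 0
    diameter = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            if target == source:
                continue
            total += d
            count += 1
            if d > diameter:
                diameter = d
    if count == 0:
        return 0.0, 0.0
    return total / count, float(diameter)


def global_properties(
    net: Network,
    clustering: str = "transitivity",
) -> GlobalProps:
    """Compute the six global properties of a network.

    Parameters
    ----------
    net : Network
    clustering : {"transitivity", "average_local"}
        ``transitivity`` (default) is the global coefficient
        3·triangles / connected triples; ``average_local`` is the mean of
        per-node local clustering coefficients.
    """
    if clustering not in ("transitivity", "average_local"):
        raise ValueError(
            f"unknown clustering convention {clustering!r}; "
            "use 'transitivity' or 'average_local'"
        )
    n, m = net.n_nodes, net.n_edges
    if n == 0:
        return GlobalProps(0, 0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    g = net.to_networkx()
    density = 2.0 * m / (n * (n - 1)) if n >= 2 else 0.0
    if clustering == "transitivity":
        cc = nx.transitivity(g)
    else:
        cc = nx.average_clustering(g)
    apl, diam = _path_length_stats(g)
    return GlobalProps(n, m, density, cc, apl, diam)


def _eigenvector(g: nx.Graph) -> dict[str, float]:
    if g.number_of_edges() == 0:
        return {v: 0.0 for v in g}
    try:
        return nx.eigenvector_centrality_numpy(g)
    except (nx.NetworkXException, TypeError):
        return nx.eigenvector_centrality(g, max_iter=2000, tol=1e-10)


def node_properties(
    net: Network,
    metrics: Sequence[str] | None = None,
    normalized_betweenness: bool = False,
) -> pd.DataFrame:
    """Per-node metric table, one row per node (sorted), one column per metric.

    Betweenness is the unnormalized shortest-path count through the node
    over all unordered source–target pairs (endpoints excluded);
    ``normalized_betweenness`` divides by (n−1)(n−2)/2. Closeness is the
    within-reachable-set form (no cross-component scaling). Coreness is the
    largest k such that the node survives k-core peeling.
    """
    if net.n_nodes == 0:
        raise ValueError("node properties of an empty network are undefined")
    wanted = list(metrics) if metrics is not None else list(NODE_METRICS)
    unknown = [m for m in wanted if m not in NODE_METRICS]
    if unknown:
        raise ValueError(
            f"unknown metric(s) {unknown}; valid metrics: {list(NODE_METRICS)}"
        )
    g = net.to_networkx()
    cols: dict[str, dict[str, float]] = {}
    for metric in wanted:
        if metric == "degree":
            cols[metric] = {v: float(d) for v, d in g.degree()}
        elif metric == "betweenness":
            cols[metric] = nx.betweenness_centrality(
                g, normalized=normalized_betweenness
            )
        elif metric == "closeness":
            cols[metric] = nx.closeness_centrality(g, wf_improved=False)
        elif metric == "eccentricity":
            ecc: dict[str, float] = {}
            for comp in nx.connected_components(g):
                sub = g.subgraph(comp)
                ecc.update({v: float(e) for v, e in nx.eccentricity(sub).items()})
            cols[metric] = ecc
        elif metric == "coreness":
            cols[metric] = {v: float(c) for v, c in nx.core_number(g).items()}
        elif metric == "eigenvector_centrality":
            cols[metric] = _eigenvector(g)
    frame = pd.DataFrame(cols, columns=wanted)
    frame.index.name = "node"
    return frame.sort_index()


def top_k_report(
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
    metric: str = "degree",
    k: int = 10,
    scope: str = "union",
) -> pd.DataFrame:
    """Top-k union nodes by a node metric, with per-network presence flags.

    The metric is always computed on the union of the selection; rows are
    sorted descending by value with lexicographic tie-breaking on node id.
    With ``scope="per-network"`` a value column per network is appended
    (the metric recomputed within each network; NaN where the node is
    absent). If k exceeds the node count, all nodes are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if scope not in ("union", "per-network"):
        raise ValueError("scope must be 'union' or 'per-network'")
    union, table = union_networks(collection, selection)
    values = node_properties(union, [metric])[metric]
    order = sorted(values.index, key=lambda v: (-values[v], v))[:k]
    names = list(table.network_names)
    rows = []
    for v in order:
        flags = table.node_membership[v]
        rows.append([v, values[v]] + [int(b) for b in flags])
    frame = pd.DataFrame(rows, columns=["node", metric] + names)
    if scope == "per-network":
        per_net: dict[str, pd.Series] = {}
        for net in collection.select(selection):
            per_net[net.name] = node_properties(net, [metric])[metric]
        for name in names:
            frame[f"{metric}:{name}"] = [
                per_net[name].get(v, float("nan")) for v in frame["node"]
            ]
    return frame


def global_properties_table(
    networks: Iterable[Network], clustering: str = "transitivity"
) -> pd.DataFrame:
    """One row of global properties per network (comparison summary table)."""
    rows = {}
    for net in networks:
        rows[net.name] = global_properties(net, clustering=clustering).as_dict()
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "network"
    return frame
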