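"""Fast-greedy community detection and cross-network community profiles.

The detector is greedy agglomerative modularity maximization
(Clauset–Newman–Moore): start from singleton communities, repeatedly merge
the pair of connected communities with the largest modularity gain, and cut
the merge sequence at the partition of maximum modularity. Modularity of a
partition is

    Q = Σ_c [ E_c/m − (d_c / 2m)² ]

with E_c the number of edges inside community c, d_c the total degree of
its nodes and m the total edge count. The implementation is written for
reproducibility: ties in the merge gain are broken by the lexicographically
smallest member labels, so repeated runs (and different platforms) give the
identical partition. Communities are reported in descending size order as
C1, C2, … — the ordering used when listing communities for inspection.

Detection is meant to run on the union of the compared networks; the
community distribution profile then shows how each community's nodes and
intra-community edges are spread across the individual networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .algebra import union_networks
from .core import Network, NetworkCollection

__all__ = [
    "CommunityPartition",
    "modularity",
    "detect_communities",
    "community_distribution",
    "community_subgraph",
]


def modularity(net: Network, communities: Sequence[frozenset[str]]) -> float:
    """Modularity Q of a partition of ``net``'s nodes (0 for edgeless graphs)."""
    m = net.n_edges
    if m == 0:
        return 0.0
    node_to_c: dict[str, int] = {}
    for i, comm in enumerate(communities):
        for v in comm:
            node_to_c[v] = i
    internal = [0] * len(communities)
    degree = [0] * len(communities)
    for u, v in net.edges:
        cu, cv = node_to_c[u], node_to_c[v]
        degree[cu] += 1
        degree[cv] += 1
        if cu == cv:
            internal[cu] += 1
    return sum(
        internal[c] / m - (degree[c] / (2.0 * m)) ** 2
        for c in range(len(communities))
    )


@dataclass(frozen=True)
class CommunityPartition:
    """Disjoint communities covering a network, largest first (C1, C2, …)."""

    communities: tuple[frozenset[str], ...]
    modularity: float

    @property
    def ids(self) -> list[str]:
        return [f"C{i + 1}" for i in range(len(self.communities))]

    def members(self, community_id: str) -> frozenset[str]:
        try:
            idx = self.ids.index(community_id)
        except ValueError:
            raise KeyError(
                f"unknown community {community_id!r}; valid ids: {self.ids}"
            ) from None
        return self.communities[idx]

    @property
    def membership(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for cid, comm in zip(self.ids, self.communities):
            for v in comm:
                out[v] = cid
        return out

    def node_set(self) -> frozenset[str]:
        return frozenset().union(*self.communities) if self.communities else frozenset()

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.membership.items())
        frame = pd.DataFrame(rows, columns=["node", "community"])
        return frame


def _sorted_communities(
    groups: Sequence[set[str] | frozenset[str]],
) -> tuple[frozenset[str], ...]:
    # descending size; equal sizes ordered by smallest member label
    return tuple(
        frozenset(c) for c in sorted(groups, key=lambda c: (-len(c), min(c)))
    )


def detect_communities(net: Network, method: str = "fast_greedy") -> CommunityPartition:
    """Detect communities by greedy modularity maximization.

    Merges proceed only across pairs of communities sharing at least one
    edge (merging disconnected communities can never raise Q), with
    deterministic lexicographic tie-breaking, and the returned partition is
    the one of maximum modularity along the merge path. Isolated nodes end
    up as singleton communities.
    """
    if method != "fast_greedy":
        raise ValueError(f"unknown method {method!r}; only 'fast_greedy'")
    if net.n_nodes == 0:
        raise ValueError("cannot detect communities in an empty network")
    m = net.n_edges
    if m == 0:
        comms = _sorted_communities([{v} for v in net.nodes])
        return CommunityPartition(comms, 0.0)

    # community label = lexicographically smallest member (stable under merges)
    members: dict[str, set[str]] = {v: {v} for v in net.nodes}
    deg: dict[str, int] = {v: 0 for v in net.nodes}
    between: dict[tuple[str, str], int] = {}
    for u, v in net.edges:
        deg[u] += 1
        deg[v] += 1
        key = (u, v) if u < v else (v, u)
        between[key] = between.get(key, 0) + 1

    two_m = 2.0 * m
    q = -sum((d / two_m) ** 2 for d in deg.values())
    best_q = q
    best = [set(c) for c in members.values()]

    while between:
        best_gain = None
        best_pair: tuple[str, str] | None = None
        for (ci, cj), eij in between.items():
            gain = eij / m - 2.0 * (deg[ci] / two_m) * (deg[cj] / two_m)
            if (
                best_gain is None
                or gain > best_gain + 1e-12
                or (abs(gain - best_gain) <= 1e-12 and (ci, cj) < best_pair)
            ):
                best_gain = gain
                best_pair = (ci, cj)
        ci, cj = best_pair  # type: ignore[misc]
        q += best_gain  # type: ignore[operator]

        # merge cj into ci (ci < cj, so ci stays the smallest member label)
        members[ci] |= members.pop(cj)
        deg[ci] += deg.pop(cj)
        del between[(ci, cj)]
        for (a, b), w in list(between.items()):
            if cj in (a, b):
                other = b if a == cj else a
                del between[(a, b)]
                if other == ci:
                    continue
                key = (ci, other) if ci < other else (other, ci)
                between[key] = between.get(key, 0) + w

        if q > best_q + 1e-12:
            best_q = q
            best = [set(c) for c in members.values()]

    comms = _sorted_communities(best)
    return CommunityPartition(comms, modularity(net, comms))


def community_distribution(
    partition: CommunityPartition,
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Community × network profile of node and intra-community edge counts.

    For each community and each selected network, counts the community
    members present in that network and the network's edges with both
    endpoints inside the community. The partition must cover the union of
    the selection (it is normally computed on exactly that union).
    """
    nets = collection.select(selection)
    union, _ = union_networks(collection, [n.name for n in nets])
    covered = partition.node_set()
    missing = union.nodes - covered
    if missing:
        raise ValueError(
            f"partition does not cover {len(missing)} union node(s), "
            f"e.g. {sorted(missing)[:5]}"
        )
    rows = []
    for cid, comm in zip(partition.ids, partition.communities):
        row: dict[str, object] = {"community": cid, "size": len(comm)}
        for net in nets:
            row[f"{net.name}:nodes"] = len(comm & net.nodes)
            row[f"{net.name}:edges"] = sum(
                1 for e in net.edges if e[0] in comm and e[1] in comm
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("community")


def community_subgraph(
    union: Network,
    partition: CommunityPartition,
    community_id: str,
) -> Network:
    """Induced subgraph of the union on one community's nodes (exportable as
    a plain node/edge list, e.g. as input to enrichment tools)."""
    members = partition.members(community_id)
    return union.induced_subgraph(members, name=f"{union.name}|{community_id}")
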