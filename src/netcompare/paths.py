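"""Unweighted shortest paths within and across networks.

Paths are computed by breadth-first search on hop count. Among equal-length
shortest paths the lexicographically smallest node sequence is returned, so
outputs are stable across runs and platforms. Unreachable pairs yield an
explicit unreachable result rather than an error; batch mode takes node-list
files (or any iterables) of sources and targets and reports every pair of
the product. ``compare_paths`` contrasts a pair's shortest path across each
selected network and their union — a path that shortens or vanishes between
conditions is often the interesting signal.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .algebra import union_networks
from .core import Network, NetworkCollection
from .io import read_node_list

__all__ = [
    "PathResult",
    "shortest_path",
    "all_shortest_paths",
    "batch_shortest_paths",
    "compare_paths",
    "paths_table",
]


@dataclass(frozen=True)
class PathResult:
    """One source→target query against one network.

    ``status`` is ``"ok"`` (path found; consecutive path nodes are edges of
    the network and length = len(path) − 1), ``"unreachable"`` (both
    endpoints present, no connecting path) or ``"missing-node"`` (an
    endpoint absent from the network; only produced by batch/compare modes).
    """

    network: str
    source: str
    target: str
    path: tuple[str, ...] | None
    length: int | None
    status: str = "ok"

    @property
    def reachable(self) -> bool:
        return self.status == "ok"


def _bfs_distances(net: Network, start: str) -> dict[str, int]:
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for w in net.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def shortest_path(net: Network, source: str, target: str) -> PathResult:
    """Minimum-hop path from source to target in one network.

    Both endpoints must exist in the network. Ties among equal-length
    paths resolve to the lexicographically smallest node sequence: walk
    from the source, always taking the smallest-labelled neighbor that
    still lies on some shortest path (distance-to-target decreases by 1).
    A source equal to the target yields the length-0 path [source].
    """
    for endpoint in (source, target):
        if endpoint not in net:
            raise KeyError(
                f"node {endpoint!r} is not in network {net.name!r}"
            )
    if source == target:
        return PathResult(net.name, source, target, (source,), 0)
    dist_to_target = _bfs_distances(net, target)
    if source not in dist_to_target:
        return PathResult(net.name, source, target, None, None, "unreachable")
    path = [source]
    current = source
    while current != target:
        d = dist_to_target[current]
        current = min(
            w for w in net.neighbors(current) if dist_to_target.get(w) == d - 1
        )
        path.append(current)
    return PathResult(net.name, source, target, tuple(path), len(path) - 1)


def all_shortest_paths(net: Network, source: str, target: str) -> list[tuple[str, ...]]:
    """Every minimum-hop path, sorted lexicographically (small graphs only —
    the number of shortest paths can grow exponentially)."""
    base = shortest_path(net, source, target)
    if not base.reachable:
        return []
    if source == target:
        return [(source,)]
    dist_to_target = _bfs_distances(net, target)

    def extend(prefix: list[str]) -> Iterable[tuple[str, ...]]:
        u = prefix[-1]
        if u == target:
            yield tuple(prefix)
            return
        d = dist_to_target[u]
        for w in sorted(net.neighbors(u)):
            if dist_to_target.get(w) == d - 1:
                yield from extend(prefix + [w])

    return list(extend([source]))


def _node_collection(arg: str | Path | Iterable[str]) -> list[str]:
    if isinstance(arg, (str, Path)):
        return sorted(read_node_list(arg))
    return sorted({str(n) for n in arg})


def batch_shortest_paths(
    net: Network,
    sources: str | Path | Iterable[str],
    targets: str | Path | Iterable[str],
) -> list[PathResult]:
    """Shortest paths for the full sources × targets product.

    ``sources``/``targets`` may be node-list file paths or iterables of
    node ids. Endpoints missing from the network produce a
    ``missing-node`` result for that pair rather than failing the batch.
    Exactly |sources| · |targets| results are returned, in sorted order.
    """
    src = _node_collection(sources)
    tgt = _node_collection(targets)
    if not src or not tgt:
        raise ValueError("source and target lists must be non-empty")
    results = []
    for s in src:
        for t in tgt:
            if s not in net or t not in net:
                results.append(
                    PathResult(net.name, s, t, None, None, "missing-node")
                )
            else:
                results.append(shortest_path(net, s, t))
    return results


def compare_paths(
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
    source: str = "",
    target: str = "",
) -> pd.DataFrame:
    """Shortest source→target path in every selected network and their union.

    Returns one row per network plus a ``union`` row, with an explicit
    status for unreachable pairs or missing endpoints, and a
    ``differs_from_union`` flag marking networks whose path length is not
    the union's (the union length is always the minimum achievable).
    """
    nets = collection.select(selection)
    union, _ = union_networks(collection, [n.name for n in nets])
    union = union.renamed("union")
    rows: list[PathResult] = []
    for net in list(nets) + [union]:
        if source not in net or target not in net:
            rows.append(PathResult(net.name, source, target, None, None, "missing-node"))
        else:
            rows.append(shortest_path(net, source, target))
    frame = paths_table(rows)
    union_len = rows[-1].length
    frame["differs_from_union"] = [
        (r.length != union_len) for r in rows
    ]
    return frame


def paths_table(results: Iterable[PathResult]) -> pd.DataFrame:
    """Long-form TSV-ready table: network, source, target, length, status,
    path as '|'-joined node sequence (empty when absent)."""
    rows = [
        {
            "network": r.network,
            "source": r.source,
            "target": r.target,
            "length": r.length,
            "status": r.status,
            "path": "|".join(r.path) if r.path else "",
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["network", "source", "target", "length", "status", "path"]
    )
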