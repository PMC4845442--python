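"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles — exhaustive enumeration,
peeling, and explicit path counting on small graphs — deliberately avoiding
the code paths (and libraries) the package itself uses for the same
quantity.
"""

from __future__ import annotations

import itertools
from collections import deque

from netcompare.core import Network


def bfs_distances(net: Network, start: str) -> dict[str, int]:
    dist = {start: 0}
    q = deque([start])
    while q:
        u = q.popleft()
        for w in net.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def all_pairs_distances(net: Network) -> dict[tuple[str, str], int]:
    out = {}
    for s in net.nodes:
        for t, d in bfs_distances(net, s).items():
            out[(s, t)] = d
    return out


def average_path_length(net: Network) -> float:
    dists = [d for (s, t), d in all_pairs_distances(net).items() if s != t]
    return sum(dists) / len(dists) if dists else 0.0


def diameter(net: Network) -> float:
    dists = [d for (s, t), d in all_pairs_distances(net).items() if s != t]
    return float(max(dists)) if dists else 0.0


def enumerate_shortest_paths(net: Network, s: str, t: str) -> list[tuple[str, ...]]:
    """All minimum-hop s→t paths by breadth-limited DFS enumeration."""
    dist = bfs_distances(net, s)
    if t not in dist:
        return []
    target_len = dist[t]
    paths = []

    def walk(prefix: list[str]) -> None:
        u = prefix[-1]
        if u == t:
            if len(prefix) - 1 == target_len:
                paths.append(tuple(prefix))
            return
        if len(prefix) - 1 >= target_len:
            return
        for w in net.neighbors(u):
            if w not in prefix:
                walk(prefix + [w])

    walk([s])
    return paths


def betweenness(net: Network) -> dict[str, float]:
    """Unnormalized betweenness by explicit shortest-path enumeration over
    unordered source–target pairs, endpoints excluded."""
    out = {v: 0.0 for v in net.nodes}
    nodes = sorted(net.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = enumerate_shortest_paths(net, s, t)
            if not paths:
                continue
            for v in net.nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                out[v] += through / len(paths)
    return out


def closeness(net: Network) -> dict[str, float]:
    """Within-reachable-set closeness: (r−1)/Σd over the r reachable nodes."""
    out = {}
    for v in net.nodes:
        dist = bfs_distances(net, v)
        total = sum(d for u, d in dist.items() if u != v)
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def eccentricity(net: Network) -> dict[str, float]:
    out = {}
    for v in net.nodes:
        dist = bfs_distances(net, v)
        out[v] = float(max(d for d in dist.values()))
    return out


def coreness(net: Network) -> dict[str, int]:
    """k-core peeling: repeatedly remove nodes of degree < k."""
    out = {}
    k = 0
    remaining = set(net.nodes)
    while remaining:
        while True:
            victims = {
                v for v in remaining
                if len(net.neighbors(v) & remaining) < k
            }
            if not victims:
                break
            for v in victims:
                out[v] = k - 1
            remaining -= victims
        k += 1
    return out


def transitivity(net: Network) -> float:
    """3 · triangles / connected triples by exhaustive enumeration."""
    triangles = 0
    for u, v, w in itertools.combinations(sorted(net.nodes), 3):
        if net.has_edge(u, v) and net.has_edge(v, w) and net.has_edge(u, w):
            triangles += 1
    triples = 0
    for v in net.nodes:
        d = len(net.neighbors(v))
        triples += d * (d - 1) // 2
    return 3.0 * triangles / triples if triples else 0.0


def modularity(net: Network, communities) -> float:
    """Q = Σ_c [E_c/m − (d_c/2m)²] computed straight from the definition."""
    m = net.n_edges
    if m == 0:
        return 0.0
    q = 0.0
    for comm in communities:
        comm = set(comm)
        internal = sum(1 for e in net.edges if e[0] in comm and e[1] in comm)
        degree = sum(len(net.neighbors(v)) for v in comm)
        q += internal / m - (degree / (2.0 * m)) ** 2
    return q


def best_partition_exhaustive(net: Network):
    """Maximum-modularity partition by enumerating all set partitions."""
    nodes = sorted(net.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {head}] + part[i + 1:]
            yield part + [{head}]

    best_q, best = float("-inf"), None
    for part in partitions(nodes):
        q = modularity(net, part)
        if q > best_q:
            best_q, best = q, part
    return best_q, best


def nsi_raw(a: Network, b: Network) -> float:
    """Per-node neighbor-set Jaccard sum, written out longhand."""
    total = 0.0
    for v in a.nodes | b.nodes:
        fa = a.neighbors(v)
        fb = b.neighbors(v)
        if fa or fb:
            total += len(fa & fb) / len(fa | fb)
    return total
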