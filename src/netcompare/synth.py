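"""Synthetic backgrounds and overlay node-list series for testing pipelines.

Emulates the typical use case of multi-network comparison: a large
interactome acting as the background, and a time-series of perturbed-gene
node lists overlaid on it, each pair of consecutive lists sharing a
controlled fraction of members. Everything is seed-deterministic and the
exact overlaps realized are emitted as a ground-truth record, so downstream
similarity and set-algebra results can be checked against known answers.

Defaults sketch a desk-scale interactome: a 500-node preferential-
attachment background (PPI degree distributions are heavy-tailed, which a
uniform random graph does not reproduce), eight overlay lists of 60 nodes
(two condition series over four time points is the motivating shape) with a
0.5 consecutive-overlap fraction — neighboring time points share about half
their perturbed genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .core import Network
from .io import overlay_nodes

__all__ = ["FixtureSpec", "generate_background", "generate_overlay_series",
           "overlay_collection_from_series"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic world; the seed fully determines output."""

    model: str = "preferential_attachment"  # or "gnm"
    n_nodes: int = 500
    n_edges: int = 1500          # used by the gnm model
    attachment: int = 3          # edges per new node in preferential attachment
    n_networks: int = 8
    overlay_sizes: tuple[int, ...] = ()
    overlap: float = 0.5         # consecutive-list shared fraction in [0, 1]
    seed: int = 0

    def sizes(self) -> tuple[int, ...]:
        if self.overlay_sizes:
            if len(self.overlay_sizes) != self.n_networks:
                raise ValueError("overlay_sizes length must equal n_networks")
            return self.overlay_sizes
        return tuple([60] * self.n_networks)


def generate_background(spec: FixtureSpec, name: str = "background") -> Network:
    """Generate a connected background network from the spec.

    The raw random graph is reduced to its largest connected component
    (background interactomes are connected for all practical purposes), so
    the realized node/edge counts can be slightly below the requested ones
    for the ``gnm`` model; preferential-attachment graphs are connected by
    construction.
    """
    if spec.n_nodes < 2:
        raise ValueError("background needs at least 2 nodes")
    if spec.model == "gnm":
        max_edges = spec.n_nodes * (spec.n_nodes - 1) // 2
        if spec.n_edges > max_edges:
            raise ValueError(
                f"{spec.n_edges} edges infeasible for {spec.n_nodes} nodes"
            )
        g = nx.gnm_random_graph(spec.n_nodes, spec.n_edges, seed=spec.seed)
    elif spec.model == "preferential_attachment":
        g = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment, seed=spec.seed)
    else:
        raise ValueError(
            f"unknown model {spec.model!r}; use 'gnm' or 'preferential_attachment'"
        )
    width = len(str(spec.n_nodes - 1))
    g = nx.relabel_nodes(g, {i: f"n{i:0{width}d}" for i in g.nodes})
    largest = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    return Network.from_networkx(g.subgraph(largest), name)


def generate_overlay_series(
    background: Network,
    spec: FixtureSpec,
) -> tuple[list[set[str]], dict]:
    """Generate the overlay node lists plus their ground-truth overlap record.

    The first list is a uniform sample of the background; each subsequent
    list keeps ``round(overlap · min(size_prev, size_cur))`` members of its
    predecessor and fills up with fresh background nodes, so consecutive
    lists share approximately the configured fraction. The record holds the
    exact shared counts, making tests self-checking.
    """
    sizes = spec.sizes()
    if any(s < 1 or s > background.n_nodes for s in sizes):
        raise ValueError("overlay sizes must lie in [1, |background|]")
    if not 0.0 <= spec.overlap <= 1.0:
        raise ValueError("overlap fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    pool = np.array(sorted(background.nodes))
    lists: list[set[str]] = []
    shared_counts: list[int] = []
    prev: set[str] = set()
    for i, size in enumerate(sizes):
        if i == 0:
            chosen = set(pool[rng.choice(len(pool), size=size, replace=False)])
        else:
            k = int(round(spec.overlap * min(len(prev), size)))
            fresh_pool = np.array(sorted(set(pool) - prev))
            n_fresh = size - k
            if n_fresh > len(fresh_pool):
                raise ValueError(
                    f"overlap {spec.overlap} infeasible for list {i}: "
                    f"needs {n_fresh} fresh nodes, only {len(fresh_pool)} left"
                )
            prev_arr = np.array(sorted(prev))
            kept = set(prev_arr[rng.choice(len(prev_arr), size=k, replace=False)])
            fresh = set(fresh_pool[rng.choice(len(fresh_pool), size=n_fresh, replace=False)])
            chosen = kept | fresh
            shared_counts.append(len(chosen & prev))
        lists.append(chosen)
        prev = chosen
    ground_truth = {
        "seed": spec.seed,
        "overlap_fraction": spec.overlap,
        "sizes": [len(s) for s in lists],
        "consecutive_shared": shared_counts,
    }
    return lists, ground_truth


def overlay_collection_from_series(
    background: Network,
    lists: Sequence[set[str]],
    names: Sequence[str] | None = None,
    keep_isolates: bool = False,
) -> list[Network]:
    """Overlay each node list on the background, yielding named networks
    (net1, net2, … unless names are given)."""
    if names is None:
        names = [f"net{i + 1}" for i in range(len(lists))]
    if len(names) != len(lists):
        raise ValueError("names and lists must have equal length")
    return [
        overlay_nodes(background, nodes, keep_isolates=keep_isolates, name=name)
        for name, nodes in zip(names, lists)
    ]
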