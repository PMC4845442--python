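"""Pairwise network similarity, similarity matrices and network clustering.

Three similarity scores between two networks A and B:

* **Jaccard node similarity** — |nodes(A) ∩ nodes(B)| / |nodes(A) ∪ nodes(B)|
* **Jaccard edge similarity** — the same ratio on canonical edge sets
* **neighborhood similarity index (NSI)** — for every node of the combined
  node set, the Jaccard overlap of its first-neighbor sets in A and in B,
  summed over all such nodes. Two networks score high when their nodes keep
  the same immediate neighborhoods, which is stricter than merely sharing
  nodes or edges. The raw score lies in [0, N]; dividing by N (the union
  node count) gives the normalized score on [0, 1] used for clustering.

A symmetric :class:`SimilarityMatrix` over a collection feeds average- (or
single-/complete-) linkage agglomerative clustering on distance 1 − s, with
newick export of the resulting dendrogram and a long-form bubble-chart
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import Network, NetworkCollection

__all__ = [
    "SIMILARITY_METHODS",
    "NsiScore",
    "SimilarityMatrix",
    "Dendrogram",
    "jaccard_node",
    "jaccard_edge",
    "nsi",
    "similarity_matrix",
    "cluster_networks",
    "bubble_chart_data",
]

SIMILARITY_METHODS = ("jaccard_node", "jaccard_edge", "nsi_normalized")


def jaccard_node(a: Network, b: Network) -> float:
    """Jaccard similarity of the two node sets."""
    union = a.nodes | b.nodes
    if not union:
        raise ValueError(
            f"node Jaccard of {a.name!r} and {b.name!r} is undefined: "
            "both networks are empty"
        )
    return len(a.nodes & b.nodes) / len(union)


def jaccard_edge(a: Network, b: Network) -> float:
    """Jaccard similarity of the two canonical edge sets.

    Edge-free pairs score 0 by convention provided at least one node
    exists; two entirely empty networks are rejected as 0/0.
    """
    if not (a.nodes | b.nodes):
        raise ValueError(
            f"edge Jaccard of {a.name!r} and {b.name!r} is undefined: "
            "both networks are empty"
        )
    union = a.edges | b.edges
    if not union:
        return 0.0
    return len(a.edges & b.edges) / len(union)


class NsiScore(NamedTuple):
    raw: float
    normalized: float
    undefined_terms: int  # union nodes isolated in both networks (0/0 → 0)


def nsi(a: Network, b: Network) -> NsiScore:
    """Neighborhood similarity index between two networks.

    raw = Σ over nodes v of nodes(A) ∪ nodes(B) of
          |N_A(v) ∩ N_B(v)| / |N_A(v) ∪ N_B(v)|,

    where N_X(v) is the first-neighbor set of v in X (empty when v ∉ X).
    A term whose neighbor sets are empty in *both* networks is 0/0; it
    contributes 0 and is counted in ``undefined_terms`` so isolates never
    inflate similarity. normalized = raw / N with N the union node count.
    """
    union_nodes = a.nodes | b.nodes
    if not union_nodes:
        raise ValueError(
            f"NSI of {a.name!r} and {b.name!r} is undefined: both empty"
        )
    raw = 0.0
    undefined = 0
    for v in union_nodes:
        fa = a.neighbors(v)
        fb = b.neighbors(v)
        denom = len(fa | fb)
        if denom == 0:
            undefined += 1
            continue
        raw += len(fa & fb) / denom
    return NsiScore(raw, raw / len(union_nodes), undefined)


_PAIRWISE = {
    "jaccard_node": jaccard_node,
    "jaccard_edge": jaccard_edge,
    "nsi_normalized": lambda a, b: nsi(a, b).normalized,
}


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarity scores over an ordered set of networks."""

    method: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("similarity matrix shape does not match names")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names),
                            columns=list(self.names))

    def score(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def similarity_matrix(
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
    method: str = "jaccard_edge",
) -> SimilarityMatrix:
    """All-pairs similarity over the selection under one method."""
    if method not in _PAIRWISE:
        raise ValueError(
            f"unknown method {method!r}; valid: {list(_PAIRWISE)}"
        )
    nets = collection.select(selection)
    if len(nets) < 2:
        raise ValueError("similarity matrix needs at least 2 networks")
    pair = _PAIRWISE[method]
    k = len(nets)
    values = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                s = pair(nets[i], nets[j])
            except ValueError as exc:
                raise ValueError(
                    f"similarity of pair ({nets[i].name!r}, {nets[j].name!r}) "
                    f"failed: {exc}"
                ) from exc
            values[i, j] = values[j, i] = s
    for i in range(k):
        if nets[i].n_nodes == 0:
            values[i, i] = 0.0  # empty network is not similar to itself
        elif method == "nsi_normalized":
            values[i, i] = nsi(nets[i], nets[i]).normalized
    return SimilarityMatrix(method, tuple(n.name for n in nets), values)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over network names.

    ``linkage_matrix`` is a scipy linkage array on distance = 1 − similarity;
    ``names`` are the leaves in the (lexicographic) order handed to scipy.
    """

    names: tuple[str, ...]
    linkage_matrix: np.ndarray
    linkage_method: str

    def merge_heights(self) -> list[float]:
        return [float(row[2]) for row in self.linkage_matrix]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height − child height."""
        n = len(self.names)

        def render(idx: int, parent_height: float) -> str:
            if idx < n:
                return f"{self.names[idx]}:{parent_height:.6g}"
            row = self.linkage_matrix[idx - n]
            h = float(row[2])
            children = f"{render(int(row[0]), h)},{render(int(row[1]), h)}"
            return f"({children}):{parent_height - h:.6g}"

        row = self.linkage_matrix[-1]
        h = float(row[2])
        return f"({render(int(row[0]), h)},{render(int(row[1]), h)});"

    def write_newick(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick() + "\n")


def cluster_networks(
    matrix: SimilarityMatrix, linkage: str = "average"
) -> Dendrogram:
    """Hierarchically cluster networks on distance = 1 − similarity.

    Leaves are handed to scipy in lexicographic name order, which fixes
    tie-breaking and makes the dendrogram reproducible across runs.
    """
    if linkage not in ("average", "single", "complete"):
        raise ValueError("linkage must be 'average', 'single' or 'complete'")
    if np.isnan(matrix.values).any():
        raise ValueError("similarity matrix contains NaN")
    order = sorted(range(len(matrix.names)), key=lambda i: matrix.names[i])
    names = tuple(matrix.names[i] for i in order)
    dist = 1.0 - matrix.values[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return Dendrogram(names, z, linkage)


def bubble_chart_data(matrix: SimilarityMatrix) -> pd.DataFrame:
    """Long-form (network_a, network_b, score) table over unordered pairs,
    sorted by descending score (ties by pair name), diagonal excluded."""
    rows = []
    k = len(matrix.names)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = sorted((matrix.names[i], matrix.names[j]))
            rows.append((a, b, float(matrix.values[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return pd.DataFrame(rows, columns=["network_a", "network_b", "score"])
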