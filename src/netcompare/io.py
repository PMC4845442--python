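"""Readers and writers for the three plain-text input modes, plus exports.

Input modes:

* **edge-list** — one node pair per line (two or more whitespace-separated
  tokens; extra tokens are ignored with a warning),
* **path-list** — one ordered node walk per line; an edge is added between
  every pair of consecutive nodes,
* **node-list** — one node per line, meant to be overlaid on a background
  network to form the induced "overlay" network.

All text inputs accept ``#`` comment lines and blank lines; the delimiter is
any run of whitespace; identifiers are case-sensitive and whitespace-trimmed.
Self-loop lines are skipped with a logged warning rather than raising, so
real interaction dumps load. Exports are Cytoscape-compatible edge-lists
(tab-separated, canonically sorted, byte-deterministic) and GML.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, TextIO

import networkx as nx

from .core import Network

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_edge_list",
    "read_path_list",
    "read_node_list",
    "overlay_nodes",
    "write_edge_list",
    "write_gml",
    "read_gml",
    "write_node_list",
]


class ParseError(ValueError):
    """Raised for a malformed input line; the message names the line number."""


def _lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, tokens) for content lines of a text file."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_edge_list(path: str | Path, name: str) -> Network:
    """Parse an edge-list file into a canonical :class:`Network`.

    Each content line must carry at least two tokens (source, target); extra
    tokens (e.g. weights or annotations) are ignored with a warning. Reversed
    duplicates collapse onto one canonical edge; self-loop lines are skipped
    with a warning and counted.
    """
    edges: list[tuple[str, str]] = []
    n_selfloops = 0
    n_extra = 0
    for lineno, tokens in _lines(path):
        if len(tokens) < 2:
            raise ParseError(
                f"{path}: line {lineno}: expected at least 2 tokens, got {len(tokens)}"
            )
        if len(tokens) > 2:
            n_extra += 1
        u, v = tokens[0], tokens[1]
        if u == v:
            n_selfloops += 1
            logger.warning("%s: line %d: skipping self-loop %r", path, lineno, u)
            continue
        edges.append((u, v))
    if n_extra:
        logger.warning("%s: ignored extra tokens on %d line(s)", path, n_extra)
    if n_selfloops:
        logger.warning("%s: skipped %d self-loop line(s)", path, n_selfloops)
    return Network(name, edges=edges)


def read_path_list(path: str | Path, name: str) -> Network:
    """Parse a path-list file: each line ``v1 v2 … vk`` contributes the edges
    ``(v1,v2) … (v(k-1),vk)``, deduplicated across lines."""
    edges: list[tuple[str, str]] = []
    n_selfloops = 0
    for lineno, tokens in _lines(path):
        if len(tokens) < 2:
            raise ParseError(
                f"{path}: line {lineno}: a path needs at least 2 nodes, got {len(tokens)}"
            )
        for u, v in zip(tokens, tokens[1:]):
            if u == v:
                n_selfloops += 1
                logger.warning(
                    "%s: line %d: skipping self-loop step %r", path, lineno, u
                )
                continue
            edges.append((u, v))
    if n_selfloops:
        logger.warning("%s: skipped %d self-loop step(s)", path, n_selfloops)
    return Network(name, edges=edges)


def read_node_list(path: str | Path) -> set[str]:
    """Parse a node-list file (one identifier per line) into a deduplicated set."""
    nodes: set[str] = set()
    for _lineno, tokens in _lines(path):
        nodes.add(tokens[0])
    return nodes


def overlay_nodes(
    background: Network,
    nodes: Iterable[str],
    keep_isolates: bool = False,
    name: str = "overlay",
) -> Network:
    """Overlay a node set on a background network.

    Returns the network of background edges whose **both** endpoints are
    overlay nodes ("only the interconnections between nodes of interest").
    With ``keep_isolates`` the result additionally keeps overlay nodes that
    exist in the background but gained no edge. Overlay nodes absent from the
    background are reported via a warning, never silently added.
    """
    if background.n_nodes == 0:
        raise ValueError("background network is empty")
    overlay = {str(n) for n in nodes}
    unmapped = sorted(overlay - background.nodes)
    if unmapped:
        logger.warning(
            "%d overlay node(s) absent from background %r: %s",
            len(unmapped),
            background.name,
            ", ".join(unmapped[:10]) + ("…" if len(unmapped) > 10 else ""),
        )
    mapped = overlay & background.nodes
    edges = [e for e in background.edges if e[0] in mapped and e[1] in mapped]
    if keep_isolates:
        node_set: set[str] = set(mapped)
    else:
        node_set = {n for e in edges for n in e}
    return Network(name, node_set, edges)


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write a tab-separated edge list, one canonical pair per line, sorted.

    Output is byte-deterministic, so identical networks always produce
    identical files. Isolated nodes are not representable in this format
    (use GML or a node list for them).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def write_node_list(nodes: Iterable[str], path: str | Path) -> None:
    """Write one identifier per line, sorted (plain gene-list format)."""
    with open(path, "w", encoding="utf-8") as fh:
        for n in sorted(set(nodes)):
            fh.write(f"{n}\n")


def write_gml(net: Network, path: str | Path) -> None:
    """Write a standard GML graph block (node id/label records, edge
    source/target records), parseable by Cytoscape and common graph tools."""
    nx.write_gml(net.to_networkx(), path)


def read_gml(path: str | Path, name: str | None = None) -> Network:
    """Read a GML file back into a :class:`Network` (labels become ids)."""
    g = nx.read_gml(path)
    return Network.from_networkx(g, name or Path(path).stem)
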