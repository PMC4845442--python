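"""Reproducible file-writing comparison runs over the library modules.

Each ``run_*`` function is a thin, scriptable front end for one capability:
it takes in-memory networks (or input declarations), executes the
corresponding module, writes plain-text outputs (TSV/JSON/GML/newick) into
an output directory and drops a ``manifest.json`` recording the inputs,
seed and package version, so a run can be reproduced byte-for-byte. All
randomness flows through the single ``seed`` argument.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .algebra import exclusive_networks, intersect_networks, union_networks
from .community import community_distribution, community_subgraph, detect_communities
from .core import Network, NetworkCollection
from .io import (
    read_edge_list,
    read_node_list,
    read_path_list,
    overlay_nodes,
    write_edge_list,
    write_gml,
    write_node_list,
)
from .metrics import global_properties_table, node_properties
from .paths import batch_shortest_paths, compare_paths, paths_table
from .significance import assess_significance
from .similarity import bubble_chart_data, cluster_networks, similarity_matrix
from .synth import (
    FixtureSpec,
    generate_background,
    generate_overlay_series,
    overlay_collection_from_series,
)

__all__ = [
    "load_declared",
    "run_compare",
    "run_metrics",
    "run_significance",
    "run_similarity",
    "run_community",
    "run_paths",
    "run_export",
    "run_simulate",
]


def _prepare(outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _manifest(out: Path, operation: str, inputs: Mapping, seed: int | None = None) -> None:
    payload = {
        "tool": "netcompare",
        "version": __version__,
        "operation": operation,
        "inputs": inputs,
        "seed": seed,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_declared(declarations: Sequence[Mapping]) -> NetworkCollection:
    """Build a collection from input declarations.

    Each declaration is a mapping with keys ``name``, ``mode`` (one of
    ``edge-list``, ``path-list``, ``node-list``) and ``path``; node-list
    declarations additionally need ``background`` (an edge-list file path)
    and accept ``keep_isolates``. Every input is validated before any
    computation starts.
    """
    networks = []
    for decl in declarations:
        name, mode, path = decl["name"], decl["mode"], decl["path"]
        if not Path(path).exists():
            raise FileNotFoundError(f"input for {name!r} not found: {path}")
        if mode == "edge-list":
            networks.append(read_edge_list(path, name))
        elif mode == "path-list":
            networks.append(read_path_list(path, name))
        elif mode == "node-list":
            background = read_edge_list(decl["background"], "background")
            networks.append(
                overlay_nodes(
                    background,
                    read_node_list(path),
                    keep_isolates=bool(decl.get("keep_isolates", False)),
                    name=name,
                )
            )
        else:
            raise ValueError(
                f"unknown input mode {mode!r}; use edge-list, path-list or node-list"
            )
    return NetworkCollection(networks)


def run_compare(
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
    op: str = "union",
    outdir: str | Path = "compare-out",
) -> Network:
    """Set-algebra run: result edge-list plus affiliation TSVs for the union."""
    out = _prepare(outdir)
    if op == "union":
        result, table = union_networks(collection, selection)
        table.write_tsv(out / "nodes.tsv", out / "edges.tsv")
    elif op == "intersect":
        result = intersect_networks(collection, selection)
    elif op == "exclusive":
        if selection is None:
            raise ValueError("exclusive requires an explicit selection")
        result = exclusive_networks(collection, selection)
    else:
        raise ValueError(f"unknown op {op!r}; use union, intersect or exclusive")
    write_edge_list(result, out / f"{op}.edges.tsv")
    write_node_list(result.nodes, out / f"{op}.nodes.txt")
    _manifest(out, f"compare:{op}",
              {"networks": collection.names, "selection": selection})
    return result


def run_metrics(
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
    outdir: str | Path = "metrics-out",
) -> None:
    """Global-properties table, per-network node metrics, JSON summary."""
    out = _prepare(outdir)
    nets = collection.select(selection)
    table = global_properties_table(nets)
    table.to_csv(out / "global_properties.tsv", sep="\t")
    for net in nets:
        node_properties(net).to_csv(out / f"node_metrics.{net.name}.tsv", sep="\t")
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(json.loads(table.to_json(orient="index")), fh, indent=2, sort_keys=True)
        fh.write("\n")
    _manifest(out, "metrics", {"networks": collection.names, "selection": selection})


def run_significance(
    collection: NetworkCollection,
    query: str,
    selection: Sequence[str] | None = None,
    background: Network | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
    outdir: str | Path = "significance-out",
):
    """Z-test one network of the collection against the union (or a given
    background); writes the report (TSV + JSON) and all null samples."""
    out = _prepare(outdir)
    if background is None:
        union, _ = union_networks(collection, selection)
        background = union.renamed("union")
    report = assess_significance(
        collection[query], background, n_reps=n_reps, rng=seed,
        alternative=alternative,
    )
    report.to_frame().to_csv(out / "significance.tsv", sep="\t")
    report.write_null_samples(out / "null_samples.tsv")
    with open(out / "significance.json", "w", encoding="utf-8") as fh:
        json.dump(
            json.loads(report.to_frame().to_json(orient="index")),
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    _manifest(out, "significance",
              {"query": query, "background": background.name,
               "n_reps": n_reps, "alternative": alternative}, seed=seed)
    return report


def run_similarity(
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
    method: str = "jaccard_edge",
    linkage: str = "average",
    outdir: str | Path = "similarity-out",
):
    """Similarity matrix TSV + dendrogram newick + bubble-chart TSV."""
    out = _prepare(outdir)
    matrix = similarity_matrix(collection, selection, method)
    matrix.write_tsv(out / "similarity_matrix.tsv")
    dendro = cluster_networks(matrix, linkage)
    dendro.write_newick(out / "dendrogram.nwk")
    bubble_chart_data(matrix).to_csv(out / "bubble_chart.tsv", sep="\t", index=False)
    _manifest(out, "similarity",
              {"networks": collection.names, "selection": selection,
               "method": method, "linkage": linkage})
    return matrix, dendro


def run_community(
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
    outdir: str | Path = "community-out",
):
    """Fast-greedy communities of the union: membership, cross-network
    profile, and one plain node-list per community (enrichment-tool input)."""
    out = _prepare(outdir)
    union, _ = union_networks(collection, selection)
    partition = detect_communities(union)
    partition.to_frame().to_csv(out / "communities.tsv", sep="\t", index=False)
    profile = community_distribution(partition, collection, selection)
    profile.to_csv(out / "profile.tsv", sep="\t")
    for cid in partition.ids:
        sub = community_subgraph(union, partition, cid)
        write_node_list(sub.nodes, out / f"community.{cid}.nodes.txt")
    _manifest(out, "community",
              {"networks": collection.names, "selection": selection,
               "modularity": partition.modularity,
               "n_communities": len(partition.communities)})
    return partition


def run_paths(
    collection: NetworkCollection,
    selection: Sequence[str] | None = None,
    source: str | None = None,
    target: str | None = None,
    sources=None,
    targets=None,
    network: str | None = None,
    outdir: str | Path = "paths-out",
):
    """Shortest-path run: either a single pair compared across networks and
    their union, or a batch sources × targets product on one network."""
    out = _prepare(outdir)
    if source is not None and target is not None:
        frame = compare_paths(collection, selection, source, target)
        inputs = {"source": source, "target": target, "selection": selection}
    elif sources is not None and targets is not None:
        if network is None:
            raise ValueError("batch mode needs the target network's name")
        results = batch_shortest_paths(collection[network], sources, targets)
        frame = paths_table(results)
        inputs = {"network": network, "mode": "batch"}
    else:
        raise ValueError("provide source+target or sources+targets")
    frame.to_csv(out / "paths.tsv", sep="\t", index=False)
    _manifest(out, "paths", inputs)
    return frame


def run_export(
    net: Network,
    outdir: str | Path = "export-out",
    formats: Sequence[str] = ("edge-list", "gml"),
) -> None:
    """Export a network as Cytoscape-compatible edge-list and/or GML."""
    out = _prepare(outdir)
    for fmt in formats:
        if fmt == "edge-list":
            write_edge_list(net, out / f"{net.name}.edges.tsv")
        elif fmt == "gml":
            write_gml(net, out / f"{net.name}.gml")
        else:
            raise ValueError(f"unknown format {fmt!r}; use edge-list or gml")
    _manifest(out, "export", {"network": net.name, "formats": list(formats)})


def run_simulate(
    spec: FixtureSpec | None = None,
    outdir: str | Path = "simulate-out",
    seed: int | None = None,
) -> NetworkCollection:
    """Generate a synthetic background + overlay series and write it out as
    standard edge-list / node-list files with a ground-truth JSON sidecar."""
    out = _prepare(outdir)
    if spec is None:
        spec = FixtureSpec(seed=seed if seed is not None else 0)
    elif seed is not None:
        spec = FixtureSpec(**{**spec.__dict__, "seed": seed})
    background = generate_background(spec)
    lists, truth = generate_overlay_series(background, spec)
    write_edge_list(background, out / "background.edges.tsv")
    for i, nodes in enumerate(lists, start=1):
        write_node_list(nodes, out / f"overlay.net{i}.nodes.txt")
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    overlays = overlay_collection_from_series(background, lists)
    _manifest(out, "simulate", {"spec": {**spec.__dict__}}, seed=spec.seed)
    return NetworkCollection([background] + overlays)
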