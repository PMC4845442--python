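"""Random-subnetwork null model and Z-test for global network properties.

Is a query network (say, the induced network of perturbed genes) unusually
dense, clustered, or stretched compared with what an equally sized chunk of
the background interactome would show? The null model answers by drawing
many random induced subnetworks of the background — a uniform node sample
of the query's size plus all background edges among the sampled nodes —
computing the global properties of each, and Z-testing the query's observed
values against the resulting null distributions.

The Z-test assumes approximate normality of the null; for lumpy, discrete
properties (diameter on small samples, clustering on very sparse samples)
the p-values are indicative only. A null with zero spread is flagged and
yields no Z-score. No multiple-testing correction is applied across
properties; raw p-values are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import Network

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PROPERTIES",
    "NullDistribution",
    "PropertySignificance",
    "SignificanceReport",
    "sample_induced_subnetwork",
    "build_null",
    "assess_significance",
]

DEFAULT_PROPERTIES = (
    "density",
    "clustering_coefficient",
    "average_path_length",
    "diameter",
)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _subgraph_properties(g: nx.Graph, props: Sequence[str]) -> dict[str, float]:
    """Global properties of an (already induced) networkx subgraph."""
    out: dict[str, float] = {}
    n = g.number_of_nodes()
    if "density" in props:
        m = g.number_of_edges()
        out["density"] = 2.0 * m / (n * (n - 1)) if n >= 2 else 0.0
    if "clustering_coefficient" in props:
        out["clustering_coefficient"] = nx.transitivity(g)
    if "average_path_length" in props or "diameter" in props:
        total = count = diam = 0
        for s, lengths in nx.all_pairs_shortest_path_length(g):
            for t, d in lengths.items():
                if t == s:
                    continue
                total += d
                count += 1
                diam = max(diam, d)
        out["average_path_length"] = total / count if count else 0.0
        out["diameter"] = float(diam)
    return {k: out[k] for k in props}


@dataclass(frozen=True)
class NullDistribution:
    """Samples of one global property over random induced subnetworks."""

    property_name: str
    samples: np.ndarray
    subnetwork_size: int
    seed: int | None = None

    @property
    def n_reps(self) -> int:
        return len(self.samples)

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        """Sample standard deviation (ddof=1)."""
        return float(np.std(self.samples, ddof=1))

    @property
    def degenerate(self) -> bool:
        """True when the null has no spread — no Z-score can be formed."""
        return self.sd == 0.0


def sample_induced_subnetwork(
    background: Network,
    n: int,
    rng: np.random.Generator | int | None = None,
    name: str = "random-subnetwork",
) -> Network:
    """Uniformly sample ``n`` background nodes and induce their edges."""
    if not 1 <= n <= background.n_nodes:
        raise ValueError(
            f"subnetwork size {n} out of range [1, {background.n_nodes}]"
        )
    rng = _as_rng(rng)
    pool = sorted(background.nodes)
    chosen = rng.choice(len(pool), size=n, replace=False)
    return background.induced_subgraph((pool[i] for i in chosen), name=name)


def build_null(
    background: Network,
    n: int,
    n_reps: int = 10_000,
    properties: Sequence[str] = DEFAULT_PROPERTIES,
    rng: np.random.Generator | int | None = None,
) -> dict[str, NullDistribution]:
    """Null distributions of global properties for size-``n`` random subnetworks.

    Draws ``n_reps`` uniform node samples of size ``n`` from the background
    and records each requested property of the induced subnetwork. Fully
    deterministic for a fixed seed. Default ``n_reps`` is 10,000 draws.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to estimate a spread")
    unknown = [p for p in properties if p not in DEFAULT_PROPERTIES]
    if unknown:
        raise ValueError(
            f"unknown properties {unknown}; valid: {list(DEFAULT_PROPERTIES)}"
        )
    if not 1 <= n <= background.n_nodes:
        raise ValueError(
            f"subnetwork size {n} out of range [1, {background.n_nodes}]"
        )
    rng = _as_rng(rng)
    g = background.to_networkx()
    pool = np.array(sorted(background.nodes))
    samples: dict[str, list[float]] = {p: [] for p in properties}
    for _ in range(n_reps):
        idx = rng.choice(len(pool), size=n, replace=False)
        sub = g.subgraph(pool[idx])
        vals = _subgraph_properties(sub, properties)
        for p in properties:
            samples[p].append(vals[p])
    out: dict[str, NullDistribution] = {}
    for p in properties:
        dist = NullDistribution(p, np.asarray(samples[p], dtype=float), n)
        if dist.degenerate:
            logger.warning(
                "null distribution of %r has zero spread; Z undefined", p
            )
        out[p] = dist
    return out


@dataclass(frozen=True)
class PropertySignificance:
    property_name: str
    observed: float
    null_mean: float
    null_sd: float
    z_score: float  # NaN when the null is degenerate
    p_value: float  # NaN when the null is degenerate
    degenerate: bool


@dataclass(frozen=True)
class SignificanceReport:
    """Z-test results for every assessed property of one query network."""

    query_name: str
    background_name: str
    subnetwork_size: int
    n_reps: int
    alternative: str
    results: Mapping[str, PropertySignificance]
    nulls: Mapping[str, NullDistribution] = field(repr=False, default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "property": r.property_name,
                "observed": r.observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z_score": r.z_score,
                "p_value": r.p_value,
                "degenerate": r.degenerate,
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows).set_index("property")

    def write_null_samples(self, path: str | Path) -> None:
        """Export all null samples as a TSV (one column per property)."""
        pd.DataFrame(
            {p: d.samples for p, d in self.nulls.items()}
        ).to_csv(path, sep="\t", index=False)


def _z_and_p(observed: float, dist: NullDistribution, alternative: str) -> tuple[float, float]:
    if dist.degenerate:
        return float("nan"), float("nan")
    z = (observed - dist.mean) / dist.sd
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    else:
        raise ValueError(
            "alternative must be 'two-sided', 'greater' or 'less'"
        )
    return float(z), float(min(p, 1.0))


def assess_significance(
    query: Network,
    background: Network,
    n_reps: int = 10_000,
    properties: Sequence[str] = DEFAULT_PROPERTIES,
    rng: np.random.Generator | int | None = None,
    alternative: str = "two-sided",
) -> SignificanceReport:
    """Z-test the query's global properties against size-matched random
    subnetworks of the background.

    The null subnetwork size equals the query's node count. The background
    is typically the union of the compared networks, or any user-supplied
    network; query nodes outside the background are allowed but warned
    about, since the null then compares against a pool the query could not
    have been drawn from.
    """
    if query.n_nodes == 0:
        raise ValueError("query network is empty")
    stray = query.nodes - background.nodes
    if stray:
        logger.warning(
            "%d query node(s) absent from background %r",
            len(stray),
            background.name,
        )
    nulls = build_null(background, query.n_nodes, n_reps, properties, rng)
    observed = _subgraph_properties(query.to_networkx(), list(properties))
    results: dict[str, PropertySignificance] = {}
    for p in properties:
        z, pv = _z_and_p(observed[p], nulls[p], alternative)
        results[p] = PropertySignificance(
            p, observed[p], nulls[p].mean, nulls[p].sd, z, pv, nulls[p].degenerate
        )
    return SignificanceReport(
        query.name, background.name, query.n_nodes, n_reps, alternative, results, nulls
    )
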