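# Methods

This note records the models, conventions and design choices behind
`netcompare`, in the package's own terms.

## Data model

A network is a named undirected simple graph: a set of case-sensitive
string node identifiers and a set of unordered edges stored canonically
(lexicographically sorted pairs). Direction in input files is ignored,
duplicate and reversed edges collapse, and self-loops are dropped at parse
time with a logged warning (real interaction dumps contain them; erroring
would make such files unloadable). Network equality compares node and edge
sets only — the name is a label — which is what makes algebraic laws such
as "union of one network equals that network" testable. Duplicate edges
across input lines are deliberately *not* counted: the comparison semantics
throughout are set semantics, not multigraph semantics.

Overlay networks are induced subgraphs of a background on a supplied node
list. By default only interconnected overlay nodes are kept
(`keep_isolates=False`); the flag exists because lists routinely contain
genes with no interactions among themselves, and whether those should
appear as isolated nodes is a presentation choice, not a modelling one.
Overlay nodes absent from the background are reported and never silently
added.

## Set algebra and affiliation

Union, intersection and exclusive regions are computed at edge and node
granularity. Intersection requires presence in **all** selected networks;
its node set additionally keeps isolated nodes common to every network
(legitimate when overlays kept isolates). Exclusivity is relative to the
unselected remainder: an edge (node) is exclusive to a selection when it
occurs in at least one selected network and no unselected one, so selecting
the whole collection is an error (no complement). Endpoints of an exclusive
edge that are themselves shared stay in the returned graph to keep it
valid; `exclusive_node_set` reports pure node-level exclusivity.

The affiliation table stores, for every union node and edge, its boolean
membership vector across the selected networks. Each vector has at least
one true entry by construction; column sums of the edge matrix equal
per-network edge counts (a conservation law the tests exercise).

## Metrics conventions

* Density `2m / n(n−1)` for `n ≥ 2`, else 0.
* Clustering coefficient defaults to **global transitivity**
  (3·triangles / connected triples) with mean local clustering available
  via `clustering="average_local"`. Both are implemented because summary
  tables in the literature often do not say which was used; the default is
  documented rather than guessed as anyone's intent.
* Average path length and diameter are computed over **reachable ordered
  pairs only**, so they stay finite on disconnected graphs; closeness uses
  the within-reachable-set form `(r−1)/Σd` and eccentricity is
  per-component, for the same reason.
* Betweenness is the unnormalized shortest-path count through a node over
  unordered pairs, endpoints excluded; a flag divides by `(n−1)(n−2)/2`.
* "Centrality" as a sixth node metric is read as **eigenvector
  centrality**, the standard measure distinct from degree, betweenness and
  closeness, which are listed separately.
* The empty network yields an all-zero report flagged `degenerate` rather
  than NaNs or an exception, so batch summaries over heterogeneous inputs
  do not fall over.

Standard metric computations are delegated to networkx; the test suite
checks them (and everything authored here) against independent brute-force
oracles — exhaustive path enumeration, triangle counting, k-core peeling —
on hundreds of small random graphs.

## Random-subnetwork significance test

The "size" of a subnetwork is its node count, and a random subnetwork is a
uniform node sample of that size with all background edges induced. This
matches how query networks themselves arise in the overlay workflow (a gene
list induced on the interactome), which is why a node-induced null rather
than, say, an edge-sampled or degree-preserving null is the reference; a
configuration-model null would be a meaningful upgrade but is out of scope.
The query's own nodes are not excluded from the sampling pool — the null
hypothesis is precisely that the query *is* such a sample.

Defaults: 10,000 draws; properties density, clustering coefficient, average
path length, diameter; background = the union of the compared networks
unless a user network is supplied. The Z-test uses the sample standard
deviation (ddof = 1) and is two-sided by default as the conservative choice,
with one-sided alternatives by flag. A null with zero spread (e.g. density
on a complete background) is flagged and produces no Z-score. No
multiple-testing correction is applied across the four properties; raw
p-values are reported and say so.

The Z-test assumes the null is approximately normal. That holds well for
density (an induced edge count is a sum of weakly dependent indicators) at
moderate sizes, and poorly for small-sample diameter or near-zero-triangle
clustering, whose nulls are discrete and lumpy — p-values for those are
indicative. The calibration acceptance test therefore measures the type-I
error rate on density, where the modelling assumption actually applies.

## Similarity and clustering

Node and edge Jaccard are plain set Jaccards; two entirely empty networks
are rejected (0/0) rather than scored. The neighborhood similarity index
sums, over every node of the combined node set, the Jaccard overlap of its
first-neighbor sets in the two networks; a node absent from one network has
an empty neighbor set there, so it contributes its term's numerator only
through the other network — i.e. nothing. A node isolated in **both**
networks is a 0/0 term: it contributes 0 and is counted in
`undefined_terms`, so keep-isolates overlays can never inflate similarity.
The normalized score (raw / union node count) puts all three methods on a
shared `[0, 1]` scale and is the clustering input; the raw score is always
reported alongside. Note the self-similarity consequence: a network with
isolates has normalized self-NSI below 1, which the honest diagonal of an
NSI similarity matrix reflects.

Clustering is scipy agglomerative linkage (average by default; single and
complete available — no linkage is canonical for this use) on distance
`1 − similarity`, with leaves handed to scipy in lexicographic name order
so tie-breaking, and hence the dendrogram and its newick serialization, is
reproducible. Newick branch lengths are parent merge height minus child
merge height, leaves at height 0. Both node- and edge-based Jaccard (and
NSI) feed the same clustering entry point; no single method is claimed as
"the" default beyond the function signature's `jaccard_edge`.

## Community detection

Greedy modularity maximization (Clauset–Newman–Moore): start from
singletons, repeatedly merge the pair of edge-connected communities with
the largest modularity gain `ΔQ = E_ij/m − d_i d_j / 2m²`, and cut at the
maximum-modularity partition along the merge path (merging disconnected
communities can only lower Q, so components are never merged and the loop
stops when no inter-community edges remain; isolated nodes stay
singletons). The implementation is authored here rather than delegated
because reproducibility across platforms requires explicit tie-breaking:
equal gains (within 1e−12) resolve to the pair with lexicographically
smallest member labels, and a community is labelled by its smallest member.
Communities are reported in descending size (ties by smallest member) as
C1, C2, …. Modularity of the edgeless graph is defined as 0. The cut is at
maximum modularity rather than a user-chosen merge step — the natural
reading of "the" partition an automatic detector returns.

Detection is intended for the union network; the distribution profile then
counts, per community × per network, member nodes present and edges of that
network internal to the community, which shows where in the series each
module lives.

## Shortest paths

Unweighted BFS. Among equal-length paths the lexicographically smallest
node sequence is returned, computed by walking from the source and always
taking the smallest neighbor whose distance-to-target decreases — a
deterministic choice that costs one extra BFS. `source == target` yields
the length-0 path `[source]` (the least surprising convention; it makes
batch products total). Unreachable is a result, not an error; an endpoint
missing from a network is an error for a direct query but a reported
per-pair status in batch and cross-network comparison, where partial
coverage is the normal case. `all_shortest_paths` enumerates minimum-hop
paths for small cases only (their number can grow exponentially).

## Synthetic world

The generator emulates the package's motivating workload: a background
interactome plus a series of overlay node lists with controlled
consecutive overlap. Defaults — a 500-node preferential-attachment
background with 3 edges per new node (~1,490 edges, mean degree ≈ 6,
heavy-tailed like real PPI degree distributions; a uniform random-graph
model is available but is not the default because it lacks hubs), eight
overlay lists (two condition series × four time points is the motivating
shape) of 60 nodes each, consecutive overlap fraction 0.5 (neighboring
time points share about half their perturbed genes). The first list is a
uniform sample; each next list keeps `round(overlap · size)` members of
its predecessor and fills with fresh nodes; the exact realized overlaps
are emitted as a ground-truth JSON sidecar so tests are self-checking.
Backgrounds are reduced to their largest connected component.

What the generator does **not** emulate: expression-derived node selection
(overlays are uniform, not biased toward dense neighborhoods the way
coordinated perturbation modules are), edge confidence scores, and any
annotation structure. A green pipeline test therefore establishes that the
machinery is correct and deterministic, not that biological effect sizes
are realistic.

## Numerical and determinism choices

All randomness flows through numpy `Generator` objects seeded from a
single integer; fixed seed ⇒ bit-identical null samples, reports,
partitions and dendrograms. Text outputs are sorted canonically
(edge-lists byte-deterministic; manifests contain no timestamps) so output
directories are diffable. Greedy-merge gain comparisons use a 1e−12
tolerance before the lexicographic tie-break. Eigenvector centrality uses
the dense solver with a power-iteration fallback, and returns zeros on
edgeless graphs where the measure is vacuous.

## Known limitations

* Weighted and directed graphs are out of scope; weights in edge-list
  files are ignored with a warning.
* The greedy community detector is the naive O(n·m)-per-sweep variant —
  fine up to a few thousand nodes, not tuned for full interactomes.
* Only the node-induced uniform null is provided; no degree-preserving
  null model.
* GO/functional enrichment of communities is intentionally external: the
  per-community plain node-list export is the hand-off point.
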