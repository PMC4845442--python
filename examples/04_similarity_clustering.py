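"""Pairwise network similarity, clustering of networks, and bubble data.

Compares three networks under node-Jaccard, edge-Jaccard and the
neighborhood similarity index (NSI), clusters them on 1 - similarity, and
prints the dendrogram as newick plus the long-form bubble-chart table.
Networks that keep the same neighborhoods score high under NSI even when
their edge overlap is modest.
"""

from netcompare import (
    Network,
    NetworkCollection,
    bubble_chart_data,
    cluster_networks,
    nsi,
    similarity_matrix,
)

A = Network("A", edges=[("a", "b"), ("b", "c"), ("c", "d")])
B = Network("B", edges=[("b", "c"), ("c", "d"), ("d", "e")])
C = Network("C", edges=[("a", "b"), ("d", "e")])
coll = NetworkCollection([A, B, C])

score = nsi(A, B)
print(f"NSI(A, B): raw={score.raw:.3f} over {len(A.nodes | B.nodes)} union "
      f"nodes -> normalized={score.normalized:.3f}")

for method in ("jaccard_node", "jaccard_edge", "nsi_normalized"):
    m = similarity_matrix(coll, method=method)
    print(f"\n{method} similarity matrix:")
    print(m.to_frame().round(3).to_string())

m = similarity_matrix(coll, method="jaccard_edge")
dendro = cluster_networks(m, linkage="average")
print("\naverage-linkage dendrogram (newick, heights = 1 - similarity):")
print(dendro.to_newick())
print("\nbubble-chart table (most similar pair first):")
print(bubble_chart_data(m).to_string(index=False))
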