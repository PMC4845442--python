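"""Union, intersection and exclusive regions of two small networks.

Builds the classic two-network fixture and prints which nodes and edges are
shared, which are specific to each network, and the full edge membership
matrix (the data behind per-node pie and edge-pie displays).
"""

from netcompare import (
    Network,
    NetworkCollection,
    edge_pie_matrix,
    exclusive_networks,
    exclusive_node_set,
    intersect_networks,
    union_networks,
)

A = Network("A", edges=[("a", "b"), ("b", "c"), ("c", "d")])
B = Network("B", edges=[("b", "c"), ("c", "d"), ("d", "e")])
coll = NetworkCollection([A, B])

union, affiliation = union_networks(coll)
print(f"union: {union.n_nodes} nodes, {union.n_edges} edges")

inter = intersect_networks(coll)
print(f"intersection edges (in both A and B): {sorted(inter.edges)}")

for name in ("A", "B"):
    excl = exclusive_networks(coll, [name])
    print(f"exclusive to {name}: edges {sorted(excl.edges)}, "
          f"nodes {sorted(exclusive_node_set(coll, [name]))}")

print("\nedge membership matrix (1 = edge occurs in that network):")
print(edge_pie_matrix(coll).to_string(index=False))
# Every row sums to >= 1 (each union edge came from somewhere) and each
# column sums to that network's edge count.
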