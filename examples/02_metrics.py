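"""Global and node-level graph properties, and a cross-network top-k table.

Shows the six global summary numbers for each network, the standard node
centralities on the union, and the top-5 union nodes by degree with their
per-network presence flags (high-degree nodes present in many networks are
the usual first suspects in a comparison).
"""

from netcompare import (
    Network,
    NetworkCollection,
    global_properties_table,
    node_properties,
    top_k_report,
    union_networks,
)

A = Network("A", edges=[("a", "b"), ("b", "c"), ("c", "d"), ("b", "d")])
B = Network("B", edges=[("b", "c"), ("c", "d"), ("d", "e"), ("c", "e")])
coll = NetworkCollection([A, B])

print("global properties (density = fraction of possible edges present):")
print(global_properties_table(coll).to_string())

union, _ = union_networks(coll)
print("\nnode centralities on the union:")
print(node_properties(union).round(3).to_string())

print("\ntop-5 union nodes by degree with per-network presence flags:")
print(top_k_report(coll, metric="degree", k=5).to_string(index=False))
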