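"""Build rank-based and value-based co-expression networks and compare them.

Simulates clustered expression data, then builds the two network types on
the same similarity matrix. The rank network keeps every gene connected
(minimum degree d) at a low edge budget; the value network at a comparable
edge count strands weakly co-expressed genes as singletons.
"""

import networkx as nx

from qcutnet import (
    compute_similarity,
    rank_network,
    simulate_clustered_expression,
    threshold_for_mean_degree,
    value_network,
)

ds = simulate_clustered_expression(n_genes=300, n_clusters=10, n_conditions=50,
                                   noise_sd=0.8, seed=0)
sim = compute_similarity(ds.expr, method="pearson")

rank = rank_network(sim, d=3)
target = 2 * rank.number_of_edges() / rank.number_of_nodes()
value = value_network(sim, threshold_for_mean_degree(sim, target))

for name, net in [("rank (d=3)", rank), (f"value (mean degree {target:.1f})", value)]:
    degrees = [net.degree[v] for v in net.nodes]
    print(f"{name:28s} edges={net.number_of_edges():4d} "
          f"min_degree={min(degrees)} max_degree={max(degrees)} "
          f"singletons={sum(1 for k in degrees if k == 0)} "
          f"components={nx.number_connected_components(net)}")

print("\nAt the same edge budget the rank network has no singletons and few")
print("components, while the global threshold over-connects tight clusters")
print("and disconnects loose ones — the motivation for rank-based construction.")
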