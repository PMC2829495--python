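"""Topology of a rank network versus its two null models.

The real-data rank network has a much larger clustering coefficient than
either null: degree-preserving rewiring keeps the degree sequence but
destroys triangles, and permuting each gene's expression destroys
co-expression before the network is even built. The degree distribution's
power-law exponent is fitted by log-log least squares.
"""

from qcutnet import (
    compute_similarity,
    fit_power_law,
    permute_expression_rows,
    rank_network,
    rewire_preserving_degrees,
    simulate_clustered_expression,
    topology_summary,
)

ds = simulate_clustered_expression(noise_sd=0.8, seed=2)
sim = compute_similarity(ds.expr, method="pearson")
net = rank_network(sim, d=3)

perm_net = rank_network(
    compute_similarity(permute_expression_rows(ds.expr, seed=2), "pearson"), d=3
)
rewired = rewire_preserving_degrees(net, seed=2)

print(f"{'network':<18s} {'C':>6s} {'<l>':>6s} {'diam':>5s} {'max_k':>6s}")
for name, g in [("real data", net), ("permuted rows", perm_net), ("rewired", rewired)]:
    s = topology_summary(g)
    print(f"{name:<18s} {s.clustering_coefficient:6.3f} {s.average_path_length:6.2f} "
          f"{s.diameter:5d} {s.max_degree:6d}")

fit = fit_power_law(topology_summary(net).degree_histogram)
print(f"\npower-law exponent of the real network: gamma = {fit.gamma:.2f}")
print("The real network's clustering coefficient C exceeds both nulls',")
print("the small-world signature; rewiring preserves degrees but not C.")
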