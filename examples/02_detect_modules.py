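"""Detect modules with Qcut and measure accuracy against planted truth.

Runs the full pipeline on the clustered-expression benchmark: simulate 600
genes in 15 clusters, build the d=4 rank network on negated Euclidean
distance, partition it with Qcut (no preset module count), and score the
result with the adjusted Rand index.
"""

from qcutnet import (
    adjusted_rand_index,
    compute_similarity,
    qcut_partition,
    rank_network,
    simulate_clustered_expression,
)

for noise_sd in (0.2, 0.8, 1.2):
    ds = simulate_clustered_expression(noise_sd=noise_sd, seed=1)
    sim = compute_similarity(ds.expr, method="negative_euclidean")
    net = rank_network(sim, d=4)
    part, score = qcut_partition(net, seed=1)
    ari = adjusted_rand_index(ds.truth, part)
    k = len(set(part.values()))
    print(f"noise_sd={noise_sd}: Q={score.q:.3f}  modules={k:2d}  ARI={ari:.3f}")

print("\nQ is the modularity of the recovered partition; ARI=1 means the 15")
print("planted clusters were recovered exactly. Accuracy degrades only at")
print("noise levels where cluster templates are barely distinguishable.")
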