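"""Hypergeometric attribute enrichment of detected modules.

Annotates a third of each planted cluster's genes with a cluster-specific
attribute, recovers modules with Qcut, and tests every (module, attribute)
pair with the cumulative hypergeometric test, Bonferroni-corrected.
"""

import numpy as np

from qcutnet import (
    compute_similarity,
    enrichment_summary,
    qcut_partition,
    rank_network,
    simulate_clustered_expression,
)
import pandas as pd

ds = simulate_clustered_expression(n_genes=300, n_clusters=6, n_conditions=40,
                                   noise_sd=0.6, seed=5)
net = rank_network(compute_similarity(ds.expr, "negative_euclidean"), d=4)
part, _ = qcut_partition(net, seed=5)

rng = np.random.default_rng(5)
genes = list(ds.expr.index)
incidence = np.zeros((len(genes), 6), dtype=int)
for i, g in enumerate(genes):
    if rng.random() < 0.33:
        incidence[i, ds.truth[g] - 1] = 1
attrs = pd.DataFrame(incidence, index=genes, columns=[f"GO:{j:04d}" for j in range(6)])

summary, results = enrichment_summary(part, attrs, alpha_grid=[0.05, 0.01, 0.001])
print(summary.to_string(index=False))
top = sorted(results, key=lambda r: r.p_corrected)[:3]
print("\nmost enriched (module, attribute) pairs:")
for r in top:
    print(f"  module {r.module_label} x {r.attribute_id}: overlap {r.overlap}/"
          f"{r.module_size}, fold {r.fold_enrichment:.1f}, "
          f"corrected p = {r.p_corrected:.2e}")
print("\nEach detected module is dominated by one planted attribute at tiny")
print("corrected p-values; the per-alpha table counts significant pairs and")
print("the fraction of modules with at least one enriched attribute.")
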