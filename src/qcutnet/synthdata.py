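"""Seeded generators for the simulation inputs used across the toolkit.

Three generators cover the study's simulation designs:

* clustered microarray data — ~600 genes in 15 clusters under 50
  conditions; genes in a cluster share a template profile (standard normal
  per condition on the log scale, i.e. log-normal intensities) plus i.i.d.
  Gaussian noise, the difficulty knob;
* Gaussian geometric clouds — 1000 points in a chosen dimension, used to
  measure at which neighbor count ``d`` the rank-based network becomes one
  connected component;
* planted-partition graphs — known groups with distinct within/between
  edge probabilities, the standard ground-truth fixture for module
  detection.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NOISE_GRID",
    "SyntheticDataset",
    "gaussian_cloud",
    "planted_partition_graph",
    "simulate_clustered_expression",
]

#: Noise standard deviations spanning easy to near-unclusterable data.
NOISE_GRID = (0.0, 0.2, 0.4, 0.8, 1.2)


@dataclass(frozen=True)
class SyntheticDataset:
    """Expression matrix bundled with its planted true partition."""

    expr: pd.DataFrame
    truth: dict[str, int]
    params: dict


def _default_sizes(n_genes: int, n_clusters: int) -> list[int]:
    base = n_genes // n_clusters
    rem = n_genes % n_clusters
    return [base + (1 if i < rem else 0) for i in range(n_clusters)]


def simulate_clustered_expression(
    n_genes: int = 600,
    n_clusters: int = 15,
    n_conditions: int = 50,
    noise_sd: float = 0.4,
    cluster_sizes: list[int] | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate clustered log-scale expression with Gaussian noise.

    Each cluster draws one template profile with i.i.d. standard-normal
    values per condition; each member gene is the template plus i.i.d.
    N(0, noise_sd²) noise. Cluster sizes default to as equal as possible
    (15 clusters of 40 at the defaults); an explicit size vector must sum
    to ``n_genes``.
    """
    if n_clusters > n_genes:
        raise ValueError("more clusters than genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if cluster_sizes is None:
        cluster_sizes = _default_sizes(n_genes, n_clusters)
    if len(cluster_sizes) != n_clusters or sum(cluster_sizes) != n_genes:
        raise ValueError(
            f"cluster sizes must be {n_clusters} values summing to {n_genes}"
        )
    rng = np.random.default_rng(seed)
    templates = rng.standard_normal((n_clusters, n_conditions))
    rows = []
    truth: dict[str, int] = {}
    gene_ids = []
    g = 0
    for c, size in enumerate(cluster_sizes):
        noise = rng.standard_normal((size, n_conditions)) * noise_sd
        rows.append(templates[c] + noise)
        for _ in range(size):
            gene_id = f"g{g + 1:04d}"
            gene_ids.append(gene_id)
            truth[gene_id] = c + 1
            g += 1
    expr = pd.DataFrame(
        np.vstack(rows),
        index=gene_ids,
        columns=[f"cond{j + 1:02d}" for j in range(n_conditions)],
    )
    params = {
        "n_genes": n_genes,
        "n_clusters": n_clusters,
        "n_conditions": n_conditions,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return SyntheticDataset(expr=expr, truth=truth, params=params)


def gaussian_cloud(n_points: int = 1000, dim: int = 20, seed: int = 0) -> pd.DataFrame:
    """Sample ``n_points`` i.i.d. standard-Gaussian points in ``dim`` dimensions."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((n_points, dim)),
        index=[f"p{i + 1:04d}" for i in range(n_points)],
        columns=[f"dim{j + 1:02d}" for j in range(dim)],
    )


def planted_partition_graph(
    sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[nx.Graph, dict[str, int]]:
    """Random graph with planted groups: within-group edges with probability
    ``p_in``, between-group with ``p_out``. Returns the graph and the planted
    partition (labels 1..len(sizes))."""
    if not 0 <= p_out <= p_in <= 1:
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    rng = np.random.default_rng(seed)
    labels: list[int] = []
    for g, size in enumerate(sizes):
        labels.extend([g + 1] * size)
    n = len(labels)
    ids = [f"v{i + 1:03d}" for i in range(n)]
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if labels[i] == labels[j] else p_out
            if rng.random() < p:
                graph.add_edge(ids[i], ids[j])
    truth = {ids[i]: labels[i] for i in range(n)}
    return graph, truth
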