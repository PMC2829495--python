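"""Topology statistics and the two null models for co-expression networks.

The diagnostics target the three properties commonly reported for
biological networks: small-world (large clustering coefficient with short
paths), scale-free (power-law degree distribution P(k) = c·k^-gamma), and
hierarchical modularity (clustering coefficient falling with degree). Two
nulls isolate what the real data contribute: degree-preserving edge
rewiring destroys local clustering while keeping the degree sequence, and
per-gene permutation of the expression matrix destroys co-expression while
keeping each gene's value distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PowerLawFit",
    "TopologySummary",
    "fit_power_law",
    "permute_expression_rows",
    "rewire_preserving_degrees",
    "topology_summary",
]


@dataclass(frozen=True)
class TopologySummary:
    """Summary statistics of an undirected network.

    The clustering coefficient ``C_i = 2 n_i / (k_i (k_i - 1))`` (``n_i`` =
    links among node i's ``k_i`` neighbors) is defined as 0 for degree-1
    nodes and averaged over non-singleton nodes only. Path statistics
    (average path length, diameter) are over reachable pairs only.
    """

    n_nodes: int
    n_edges: int
    n_singletons: int
    largest_component_size: int
    mean_degree: float
    max_degree: int
    clustering_coefficient: float
    average_path_length: float
    diameter: int
    degree_histogram: dict[int, int] = field(default_factory=dict)
    ck_curve: dict[int, float] = field(default_factory=dict)


def topology_summary(net: nx.Graph) -> TopologySummary:
    """Compute all topology statistics of a network (unweighted paths)."""
    n = net.number_of_nodes()
    if n == 0:
        return TopologySummary(0, 0, 0, 0, 0.0, 0, 0.0, 0.0, 0)
    degrees = dict(net.degree())
    deg_vals = list(degrees.values())
    singletons = sum(1 for k in deg_vals if k == 0)
    components = list(nx.connected_components(net)) if n else []
    largest = max((len(c) for c in components), default=0)

    clustering = nx.clustering(net)  # degree<2 nodes get 0
    non_single = [v for v in net.nodes if degrees[v] >= 1]
    c_mean = float(np.mean([clustering[v] for v in non_single])) if non_single else 0.0

    # exact BFS from every node; each unordered reachable pair counted once
    total_len = 0
    n_pairs = 0
    diameter = 0
    for v in net.nodes:
        lengths = nx.single_source_shortest_path_length(net, v)
        for u, length in lengths.items():
            if u == v:
                continue
            total_len += length
            n_pairs += 1
            diameter = max(diameter, length)
    avg_path = total_len / n_pairs if n_pairs else 0.0

    hist: dict[int, int] = {}
    for k in deg_vals:
        hist[k] = hist.get(k, 0) + 1
    ck: dict[int, float] = {}
    for k in sorted(set(deg_vals)):
        members = [v for v in net.nodes if degrees[v] == k]
        ck[k] = float(np.mean([clustering[v] for v in members]))

    return TopologySummary(
        n_nodes=n,
        n_edges=net.number_of_edges(),
        n_singletons=singletons,
        largest_component_size=largest,
        mean_degree=2.0 * net.number_of_edges() / n,
        max_degree=max(deg_vals),
        clustering_coefficient=c_mean,
        average_path_length=avg_path,
        diameter=diameter,
        degree_histogram=hist,
        ck_curve=ck,
    )


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of P(k) = c * k**-gamma to a degree histogram."""

    gamma: float
    c: float
    k_range: tuple[int, int]


def fit_power_law(degree_histogram: dict[int, int], method: str = "ls") -> PowerLawFit:
    """Fit a power law to a degree histogram f(k).

    ``method="ls"`` (default): least-squares line on (log10 k, log10 f(k))
    over degrees k >= 1 with f(k) > 0; gamma is the negated slope and c the
    back-transformed intercept. ``method="mle"``: the discrete maximum
    likelihood estimator gamma = 1 + n / sum(ln(k / (kmin - 1/2))), with c
    reported as the empirical frequency normalizer. Requires at least three
    distinct supported degrees.
    """
    pts = sorted((k, f) for k, f in degree_histogram.items() if k >= 1 and f > 0)
    if len(pts) < 3:
        raise ValueError(f"need >=3 distinct degrees with nonzero frequency, got {len(pts)}")
    ks = np.array([k for k, _ in pts], dtype=float)
    fs = np.array([f for _, f in pts], dtype=float)
    k_range = (int(ks[0]), int(ks[-1]))
    if method == "ls":
        slope, intercept = np.polyfit(np.log10(ks), np.log10(fs), 1)
        return PowerLawFit(gamma=float(-slope), c=float(10.0**intercept), k_range=k_range)
    if method == "mle":
        kmin = ks[0]
        n_obs = fs.sum()
        gamma = 1.0 + n_obs / float((fs * np.log(ks / (kmin - 0.5))).sum())
        return PowerLawFit(gamma=float(gamma), c=float(n_obs), k_range=k_range)
    raise ValueError(f"unknown method {method!r}")


def rewire_preserving_degrees(
    net: nx.Graph, seed: int = 0, n_swaps: int | None = None
) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Attempts ``n_swaps`` (default 10·|E|) swaps of edge pairs
    (a–b, c–d) → (a–d, c–b); any attempt that would create a self-loop or a
    duplicate edge is rejected, so every node's degree is exactly preserved.
    Networks with no legal swap (e.g. a triangle) come back unchanged.
    Edge weights are not preserved; the null is used for unweighted
    topology statistics.
    """
    if net.number_of_edges() < 2:
        return net.copy()
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)
    edges = list(g.edges)
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    for _ in range(n_swaps):
        i, j = rng.integers(len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed: a-d, c-b
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
    return g


def permute_expression_rows(expr: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Permute each row's values by an independent uniform permutation.

    Destroys all between-gene co-expression while preserving each gene's
    multiset of values; the basis of the permuted-data null network.
    """
    rng = np.random.default_rng(seed)
    x = expr.to_numpy(dtype=float).copy()
    for i in range(x.shape[0]):
        x[i] = x[i, rng.permutation(x.shape[1])]
    return pd.DataFrame(x, index=expr.index, columns=expr.columns)
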