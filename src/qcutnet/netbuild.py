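"""Pairwise similarity and co-expression network construction.

Two construction strategies are provided. The *rank-based* network connects
each entity to its ``d`` most similar partners and takes the union over all
entities; because ranking is asymmetric, node degrees adapt to local
co-expression strength (minimum degree ``d``, mean degree between ``d`` and
``2d``). The *value-based* network applies one global similarity threshold,
which tends to over-connect strongly co-expressed modules while leaving
weakly co-expressed genes as singletons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SimilarityMatrix",
    "compute_similarity",
    "rank_network",
    "threshold_for_mean_degree",
    "value_network",
]

#: Similarity assigned to zero-variance profiles under Pearson, so that flat
#: genes rank strictly last for every partner.
ZERO_VARIANCE_SENTINEL = -np.inf


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric entity × entity similarity; larger always means more similar.

    ``kind`` is ``"pearson"`` (values in [-1, 1]) or ``"negative_euclidean"``
    (the negated Euclidean distance, values in (-inf, 0]). The diagonal is
    ignored by every consumer.
    """

    entity_ids: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match entity ids")

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle similarities as a flat vector (each pair once)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def compute_similarity(expr: pd.DataFrame, method: str = "pearson") -> SimilarityMatrix:
    """Compute all pairwise profile similarities.

    Parameters
    ----------
    expr
        Entities × conditions expression matrix (log scale).
    method
        ``"pearson"`` for the Pearson correlation coefficient, or
        ``"negative_euclidean"`` for the negated Euclidean distance, so that
        a larger value means more similar under both methods.

    Under Pearson, rows with zero variance have no defined correlation; their
    similarities are set to ``-inf`` so they rank last, and a warning is
    emitted.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 conditions to compute similarities")
    x = expr.to_numpy(dtype=float)
    ids = tuple(str(i) for i in expr.index)
    if method == "pearson":
        sd = x.std(axis=1)
        flat = sd == 0.0
        if flat.any():
            names = [ids[i] for i in np.flatnonzero(flat)]
            warnings.warn(
                f"{flat.sum()} zero-variance profile(s) under Pearson "
                f"(e.g. {names[:3]}); ranked last",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.corrcoef(x)
        sim = np.clip(sim, -1.0, 1.0)
        if flat.any():
            sim[flat, :] = ZERO_VARIANCE_SENTINEL
            sim[:, flat] = ZERO_VARIANCE_SENTINEL
        np.fill_diagonal(sim, 1.0)
    elif method == "negative_euclidean":
        sim = -squareform(pdist(x, metric="euclidean"))
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    return SimilarityMatrix(entity_ids=ids, values=sim, kind=method)


def _top_d_neighbors(values: np.ndarray, d: int) -> np.ndarray:
    """Per-row top-``d`` partner indices, ties broken by ascending index."""
    n = values.shape[0]
    masked = values.copy()
    np.fill_diagonal(masked, -np.inf)
    # stable sort on descending similarity keeps ascending index among ties
    order = np.argsort(-masked, axis=1, kind="stable")
    return order[:, :d]


def rank_network(sim: SimilarityMatrix, d: int, floor: float | None = None) -> nx.Graph:
    """Build the rank-based network: the union of every node's top-``d`` list.

    An edge exists when either endpoint lists the other among its ``d`` most
    similar partners (self excluded, ties broken by node index). With
    ``floor`` set, edges whose similarity is below ``floor`` are dropped
    after the rank step, so isolated nodes may remain as singletons.
    """
    n = sim.n
    if not 1 <= d <= n - 1:
        raise ValueError(f"d must be in [1, {n - 1}], got {d}")
    top = _top_d_neighbors(sim.values, d)
    g = nx.Graph()
    g.add_nodes_from(sim.entity_ids)
    ids = sim.entity_ids
    for i in range(n):
        for j in top[i]:
            if floor is not None and sim.values[i, j] < floor:
                continue
            g.add_edge(ids[i], ids[int(j)])
    return g


def value_network(sim: SimilarityMatrix, threshold: float) -> nx.Graph:
    """Build the value-based network: edge iff similarity ≥ ``threshold``.

    Nodes below the threshold for all partners are retained as singletons.
    """
    g = nx.Graph()
    g.add_nodes_from(sim.entity_ids)
    iu, ju = np.triu_indices(sim.n, k=1)
    keep = sim.values[iu, ju] >= threshold
    ids = sim.entity_ids
    g.add_edges_from((ids[int(i)], ids[int(j)]) for i, j in zip(iu[keep], ju[keep]))
    return g


def threshold_for_mean_degree(sim: SimilarityMatrix, target_mean_degree: float) -> float:
    """Largest threshold whose value-based network reaches a target mean degree.

    A network on ``n`` nodes with mean degree ``t`` has ``n·t/2`` edges, so
    the exact answer is the ``⌈n·t/2⌉``-th largest off-diagonal similarity.
    """
    n = sim.n
    if not 0 < target_mean_degree <= n - 1:
        raise ValueError(f"target mean degree must be in (0, {n - 1}]")
    vals = np.sort(sim.offdiagonal())[::-1]
    n_edges = math.ceil(n * target_mean_degree / 2)
    return float(vals[n_edges - 1])
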