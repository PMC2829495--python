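"""Reference networks from gene attributes and partition scoring against them.

A reference network encodes independent functional knowledge (shared GO
terms, common transcription-factor regulators, protein interactions) as a
weighted graph over the same entities as a co-expression network. A
partition found on the co-expression network is imposed unchanged on the
reference network and scored by the weighted modularity it induces there.
Because modularity compares within-module weight to a degree-preserving
random expectation, the score is not biased by the number of modules or
their size distribution, and size-preserving random shuffles of any
partition score near zero.

Attribute vectors are IDF-weighted before comparison: attribute ``j``
covering ``n_j`` of ``n`` entities gets weight ``idf_j = log(n / n_j)``, so
non-specific annotations near an ontology root contribute little, and the
edge weight between two entities is the cosine of their weighted vectors.
"""

from __future__ import annotations

from typing import Hashable

import networkx as nx
import numpy as np
import pandas as pd

from qcutnet.io import relabel_partition
from qcutnet.qcut import ModularityScore, modularity

__all__ = [
    "build_reference_network",
    "idf_weight",
    "propagate_and_filter",
    "score_partition_on_reference",
    "shuffle_partition_preserving_sizes",
]


def propagate_and_filter(
    attrs: pd.DataFrame,
    dag: nx.DiGraph | None = None,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Close annotations over ancestors, drop redundant and extreme terms.

    With an ontology DAG (child → parent edges), an entity annotated to a
    term is also annotated to all the term's ancestors. Among terms that
    end up covering exactly the same entity set only the lexicographically
    smallest id is kept, and terms covering fewer than ``min_size`` or more
    than ``max_size`` entities are removed. Filtering happens after closure
    and deduplication.
    """
    mat = attrs.to_numpy(dtype=bool).copy()
    cols = {a: j for j, a in enumerate(attrs.columns)}
    if dag is not None:
        for term in attrs.columns:
            if term not in dag:
                continue
            for anc in nx.descendants(dag, term):  # edges run child -> parent
                if anc in cols:
                    mat[:, cols[anc]] |= mat[:, cols[term]]
    closed = pd.DataFrame(mat.astype(int), index=attrs.index, columns=attrs.columns)

    by_span: dict[frozenset, str] = {}
    for attr in closed.columns:
        span = frozenset(closed.index[closed[attr] == 1])
        if span not in by_span or str(attr) < str(by_span[span]):
            by_span[span] = attr
    keep = sorted(by_span.values(), key=lambda a: list(closed.columns).index(a))
    deduped = closed[keep]

    counts = deduped.sum(axis=0)
    kept = [a for a in deduped.columns if min_size <= counts[a] <= max_size]
    return deduped[kept]


def idf_weight(attrs: pd.DataFrame) -> pd.DataFrame:
    """Weight a binary incidence matrix by inverse document frequency.

    ``w_ij = a_ij * log(n / n_j)`` with the natural log, ``n`` the number of
    entities and ``n_j`` the coverage of attribute ``j``. An attribute
    present in every entity is weighted to zero; an attribute covering no
    entity is an error.
    """
    a = attrs.to_numpy(dtype=float)
    counts = a.sum(axis=0)
    if (counts == 0).any():
        bad = attrs.columns[np.flatnonzero(counts == 0)[0]]
        raise ValueError(f"attribute {bad!r} covers no entity; idf undefined")
    idf = np.log(len(attrs.index) / counts)
    return pd.DataFrame(a * idf, index=attrs.index, columns=attrs.columns)


def build_reference_network(wattrs: pd.DataFrame, weight_cutoff: float = 0.0) -> nx.Graph:
    """Cosine-similarity reference network over IDF-weighted attribute rows.

    Two entities are joined iff they share at least one attribute (nonzero
    incidence in a common column) and the cosine of their weighted vectors
    is at least ``weight_cutoff``; the cosine becomes the edge weight.
    Entities with an all-zero weight vector stay as singletons.
    """
    if not 0.0 <= weight_cutoff <= 1.0:
        raise ValueError("weight cutoff must be in [0, 1]")
    w = wattrs.to_numpy(dtype=float)
    ids = list(wattrs.index)
    norms = np.linalg.norm(w, axis=1)
    shared = (w > 0) @ (w > 0).T  # pairs sharing >=1 positively weighted attribute
    g = nx.Graph()
    g.add_nodes_from(ids)
    nz = norms > 0
    dots = w @ w.T
    n = len(ids)
    for i in range(n):
        if not nz[i]:
            continue
        for j in range(i + 1, n):
            if not nz[j] or not shared[i, j]:
                continue
            cos = dots[i, j] / (norms[i] * norms[j])
            if cos >= weight_cutoff and cos > 0:
                g.add_edge(ids[i], ids[j], weight=float(cos))
    return g


def score_partition_on_reference(
    ref: nx.Graph, part: dict[Hashable, int]
) -> ModularityScore:
    """Weighted modularity of the reference network under an imposed partition.

    The partition found on the co-expression network is applied verbatim to
    the reference network's nodes; entities in the partition but absent
    from the reference contribute nothing, and reference nodes missing from
    the partition are an error. A score of 1 means the modules perfectly
    agree with the reference's modular structure; shuffled modules score
    near 0.
    """
    restricted = {v: part[v] for v in ref.nodes if v in part}
    missing = [v for v in ref.nodes if v not in part]
    if missing:
        raise ValueError(f"partition does not cover reference node {missing[0]!r}")
    return modularity(ref, restricted)


def shuffle_partition_preserving_sizes(
    part: dict[Hashable, int], seed: int = 0
) -> dict[Hashable, int]:
    """Permute module memberships uniformly, keeping the module sizes.

    The multiset of labels is reassigned to nodes by a uniform random
    permutation: module sizes are exactly preserved while any association
    between nodes and modules is destroyed. This is the null used to show a
    reference score is meaningful.
    """
    rng = np.random.default_rng(seed)
    nodes = list(part.keys())
    labels = np.array([part[v] for v in nodes])
    shuffled = labels[rng.permutation(len(labels))]
    return relabel_partition({v: int(lab) for v, lab in zip(nodes, shuffled)})
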