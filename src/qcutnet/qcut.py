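"""Modularity and the Qcut module-detection algorithm.

The modularity of a partition is

    Q = sum_i (e_ii - a_i**2)

where ``e_ii`` is the fraction of edge weight fully inside module ``i`` and
``a_i`` is module ``i``'s share of edge endpoints (half its weighted-degree
sum over twice the total weight). Q lies in [-1, 1]; the single-module
partition scores exactly 0, and a partition no better than random placement
scores <= 0. Exact maximization is NP-hard, so Qcut is a heuristic in two
phases: recursive spectral 2/3/4-way splitting, accepting a split only when
the global Q strictly increases, followed by greedy refinement that applies
node moves, module merges and module re-splits until none improves Q. The
number of modules is determined by the optimization, not by the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Iterable

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.cluster import KMeans

__all__ = [
    "ModularityScore",
    "modularity",
    "qcut_partition",
    "refine_partition",
    "spectral_split",
]

#: Minimum Q gain for accepting a split/move/merge: strict increase up to
#: floating-point noise.
Q_TOLERANCE = 1e-10


@dataclass(frozen=True)
class ModularityScore:
    """Modularity value with its per-module decomposition.

    ``per_module[label] = (e_ii, a_i)``: the within-module edge-weight
    fraction and the module's endpoint share.
    """

    q: float
    per_module: dict[int, tuple[float, float]]


def _edge_weight(data: dict) -> float:
    return float(data.get("weight", 1.0))


def _total_weight(net: nx.Graph) -> float:
    return sum(_edge_weight(d) for _, _, d in net.edges(data=True))


def modularity(net: nx.Graph, part: dict[Hashable, int]) -> ModularityScore:
    """Evaluate Q for a total partition of ``net``'s nodes.

    Weighted graphs use edge weights in place of edge counts. An edgeless
    network has no defined Q and raises ``ValueError``.
    """
    missing = [v for v in net.nodes if v not in part]
    if missing:
        raise ValueError(f"partition does not cover node {missing[0]!r}")
    m = _total_weight(net)
    if m == 0:
        raise ValueError("modularity is undefined for a network with no edges")
    internal: dict[int, float] = {}
    degree_sum: dict[int, float] = {}
    for v in net.nodes:
        degree_sum.setdefault(part[v], 0.0)
        internal.setdefault(part[v], 0.0)
    for u, v, data in net.edges(data=True):
        w = _edge_weight(data)
        degree_sum[part[u]] += w
        degree_sum[part[v]] += w
        if part[u] == part[v]:
            internal[part[u]] += w
    per_module = {
        lab: (internal[lab] / m, degree_sum[lab] / (2.0 * m)) for lab in sorted(degree_sum)
    }
    q = sum(e - a * a for e, a in per_module.values())
    return ModularityScore(q=q, per_module=per_module)


# ---------------------------------------------------------------------------
# spectral splitting


def _spectral_embedding(adj: sp.csr_matrix, k: int, seed: int) -> np.ndarray:
    """Top-k eigenvectors of the normalized adjacency D^-1/2 A D^-1/2.

    Equivalent to the smallest-eigenvalue eigenvectors of the symmetric
    normalized Laplacian; rows are later normalized to the unit sphere
    before k-means (Ng-Jordan-Weiss).
    """
    n = adj.shape[0]
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    d_half = sp.diags(inv_sqrt)
    m_norm = d_half @ adj @ d_half
    if n <= 400 or k >= n - 1:
        vals, vecs = np.linalg.eigh(m_norm.toarray())
        return vecs[:, np.argsort(vals)[::-1][:k]]
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(n)
    try:
        vals, vecs = spla.eigsh(m_norm, k=k, which="LA", v0=v0)
    except spla.ArpackNoConvergence:
        vals, vecs = np.linalg.eigh(m_norm.toarray())
        return vecs[:, np.argsort(vals)[::-1][:k]]
    return vecs[:, np.argsort(vals)[::-1]]


def _split_gain(
    groups: np.ndarray,
    sub_adj: sp.csr_matrix,
    full_degrees: np.ndarray,
    m: float,
) -> float:
    """Q gain of dividing one module into the given groups.

    Only the split module's own terms change, so the gain is computed
    locally; ``full_degrees`` are weighted degrees in the whole network so
    that edges leaving the subset still count toward each group's a_i.
    """
    whole_internal = sub_adj.sum() / 2.0
    whole_deg = full_degrees.sum()
    before = whole_internal / m - (whole_deg / (2.0 * m)) ** 2
    after = 0.0
    for g in np.unique(groups):
        mask = groups == g
        internal = sub_adj[mask][:, mask].sum() / 2.0
        deg = full_degrees[mask].sum()
        after += internal / m - (deg / (2.0 * m)) ** 2
    return after - before


def spectral_split(
    net: nx.Graph,
    nodes: Iterable[Hashable] | None = None,
    max_way: int = 4,
    seed: int = 0,
) -> tuple[dict[Hashable, int] | None, float]:
    """Best spectral 2..``max_way``-way split of a node subset.

    Each candidate k-way split is scored by the change in the *global* Q
    when the subset, currently one module, is replaced by the k groups
    (edges leaving the subset keep counting toward a_i). Returns the
    highest-gain split as a label map 1..k over the subset and its Q gain,
    or ``(None, 0.0)`` when the subset has no internal edges or no split
    increases Q.
    """
    node_list = list(net.nodes if nodes is None else nodes)
    m = _total_weight(net)
    if m == 0:
        raise ValueError("cannot split a network with no edges")
    sub = net.subgraph(node_list)
    if sub.number_of_edges() == 0:
        return None, 0.0
    idx = {v: i for i, v in enumerate(node_list)}
    rows, cols, weights = [], [], []
    for u, v, data in sub.edges(data=True):
        w = _edge_weight(data)
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
        weights += [w, w]
    sub_adj = sp.csr_matrix((weights, (rows, cols)), shape=(len(node_list), len(node_list)))
    full_degrees = np.array(
        [sum(_edge_weight(d) for _, _, d in net.edges(v, data=True)) for v in node_list]
    )
    sub_deg = np.asarray(sub_adj.sum(axis=1)).ravel()
    connected = np.flatnonzero(sub_deg > 0)
    isolated = np.flatnonzero(sub_deg == 0)
    n_conn = len(connected)
    if n_conn < 2:
        return None, 0.0

    adj_c = sub_adj[connected][:, connected]
    max_k = min(max_way, n_conn)
    embedding = _spectral_embedding(adj_c, max_k, seed)
    norms = np.linalg.norm(embedding, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    embedding = embedding / norms

    best_gain = 0.0
    best_groups: np.ndarray | None = None
    for k in range(2, max_k + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31))
        labels_c = km.fit_predict(embedding[:, :k])
        groups = np.zeros(len(node_list), dtype=int)
        groups[connected] = labels_c
        if isolated.size:
            # no internal edges: place each on the lightest group to
            # minimize the a_i^2 penalty
            group_deg = {g: full_degrees[connected][labels_c == g].sum() for g in range(k)}
            order = np.argsort(-full_degrees[isolated])
            for i in order:
                g = min(group_deg, key=group_deg.get)
                groups[isolated[i]] = g
                group_deg[g] += full_degrees[isolated[i]]
        if len(np.unique(groups[connected])) < 2:
            continue
        gain = _split_gain(groups, sub_adj, full_degrees, m)
        if gain > best_gain + Q_TOLERANCE or (best_groups is None and gain > Q_TOLERANCE):
            best_gain = gain
            best_groups = groups
    if best_groups is None or best_gain <= Q_TOLERANCE:
        return None, 0.0
    relabel = {g: i + 1 for i, g in enumerate(np.unique(best_groups))}
    return {v: relabel[int(best_groups[idx[v]])] for v in node_list}, float(best_gain)


# ---------------------------------------------------------------------------
# greedy refinement


class _RefineState:
    """Incremental bookkeeping for Q during greedy refinement."""

    def __init__(self, net: nx.Graph, part: dict[Hashable, int]):
        self.nodes = list(net.nodes)
        self.adj: dict[Hashable, list[tuple[Hashable, float]]] = {v: [] for v in self.nodes}
        self.m = 0.0
        for u, v, data in net.edges(data=True):
            w = _edge_weight(data)
            self.adj[u].append((v, w))
            self.adj[v].append((u, w))
            self.m += w
        if self.m == 0:
            raise ValueError("refinement is undefined for a network with no edges")
        self.k = {v: sum(w for _, w in self.adj[v]) for v in self.nodes}
        self.module = {v: part[v] for v in self.nodes}
        self.deg_sum: dict[int, float] = {}
        self.internal: dict[int, float] = {}
        self.size: dict[int, int] = {}
        for v in self.nodes:
            lab = self.module[v]
            self.deg_sum[lab] = self.deg_sum.get(lab, 0.0) + self.k[v]
            self.internal.setdefault(lab, 0.0)
            self.size[lab] = self.size.get(lab, 0) + 1
        for u, v, data in net.edges(data=True):
            if self.module[u] == self.module[v]:
                self.internal[self.module[u]] += _edge_weight(data)
        self.next_label = max(self.deg_sum) + 1

    def q(self) -> float:
        m = self.m
        return sum(self.internal.values()) / m - sum(
            d * d for d in self.deg_sum.values()
        ) / (4.0 * m * m)

    def neighbor_module_weights(self, v: Hashable) -> dict[int, float]:
        out: dict[int, float] = {}
        for u, w in self.adj[v]:
            lab = self.module[u]
            out[lab] = out.get(lab, 0.0) + w
        return out

    def move_gain(self, v: Hashable, target: int, nbr_w: dict[int, float]) -> float:
        src = self.module[v]
        w_src = nbr_w.get(src, 0.0)
        w_tgt = nbr_w.get(target, 0.0)
        d_tgt = self.deg_sum.get(target, 0.0)
        kv = self.k[v]
        return (w_tgt - w_src) / self.m - kv * (d_tgt - self.deg_sum[src] + kv) / (
            2.0 * self.m * self.m
        )

    def apply_move(self, v: Hashable, target: int, nbr_w: dict[int, float]) -> None:
        src = self.module[v]
        kv = self.k[v]
        self.internal[src] -= nbr_w.get(src, 0.0)
        self.deg_sum[src] -= kv
        self.size[src] -= 1
        if self.size[src] == 0:
            self.internal.pop(src)
            self.deg_sum.pop(src)
            self.size.pop(src)
        self.module[v] = target
        self.internal[target] = self.internal.get(target, 0.0) + nbr_w.get(target, 0.0)
        self.deg_sum[target] = self.deg_sum.get(target, 0.0) + kv
        self.size[target] = self.size.get(target, 0) + 1

    def cross_weights(self) -> dict[tuple[int, int], float]:
        seen: set[tuple[Hashable, Hashable]] = set()
        cross: dict[tuple[int, int], float] = {}
        for u in self.nodes:
            for v, w in self.adj[u]:
                if (v, u) in seen:
                    continue
                seen.add((u, v))
                a, b = self.module[u], self.module[v]
                if a != b:
                    key = (min(a, b), max(a, b))
                    cross[key] = cross.get(key, 0.0) + w
        return cross

    def merge_gain(self, a: int, b: int, w_ab: float) -> float:
        return w_ab / self.m - self.deg_sum[a] * self.deg_sum[b] / (2.0 * self.m * self.m)

    def apply_merge(self, a: int, b: int, w_ab: float) -> None:
        for v in self.nodes:
            if self.module[v] == b:
                self.module[v] = a
        self.internal[a] += self.internal.pop(b) + w_ab
        self.deg_sum[a] += self.deg_sum.pop(b)
        self.size[a] += self.size.pop(b)

    def apply_split(self, label: int, sub_labels: dict[Hashable, int], net: nx.Graph) -> None:
        label_map = {1: label}
        for s in sorted(set(sub_labels.values())):
            if s != 1:
                label_map[s] = self.next_label
                self.next_label += 1
        for v, s in sub_labels.items():
            self.module[v] = label_map[s]
        # rebuild the affected modules' sums from scratch (cheap, local)
        for lab in label_map.values():
            self.internal[lab] = 0.0
            self.deg_sum[lab] = 0.0
            self.size[lab] = 0
        for v, s in sub_labels.items():
            self.deg_sum[label_map[s]] += self.k[v]
            self.size[label_map[s]] += 1
        counted: set[tuple[Hashable, Hashable]] = set()
        for v, s in sub_labels.items():
            for u, w in self.adj[v]:
                if u in sub_labels and sub_labels[u] == s and (u, v) not in counted:
                    counted.add((v, u))
                    self.internal[label_map[s]] += w


def refine_partition(
    net: nx.Graph,
    part: dict[Hashable, int],
    seed: int = 0,
    on_accept: Callable[[str, float, dict[Hashable, int]], None] | None = None,
) -> dict[Hashable, int]:
    """Greedily improve a partition by node moves, merges, and re-splits.

    Repeats three operation families — moving a node to another module (or
    detaching it into a new one), merging two modules, and spectrally
    re-splitting a module — applying any operation that increases Q, until a
    full cycle brings no improvement. The returned partition's Q is never
    below the input's. ``on_accept(op, q, partition)`` is invoked after each
    accepted operation, mainly for auditing the incremental Q updates.
    """
    state = _RefineState(net, part)
    rng = np.random.default_rng(seed)

    def notify(op: str) -> None:
        if on_accept is not None:
            on_accept(op, state.q(), dict(state.module))

    improved_cycle = True
    while improved_cycle:
        improved_cycle = False

        # node moves: full sweeps in fixed node order until stable
        moved = True
        while moved:
            moved = False
            for v in state.nodes:
                nbr_w = state.neighbor_module_weights(v)
                src = state.module[v]
                candidates = [lab for lab in nbr_w if lab != src]
                if state.size[src] > 1:
                    candidates.append(state.next_label)  # detach into a new module
                best_lab, best_gain = None, Q_TOLERANCE
                for lab in candidates:
                    gain = state.move_gain(v, lab, nbr_w)
                    if gain > best_gain:
                        best_lab, best_gain = lab, gain
                if best_lab is not None:
                    if best_lab == state.next_label:
                        state.next_label += 1
                    state.apply_move(v, best_lab, nbr_w)
                    moved = improved_cycle = True
                    notify("move")

        # merges: apply the best positive merge until none remains
        while True:
            cross = state.cross_weights()
            best_pair, best_gain = None, Q_TOLERANCE
            for (a, b), w_ab in cross.items():
                gain = state.merge_gain(a, b, w_ab)
                if gain > best_gain:
                    best_pair, best_gain = (a, b, w_ab), gain
            if best_pair is None:
                break
            state.apply_merge(*best_pair)
            improved_cycle = True
            notify("merge")

        # re-splits: try a spectral split of each current module
        for lab in sorted(set(state.module.values())):
            members = [v for v in state.nodes if state.module[v] == lab]
            if len(members) < 2:
                continue
            sub_labels, gain = spectral_split(
                net, members, seed=int(rng.integers(2**31))
            )
            if sub_labels is not None and gain > Q_TOLERANCE:
                state.apply_split(lab, sub_labels, net)
                improved_cycle = True
                notify("split")

    return _relabel(state.module)


def _relabel(part: dict[Hashable, int]) -> dict[Hashable, int]:
    remap: dict[int, int] = {}
    out: dict[Hashable, int] = {}
    for v, lab in part.items():
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[v] = remap[lab]
    return out


def qcut_partition(
    net: nx.Graph, seed: int = 0
) -> tuple[dict[Hashable, int], ModularityScore]:
    """Partition a network into modules by maximizing Q.

    Phase one splits recursively: starting from one module, the best
    spectral 2/3/4-way split is applied to each module whenever it strictly
    increases the global Q, depth-first. Phase two runs greedy
    merge/move/split refinement. Deterministic for a given seed. Returns the
    final partition (labels 1..k) and its modularity.

    Disconnected components are never merged — a merge across components
    adds no internal weight and only grows a_i, so refinement cannot
    accept it.
    """
    if net.number_of_edges() == 0:
        raise ValueError("cannot partition a network with no edges")
    rng = np.random.default_rng(seed)
    part: dict[Hashable, int] = {v: 1 for v in net.nodes}
    next_label = 2
    stack = [1]
    while stack:
        lab = stack.pop()
        members = [v for v in part if part[v] == lab]
        if len(members) < 2:
            continue
        sub_labels, gain = spectral_split(net, members, seed=int(rng.integers(2**31)))
        if sub_labels is None or gain <= Q_TOLERANCE:
            continue
        label_map: dict[int, int] = {}
        for s in sorted(set(sub_labels.values())):
            if s == 1:
                label_map[s] = lab
            else:
                label_map[s] = next_label
                next_label += 1
        for v, s in sub_labels.items():
            part[v] = label_map[s]
        stack.extend(label_map.values())
    part = refine_partition(net, part, seed=int(rng.integers(2**31)))
    return part, modularity(net, part)
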