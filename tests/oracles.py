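"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: brute-force
enumeration over all set partitions for maximal modularity, pair counting
for the adjusted Rand index, and explicit combinatorial tail sums for the
hypergeometric test.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx

from qcutnet.qcut import modularity


def set_partitions(items: list):
    """Yield every partition of ``items`` as a list of blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def blocks_to_partition(blocks) -> dict:
    return {v: i + 1 for i, block in enumerate(blocks) for v in block}


def brute_force_max_q(net: nx.Graph) -> float:
    """Exhaustive maximum of Q over every partition of the node set."""
    best = -2.0
    for blocks in set_partitions(list(net.nodes)):
        best = max(best, modularity(net, blocks_to_partition(blocks)).q)
    return best


def brute_force_q_range(net: nx.Graph) -> tuple[float, float]:
    """(min Q, max Q) over every partition of the node set."""
    lo, hi = 2.0, -2.0
    for blocks in set_partitions(list(net.nodes)):
        q = modularity(net, blocks_to_partition(blocks)).q
        lo, hi = min(lo, q), max(hi, q)
    return lo, hi


def ari_pair_counting(x: dict, y: dict) -> float:
    """Adjusted Rand index by direct pair counting over all object pairs.

    a = pairs together in both partitions, b = together only in x,
    c = together only in y, d = apart in both; the chance-corrected index
    is 2(ad - bc) / ((a+b)(b+d) + (a+c)(c+d)).
    """
    objs = sorted(x.keys(), key=str)
    a = b = c = d = 0
    for u, v in itertools.combinations(objs, 2):
        same_x = x[u] == x[v]
        same_y = y[u] == y[v]
        if same_x and same_y:
            a += 1
        elif same_x:
            b += 1
        elif same_y:
            c += 1
        else:
            d += 1
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        return 1.0
    return 2.0 * (a * d - b * c) / denom


def hypergeom_tail_enumeration(n_univ: int, n_attr: int, n_module: int, k: int) -> float:
    """P(X >= k) by explicit summation of the hypergeometric pmf."""
    total = comb(n_univ, n_module)
    tail = 0
    for i in range(k, min(n_attr, n_module) + 1):
        tail += comb(n_attr, i) * comb(n_univ - n_attr, n_module - i)
    return tail / total
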