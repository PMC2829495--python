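"""Partition accuracy (adjusted Rand index) and attribute enrichment statistics.

The adjusted Rand index is the Hubert-Arabie chance-corrected agreement
between two partitions of the same objects: 1 for identical partitions (up
to relabeling), about 0 for independent ones. Enrichment of an attribute in
a module is tested with the cumulative (upper-tail) hypergeometric
distribution and Bonferroni-corrected over all (module, attribute) tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Hashable

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentResult",
    "adjusted_rand_index",
    "contingency_table",
    "enrichment_summary",
    "hypergeometric_enrichment",
]


def contingency_table(x: dict[Hashable, int], y: dict[Hashable, int]) -> pd.DataFrame:
    """Overlap counts n_ij between modules of two partitions of one object set."""
    if set(x) != set(y):
        raise ValueError("partitions cover different object sets")
    x_labels = sorted(set(x.values()))
    y_labels = sorted(set(y.values()))
    table = np.zeros((len(x_labels), len(y_labels)), dtype=int)
    xi = {lab: i for i, lab in enumerate(x_labels)}
    yj = {lab: j for j, lab in enumerate(y_labels)}
    for obj in x:
        table[xi[x[obj]], yj[y[obj]]] += 1
    return pd.DataFrame(table, index=x_labels, columns=y_labels)


def adjusted_rand_index(x: dict[Hashable, int], y: dict[Hashable, int]) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    From the contingency table N = (n_ij) with row sums n_i., column sums
    n_.j and total n:

        ARI = (sum_ij C(n_ij,2) - E) / (M - E)
        E   = sum_i C(n_i.,2) * sum_j C(n_.j,2) / C(n,2)
        M   = (sum_i C(n_i.,2) + sum_j C(n_.j,2)) / 2

    Returns 1.0 when both partitions are the same single cluster (the index
    is degenerate there; total agreement is reported).
    """
    table = contingency_table(x, y).to_numpy()
    n = table.sum()
    sum_ij = comb(table, 2).sum()
    sum_i = comb(table.sum(axis=1), 2).sum()
    sum_j = comb(table.sum(axis=0), 2).sum()
    expected = sum_i * sum_j / comb(n, 2)
    max_index = 0.5 * (sum_i + sum_j)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass(frozen=True)
class EnrichmentResult:
    """One (module, attribute) hypergeometric enrichment test."""

    module_label: int | None
    attribute_id: str | None
    overlap: int
    module_size: int
    attribute_size: int
    universe_size: int
    fold_enrichment: float
    p_raw: float
    p_corrected: float


def hypergeometric_enrichment(
    module: Collection[Hashable],
    attribute: Collection[Hashable],
    universe: Collection[Hashable],
    n_tests: int = 1,
    module_label: int | None = None,
    attribute_id: str | None = None,
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of attribute over-representation.

    With a universe of N entities of which K carry the attribute, and a
    module of size n overlapping the attribute in k entities, the raw
    p-value is P(X >= k) for X ~ Hypergeom(N, K, n). Fold enrichment is
    (k/n) / (K/N). The corrected p is min(1, raw * n_tests) (Bonferroni).
    """
    module, attribute, universe = set(module), set(attribute), set(universe)
    if not module or not attribute:
        raise ValueError("module and attribute must be non-empty")
    if not module <= universe or not attribute <= universe:
        raise ValueError("module and attribute must be subsets of the universe")
    n_univ = len(universe)
    k = len(module & attribute)
    p_raw = float(hypergeom.sf(k - 1, n_univ, len(attribute), len(module)))
    p_raw = min(1.0, p_raw)
    fold = (k / len(module)) / (len(attribute) / n_univ)
    return EnrichmentResult(
        module_label=module_label,
        attribute_id=attribute_id,
        overlap=k,
        module_size=len(module),
        attribute_size=len(attribute),
        universe_size=n_univ,
        fold_enrichment=fold,
        p_raw=p_raw,
        p_corrected=min(1.0, p_raw * n_tests),
    )


def enrichment_summary(
    part: dict[Hashable, int],
    attrs: pd.DataFrame,
    alpha_grid: Collection[float] = (0.05,),
) -> tuple[pd.DataFrame, list[EnrichmentResult]]:
    """Enrichment of every attribute in every module, summarized per alpha.

    The universe is the partitioned entity set; attributes are tested only
    if at least one of their members lies in that universe, and the
    Bonferroni multiplier is the number of (module, attribute) tests
    actually performed. Returns a per-alpha table with (i) the number of
    tests significant at that corrected level and (ii) the fraction of
    modules with at least one significant attribute, plus the full list of
    test results.
    """
    universe = set(part.keys())
    modules: dict[int, set] = {}
    for ent, lab in part.items():
        modules.setdefault(lab, set()).add(ent)
    attr_sets = {
        str(a): set(attrs.index[attrs[a] == 1]) & universe for a in attrs.columns
    }
    attr_sets = {a: s for a, s in attr_sets.items() if s}
    n_tests = len(modules) * len(attr_sets)
    results: list[EnrichmentResult] = []
    for lab in sorted(modules):
        for attr, members in attr_sets.items():
            results.append(
                hypergeometric_enrichment(
                    modules[lab],
                    members,
                    universe,
                    n_tests=n_tests,
                    module_label=lab,
                    attribute_id=attr,
                )
            )
    rows = []
    for alpha in alpha_grid:
        hits = [r for r in results if r.p_corrected <= alpha]
        hit_modules = {r.module_label for r in hits}
        rows.append(
            {
                "alpha": alpha,
                "n_enriched_pairs": len(hits),
                "fraction_modules_enriched": len(hit_modules) / len(modules) if modules else 0.0,
            }
        )
    return pd.DataFrame(rows), results
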