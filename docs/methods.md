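# Methods

## Similarity and network construction

`compute_similarity` supports the Pearson correlation coefficient and the
negated Euclidean distance; both are oriented so that larger means more
similar, which lets every downstream consumer (ranking, thresholding) treat
them identically. Expression values are assumed to be on the log scale
already; no transformation is applied at load time. Zero-variance profiles
have no defined correlation; rather than failing on the flat genes real
matrices contain, their similarities are set to −∞ so they rank strictly
last, with a warning.

`rank_network` connects each node to its `d` most similar partners and
unions the per-node lists. Ties in similarity are broken by ascending node
index and exactly `d` partners are taken; the construction is therefore
deterministic, and invariant under any strictly monotone transformation of
the similarities (only ranks matter). An optional `floor` drops edges whose
raw similarity falls below a confidence cutoff after the rank step — used,
for example, when building sample–sample networks where correlations below
0.2 are considered noise — at the cost of the minimum-degree guarantee.

`value_network` uses a closed threshold (edge iff similarity ≥ t). The
closed convention makes `threshold_for_mean_degree` exact: a mean degree
target `t` on `n` nodes needs `⌈n·t/2⌉` edges, so the answer is that order
statistic of the off-diagonal similarities, and the returned threshold is
the largest one meeting the target.

## Modularity and Qcut

Modularity is `Q = Σᵢ (eᵢᵢ − aᵢ²)` with `eᵢᵢ` the within-module fraction of
total edge weight and `aᵢ` the module's endpoint share (half its weighted
degree sum over total weight). This is the standard Newman–Girvan
normalization, under which the single-module partition scores exactly 0 and
`Σ aᵢ = 1` on a connected edge set; the per-module `(eᵢᵢ, aᵢ)` decomposition
is exposed on the returned score object. Weighted graphs substitute edge
weights for counts; uniform weights reduce exactly to the unweighted case.

Qcut has two phases.

1. **Recursive spectral splitting.** For the current module, the induced
   subgraph's symmetric normalized adjacency `D^{-1/2} A D^{-1/2}` is
   eigendecomposed (dense below 400 nodes, Lanczos above), the top-k
   eigenvector rows are normalized to the unit sphere, and k-means with 10
   restarts clusters them, for k ∈ {2, 3, 4}. Each candidate split is scored
   by the change in *global* Q — edges leaving the subset still count toward
   each group's `aᵢ` — and the best is accepted only if it increases Q by
   more than 1e−10 (strict increase up to floating noise). Accepted splits
   are pushed back for further splitting, depth-first.
2. **Greedy refinement.** Three operation families are applied until a full
   cycle brings no improvement: single-node moves to any adjacent module or
   detachment into a new singleton module (full sweeps in fixed node order,
   best-improvement per node); merges of adjacent module pairs
   (best-improvement, recomputed after each merge); and per-module spectral
   re-splits. Moves and merges use O(1) incremental Q updates from
   per-module degree sums and internal weights; the update algebra is
   audited in the tests against from-scratch evaluation after every accepted
   operation. The move-first order was chosen because moves are the
   cheapest operation and fix most spectral misassignments before the
   coarser operations run.

Q strictly increases with every accepted operation, so the procedure
terminates without an iteration cap. Components of a disconnected network
are never merged (a cross-component merge adds no internal weight and only
grows `aᵢ`). On graphs small enough to enumerate every set partition, the
heuristic attains the exhaustive maximum of Q on well over 90 % of random
instances, and can never exceed it.

## Topology diagnostics and null models

The clustering coefficient `Cᵢ = 2nᵢ/(kᵢ(kᵢ−1))` is defined as 0 for
degree-1 nodes (the formula is 0/0 there) and the network value averages
over non-singleton nodes only; path length and diameter are computed by BFS
from every node over reachable pairs only (O(n·|E|)). The power-law
exponent is fitted by default with unbinned least squares on
(log₁₀ k, log₁₀ f(k)) over supported degrees — the simplest reproducible
choice — with the discrete Clauset-style MLE available as an option (the
MLE approximation is accurate only when the minimum degree is well above
1). The two null models are degree-preserving double-edge swaps (attempted
10·|E| times by default, rejecting any swap creating a self-loop or
duplicate edge, so graphs with no legal swap return unchanged) and
independent per-row permutation of the expression matrix before network
construction.

## Reference-network scoring

Attribute matrices are first closed over the ontology (a gene annotated to
a term inherits all ancestors), deduplicated (terms covering identical gene
sets keep only the lexicographically smallest id — a deterministic rule),
and size-filtered (default 5–500 genes, applied after closure and dedup).
IDF weights use the natural log; the cosine is invariant to the base, as
the tests verify numerically. Edges require both a shared attribute and a
cosine at or above the weight cutoff, and sub-cutoff edges are removed
while surviving edges keep their cosine weights (rather than being
binarized). Scoring imposes the co-expression partition on the reference
graph verbatim and evaluates weighted modularity there; entities absent
from the reference contribute nothing, since the metric is a property of
the reference graph's edges. The null is a size-preserving uniform shuffle
of module memberships, which scores ≈ 0 by the same chance-correction that
makes the single-module partition score 0.

## Evaluation statistics

The adjusted Rand index uses the Hubert–Arabie contingency-table form; the
tests cross-check it against independent pair counting and against
scikit-learn. Both marginals are the usual row/column sums of the
contingency table. The hypergeometric enrichment p-value is the upper tail
P(X ≥ k); the Bonferroni multiplier is the number of (module, attribute)
tests actually performed, where attributes are tested only if at least one
member lies in the partitioned universe (zero-overlap tests are
uninformative and would only inflate the multiplier).

## Synthetic data

`simulate_clustered_expression` emulates clustered microarray benchmarks:
each cluster draws a template profile i.i.d. standard normal per condition
— log-scale values, so raw intensities are log-normal — and each member
gene adds i.i.d. N(0, σ²) noise. Defaults are 600 genes, 15 equal clusters
of 40, 50 conditions; the noise grid {0, 0.2, 0.4, 0.8, 1.2} spans
trivially separable to barely clusterable data. The generator omits real
microarray artifacts (dye bias, missing values, heteroscedastic noise,
correlated conditions, unequal cluster sizes unless requested), so passing
tests demonstrate correct algorithmic behavior under the stated model, not
performance on any particular real dataset. `gaussian_cloud` provides the
1000-point geometric clouds used to measure at which `d` the
nearest-neighbor network becomes a single component, and
`planted_partition_graph` the standard known-groups random graph fixture.
All generators are pure functions of their seed.

## Problem sizes and numerical choices

The test and acceptance workloads use the generators at their default study
conditions: 600-gene/15-cluster expression data (20 replicates per noise
level), 1000-point clouds in dimensions {2, 3, 5, 20} (20 replicates each),
exhaustive partition enumeration on graphs of up to 6 nodes (for Q bounds)
and up to 8 nodes (for optimality comparisons, 100 graphs). Split
acceptance uses a 1e−10 tolerance; k-means uses 10 restarts per k; all
randomness flows from explicit integer seeds, with per-stage substreams in
the CLI so multi-stage pipelines are reproducible end to end.

## Known limitations

Exact modularity maximization is NP-hard; Qcut is a heuristic and offers no
optimality guarantee at scale. Modularity itself has a resolution limit:
very small, well-formed modules in very large networks can be absorbed.
The value-network threshold convention ("≥") and the exact-d tie rule are
deterministic choices among behaviorally equivalent alternatives; both are
documented where they matter. The reference-scoring machinery accepts
simplified two-column annotation and ontology tables, not OBO/GAF files.
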