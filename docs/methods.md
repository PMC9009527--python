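# Methods

This note records the models, conventions and numerical choices behind
`hubtrace`, and what the synthetic benchmarks do and do not demonstrate.

## Network model and conventions

The substrate is a simple undirected unweighted graph: protein symbols as
nodes, physical interactions as edges.  Curation removes self-loops first
and isolated nodes second (a node isolated *by* loop removal is also
dropped); curation is idempotent and the package refuses an empty result.
Any weight column in an input edge list is ignored with a warning —
every downstream formula uses the binary adjacency matrix.

Two conventions deliberately differ from common library defaults and are
guarded by regression tests:

* **Closeness** is `C_C(i) = n / Σ_j d_ij` with `n` the size of the
  component containing `i` — not the conventional `n − 1` numerator.  The
  two differ by the constant factor `n/(n−1)` and so never change
  rankings, but reported values follow this definition exactly.
* **Normalised betweenness** divides the raw pair-dependency sum (over
  unordered pairs) by `M = (n−1)(n−2)/2`, the number of unordered pairs
  excluding the focal node, bounding `C_B` in `[0, 1]`.

On a disconnected network, closeness and betweenness are computed within
each component using that component's `n`; eigenvector centrality is
reported on the largest component (zeros elsewhere) with a warning.
Eigenvector centrality uses power iteration on `A + I` (the shift
guarantees convergence on bipartite components) to a fixed tolerance of
1e-13, reports the Rayleigh quotient of `A` as `λ_max`, and L2-normalises
the Perron vector with non-negative sign.  Local clustering of degree-0/1
nodes is defined as 0.

## Power-law fits and topology classification

Spectrum fits are ordinary least squares of `log10 y` on `log10 x` over
per-degree means, the estimator that matches how such spectra are plotted
and compared; zero-valued `y` (e.g. clustering of degree-1 nodes) is
dropped with a logged count, and at least three distinct degrees are
required.  A Hill-type maximum-likelihood estimator
(`α = 1 + n / Σ ln(x_i / (x_min − ½))`) is available as an alternative for
heavy-tailed degree samples; it is accurate for `x_min ≥ 2` and is not the
default because the OLS spectrum fit is the comparable quantity.

Classification: "hierarchical scale-free" requires decaying power laws
(negative slope, R² ≥ 0.5, |slope| ≥ 0.05 by default; both thresholds
configurable) for `P(k)` **and** `C(k)`; `P(k)` alone gives "scale-free".
Assortativity is the sign of the `C_N(k)` slope, with |slope| below the
threshold read as neutral.  The fitted exponents are reported as-is; no
expected range is enforced.

## Community hierarchy

`detect_communities` maximises Newman–Girvan modularity.  Three regimes:

* **n ≤ 10**: exact maximisation by dynamic programming over the subset
  lattice (3^n submask visits).  Tiny communities deep in a decomposition
  are therefore never subject to heuristic artefacts, and the worked
  two-triangle and two-clique examples are provably optimal.
* **n > 10**: Louvain, run 8 times with visit orders derived from the
  seed, keeping the best-modularity partition (earliest restart wins
  ties).  Before any run the graph is rebuilt with sorted node and edge
  insertion order; without this, subgraph views iterate node sets in hash
  order and the partition would differ between interpreter sessions.
* A Girvan–Newman divisive backend (`method="girvan_newman"`) scans the
  dendrogram for the maximum-modularity cut, which may be the trivial
  single community.

`decompose` recurses breadth-first: a community qualifies for further
splitting when it contains at least one triangle (`G(3,3)`), has more
than three members, and re-partitioning its induced subgraph yields at
least two parts.  Exactly-three-node, three-edge communities are terminal
motifs.  If the *root* partition returns a single community, it is still
recorded as the (terminal) first level of organisation, so a fully
cohesive network reports one level with one community.  Resolution
defaults to 1.0 and the seed to 42; both are exposed because modularity
optimisation is order-dependent.

Key regulators use the strict reading: a hub is a key regulator iff its
chain of containing communities ends in a terminal motif at the tree's
maximum depth.  Hubs whose chains stop earlier are reported with their
deepest level, so partial "modular paths" remain inspectable.  Hub
selection by `top_n` includes all nodes tied at the cut-off degree (the
reported set may exceed `top_n`); `min_degree` is the threshold variant.
The default `top_n = 65` mirrors the published analysis scale.

## Deregulation filter

Replicate ratios are multiplicative, so testing and averaging happen on
the log2 scale: the per-protein fold change is the ratio of *geometric*
means of case and control replicate ratios, and the two-sample t-test runs
on log2 ratios.  Student's equal-variance form is the default — it is the
classical test for this design and is exactly calibrated in the package's
own type-I benchmark (empirical rate 0.0498 at nominal 0.05 with 4
replicates per side), whereas Welch's form (available via
`equal_var=False`) is measurably conservative at such small n (≈ 0.041).
No multiple-testing correction is applied by default because the filter
is a raw-p screen; Benjamini–Hochberg adjusted values can be reported
alongside (`adjust="bh"`) without changing selection.  Selection requires
`|log2 FC| ≥ log2(1.5) = 0.585` and `p ≤ 0.05` jointly by default;
`require_both=False` reproduces fold-change-only counts.  Proteins with
fewer than two replicates on either side get an undefined, flagged
p-value and are never selected by the joint filter.

## Synthetic data: what it emulates, and what it does not

**Deterministic hierarchical network.**  The five-node-module replication
construction: a 5-clique whose four peripheral nodes are replicated
four-fold at each iteration, with every copy's peripheral nodes wired to
the original central hub; `N = 5^iterations`.  This is the canonical
model whose clustering spectrum obeys `C(k) ~ k^−1`, and it anchors the
hierarchical-topology benchmark (fitted |slope| 1.109, R² 0.995 at 625
nodes).

**Planted hierarchy.**  A three-level nested block structure
(4 × 3 × 2 leaves of 6 nodes, 144 nodes total by default).  Each leaf is
two triangles joined by five bridge edges; sibling leaves are coupled by
a deterministic, evenly spread circulant pattern whose density derives
from `p_in_by_level[0] = 0.20`; shallower levels get randomly placed
edges with fixed counts (`p_in_by_level[1] = 0.06` within level-1 blocks,
`p_out = 0.005` between them).  These densities were chosen once, at
design time, so that each scale of the hierarchy is the modularity
optimum of its parent's induced subgraph — the regime in which recursive
modularity optimisation can recover nested structure at all.  Determinism
at the finest scale and fixed edge counts elsewhere are deliberate
variance-reduction choices: at 6–12-node scales, unconstrained random
placement makes community splits erratic for a sizeable fraction of
seeds.  Fifteen regulator nodes (one per distinct leaf, always a triangle
member) receive (2, 4, 12) extra edges to uniformly drawn nodes of their
level-2 block, level-1 block and the remaining network, making them the
strictly top-degree nodes while leaving every leaf's internal scaffold
untouched.

**Quant table.**  Two groups ("case", "control"), four replicates each;
log2 ratios are Gaussian with standard deviation 0.20 (log-normal ratios,
the usual iTRAQ behaviour at moderate loading differences).  Planted
proteins carry `|log2 FC| = log2(1.5) + Exponential(mean 0.8)` — effects
start exactly at the filter threshold and tail off toward the ~15-fold
changes seen for strong inflammatory markers — signed positive for the 49
upregulated and negative for the 16 downregulated of 65 planted among 434
proteins.  At these defaults the filter's measured sensitivity is ≈ 0.97
with zero false discoveries at seed 3.

**What passing these benchmarks shows — and does not.**  The planted
generators demonstrate that the implementation recovers structure *when
the generative assumptions hold*: block-modular organisation with
separated density scales, triangle-terminated leaves, hub regulators that
are genuinely top-degree, log-normal replicate noise, exchangeable
replicates.  Real interactomes violate several of these (degree
heterogeneity inside modules, overlapping complexes, study-bias edges;
ratio compression and peptide-level artefacts in iTRAQ data), so
recovery rates measured here are upper bounds on real-data behaviour, not
estimates of it.  Conversely the two data-free anchors — the 0.585
threshold identity and the `α ∼ 1` clustering law — hold regardless.

## Degenerate inputs and tie-breaks

Duplicate edge-list rows collapse; SIF rows may carry multiple targets;
a TSV header row is auto-detected when its tokens recur nowhere else (the
writer emits an explicit `source/target` header so round-trips are
unambiguous).  Communities are output sorted by smallest member; hub
ranking breaks degree ties by node label; modularity ties across Louvain
restarts keep the earliest restart.  Fitting refuses fewer than three
distinct positive abscissae.  `top_n` larger than the network returns all
nodes with a warning.  Identical zero-variance groups get p = 1 (p = 0
if their means differ).

## Limitations

* Modularity optimisation has a resolution limit; very small or very
  imbalanced real modules may merge regardless of seed.  The exact solver
  only guards sub-networks of ≤ 10 nodes.
* The strict key-regulator rule (terminal motif at maximum depth) is one
  of two defensible readings of "represented at all levels"; the report
  retains per-hub deepest levels so the lenient reading can be derived.
* Power-law OLS fits over per-degree means are descriptive, not
  inferential — standard errors assume independent homoscedastic log
  residuals, which degree spectra do not strictly satisfy.
* The pipeline consumes a network as a file; building one (database
  retrieval, identifier mapping, evidence filtering) is out of scope.
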