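# hubtrace

Key-regulator discovery in protein–protein interaction (PPI) networks, for
systems-biology analyses that combine network topology with quantitative
proteomics.  Given an interaction network and an iTRAQ-style protein ratio
table, the pipeline answers: *which hub proteins sit at the structural core
of the network at every scale of its modular organisation, and which of
them are also deregulated in disease?*

The package targets desk-scale analyses of curated interactomes (hundreds
of nodes, the scale of a tissue proteome's physical-interaction network)
and ships a synthetic-data module that generates networks and ratio tables
with planted ground truth, so every stage is testable end to end without
external databases.

## The method

1. **Curation and topology.** The network `G(N, E)` is simplified
   (self-loops, then isolated nodes removed).  Per-degree spectra are the
   degree distribution `P(k) = N_k / N`, the clustering spectrum
   `C(k)` (mean of `c_i = 2 m_i / (k_i (k_i − 1))` over nodes of degree
   `k`, where `m_i` counts edges among the neighbours of `i`), and the
   neighbourhood connectivity `C_N(k)` (mean neighbour degree).  Per-node
   centralities are closeness `C_C(i) = n / Σ_j d_ij` (note the
   component-size numerator, kept as-is for comparability — conventional
   closeness uses `n − 1`), normalised betweenness
   `C_B(v) = C_b(v) / M` with `M = (n−1)(n−2)/2`, and eigenvector
   centrality (principal eigenvector of the adjacency matrix, power
   iteration, L2-normalised).  Log–log least-squares fits of the spectra
   classify the network: decaying power laws for both `P(k)` and `C(k)`
   indicate hierarchical scale-free organisation (`C(k) ~ k^−α` with
   `α ∼ 1` in the canonical hierarchical model); the sign of the `C_N(k)`
   exponent reads out assortativity.

2. **Hierarchical decomposition.** Communities are found by modularity
   optimisation (Louvain; seeded and deterministic, with exact
   maximisation on sub-networks of ≤ 10 nodes and a Girvan–Newman backend
   as an alternative).  Every community that contains at least one
   triangle — the qualification motif `G(3,3)` — and has more than three
   members is recursively re-partitioned on its induced subgraph,
   producing levels of organisation that terminate at triangle motifs.

3. **Key-regulator tracing.** The top-degree hubs (default: top 65, ties
   included) are followed through their containing community at every
   level.  A hub whose chain ends in a terminal triangle at the tree's
   maximum depth is a *key regulator* — present in modules at every scale
   down to the motif that acts as the network's controlling unit.

4. **Deregulation filter and intersection.**  Replicate ratios are tested
   per protein on the log2 scale (Student's t); proteins with
   `|log2 FC| ≥ log2 1.5 = 0.585` **and** `p ≤ 0.05` are deregulated.
   Intersecting named candidate lists (key regulators, deregulated sets
   from different contrasts) yields the common candidate target with a
   Venn-style membership summary.

## Worked example

```python
import hubtrace as ht

# topology of the 625-node deterministic hierarchical network
rb = ht.make_deterministic_hierarchical(4).graph
spec = ht.degree_spectra(rb)
k = spec.per_degree["degree"].to_numpy(dtype=float)
fits = {lab: ht.fit_power_law(k, spec.per_degree[col].to_numpy())
        for lab, col in [("P(k)", "P"), ("C(k)", "C"), ("C_N(k)", "C_N")]}
print(ht.classify_topology(fits).label)

# planted network: decompose, trace hubs, filter, intersect
net = ht.make_planted_hierarchy(seed=7)
tree = ht.decompose(net.graph, seed=42)
report = ht.trace_hubs(tree, ht.select_hubs(net.graph, top_n=15))
quant = ht.make_quant_table(
    n_proteins=144, n_deregulated=20, n_up=15,
    protein_ids=sorted(net.graph.nodes()),
    force_deregulated=net.planted_regulators[:5], seed=11)
de = ht.select_deregulated(quant.table, ("case", "control"))
venn = ht.intersect_lists({"key_regulators": report.key_regulators,
                           "deregulated": de.proteins})
print(sorted(venn.common))
```

This prints:

```
hierarchical scale-free
['P0012', 'P0030', 'P0054', 'P0078', 'P0108']
```

The fitted exponents behind the first line are `P(k)`: slope −1.182
(R² 0.93) and `C(k)`: slope −1.109 (R² 0.995) — the clustering spectrum
decays with exponent magnitude ≈ 1, the hierarchical signature.  The
second line is the intersection of the 15 recovered key regulators with
the 20 deregulated proteins: exactly the five proteins that the generators
planted as both, i.e. the pipeline's "common candidate target" nomination.

The same analysis runs from the shell:

```sh
hubtrace generate --model planted --seed 7 -o net.tsv
hubtrace decompose -i net.tsv --seed 42
hubtrace regulators -i net.tsv --top-n 15
hubtrace run -c pipeline.cfg        # full pipeline from a key=value config
```

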