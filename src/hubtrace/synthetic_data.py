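"""Synthetic networks and quantitation tables with planted ground truth.

Every pipeline stage is testable without external data:

* :func:`make_deterministic_hierarchical` builds the five-node-module
  replication network (Ravasz–Barabási construction), the canonical testbed
  whose clustering spectrum follows ``C(k) ~ k^-1``.
* :func:`make_planted_hierarchy` builds a nested stochastic-block network
  with triangle-rich leaf blocks and designated cross-level regulator nodes,
  so multi-level community recovery and key-regulator tracing can be scored
  against known truth.
* :func:`make_control` builds preferential-attachment and Erdős–Rényi
  control networks (scale-free degree law without hierarchical clustering;
  Poisson degree law).
* :func:`make_quant_table` builds an iTRAQ-like replicate ratio table with
  a planted deregulated subset at or above a minimum fold change.

All stochastic generators are bit-reproducible for a given seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .quant_filter import QuantTable

__all__ = [
    "GeneratedNetwork",
    "GeneratedQuantTable",
    "make_deterministic_hierarchical",
    "make_planted_hierarchy",
    "make_control",
    "make_quant_table",
]


@dataclass
class GeneratedNetwork:
    """A generated network plus its planted ground truth."""

    graph: nx.Graph
    generator: str
    params: dict
    seed: int | None = None
    # planted level -> {node -> block label}; empty when nothing is planted
    planted_partitions: dict[int, dict] = field(default_factory=dict)
    planted_regulators: list = field(default_factory=list)

    def __post_init__(self):
        for node in self.planted_regulators:
            assert node in self.graph, f"planted regulator {node!r} missing"
        for level, part in self.planted_partitions.items():
            assert set(part) == set(self.graph.nodes()), \
                f"planted partition at level {level} is not a full partition"


@dataclass
class GeneratedQuantTable:
    """A generated quant table plus its planted deregulation truth."""

    table: QuantTable
    truth: pd.DataFrame   # protein_id, deregulated, true_log2_fc, direction
    params: dict
    seed: int

    @property
    def planted(self) -> list:
        return sorted(self.truth.loc[self.truth["deregulated"], "protein_id"])


# ---------------------------------------------------------------------------
# deterministic hierarchical (five-node replication) network
# ---------------------------------------------------------------------------

def make_deterministic_hierarchical(iterations: int = 4) -> GeneratedNetwork:
    """Five-node-module replication network with ``N = 5^iterations`` nodes.

    Construction: start from a 5-clique whose node 0 is the central hub; at
    each subsequent iteration make four copies of the current graph and
    connect the peripheral nodes of every copy to the original central hub.
    The peripheral set of the result is the union of the copies' peripheral
    sets, so hubs acquire degree across all scales and the clustering
    spectrum decays as ``C(k) ~ k^-1``.

    ``iterations=1`` is the base 5-clique.  Fully deterministic.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if iterations > 5:
        raise ValueError("iterations > 5 exceeds desk scale (5^6 nodes)")

    G: nx.Graph = nx.complete_graph(5)
    center = 0
    peripheral = [1, 2, 3, 4]

    for _ in range(iterations - 1):
        n = G.number_of_nodes()
        new_G = G.copy()
        new_peripheral = []
        for i in range(1, 5):
            offset = i * n
            new_G.add_edges_from((u + offset, v + offset) for u, v in G.edges())
            new_peripheral.extend(p + offset for p in peripheral)
        new_G.add_edges_from((p, center) for p in new_peripheral)
        G = new_G
        peripheral = new_peripheral

    return GeneratedNetwork(
        graph=G,
        generator="deterministic_hierarchical",
        params={"iterations": iterations, "center": center},
    )


# ---------------------------------------------------------------------------
# planted nested hierarchy with cross-level regulators
# ---------------------------------------------------------------------------

def _leaf_scaffold(members: list, n_bridges: int = 1) -> list[tuple]:
    """Triangle scaffold inside one leaf block.

    Members are grouped into consecutive triangles (a final remainder of 1
    or 2 nodes is absorbed into the last group as a clique, which still
    contains a triangle); consecutive groups are joined by ``n_bridges``
    bridge edges each, assigned round-robin over the cross pairs.  A 6-node
    leaf with one bridge is exactly two triangles joined by one edge; more
    bridges tighten the leaf without merging its triangles.
    """
    groups = []
    i = 0
    while len(members) - i >= 3:
        groups.append(members[i:i + 3])
        i += 3
    if i < len(members):
        groups[-1].extend(members[i:])
    edges = []
    for g in groups:
        edges.extend(itertools.combinations(g, 2))
    for a, b in zip(groups, groups[1:]):
        cross = [(a[i % len(a)], b[(i + i // len(b)) % len(b)])
                 for i in range(len(a) * len(b))]
        seen = dict.fromkeys(cross)  # round-robin order, de-duplicated
        edges.extend(list(seen)[:n_bridges])
    return edges


def _circulant_pairs(size: int, count: int) -> list[tuple[int, int]]:
    """``count`` index pairs (i, j) spread evenly between two size-``size`` sets.

    Full circulant offsets are taken first (every i paired with i+offset);
    a partial final offset is distributed with an even stride so no index
    is overloaded.
    """
    count = min(count, size * size)
    pairs: list[tuple[int, int]] = []
    offset = 0
    while len(pairs) + size <= count:
        pairs.extend((i, (i + offset) % size) for i in range(size))
        offset += 1
    r = count - len(pairs)
    if r:
        idx = [int(round(j * size / r)) % size for j in range(r)]
        pairs.extend((i, (i + offset) % size) for i in sorted(set(idx))[:r])
    return pairs


def make_planted_hierarchy(
    levels: int = 3,
    branches_per_level: tuple = (4, 3, 2),
    leaf_size: int = 6,
    p_in_by_level: tuple | None = None,
    p_out: float = 0.005,
    n_regulators: int = 15,
    regulator_boost: tuple = (2, 4, 12),
    leaf_bridges: int = 5,
    seed: int = 7,
) -> GeneratedNetwork:
    """Nested stochastic-block network with planted multi-level communities.

    The block tree has ``branches_per_level[0]`` level-1 blocks, each split
    into ``branches_per_level[1]`` level-2 blocks, and so on down to leaf
    blocks of ``leaf_size`` nodes.  Leaves carry a deterministic triangle
    scaffold (two triangles joined by one edge for ``leaf_size=6``), so the
    finest level decomposes into G(3,3) motifs.  Between leaves, a pair of
    nodes is joined with probability ``p_in_by_level[d]`` where ``d`` indexes
    the deepest block level the pair shares, ordered deepest-first; the
    entries must be strictly decreasing towards ``p_out`` (shallower shared
    ancestry = sparser), which makes the hierarchy detectable coarse-to-fine
    by modularity optimisation.  Defaults for 3 levels: ``(0.20, 0.06)``.

    ``n_regulators`` designated nodes — one triangle member per distinct
    leaf — receive ``regulator_boost`` extra edges to uniformly drawn nodes
    of (their level-2 block, their level-1 block, the rest of the network),
    making them the strictly top-degree nodes while every one of them still
    terminates in a leaf triangle.

    Ground truth (level-wise partitions and the regulator list) is recorded
    on the returned :class:`GeneratedNetwork`.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if len(branches_per_level) != levels:
        raise ValueError(
            f"branches_per_level must have {levels} entries, got "
            f"{len(branches_per_level)}"
        )
    if leaf_size < 3:
        raise ValueError("leaf_size must be >= 3 (a leaf must hold a triangle)")
    if p_in_by_level is None:
        defaults = (0.20, 0.06, 0.03, 0.015, 0.008)
        p_in_by_level = defaults[: levels - 1]
    if len(p_in_by_level) != max(levels - 1, 0):
        raise ValueError(
            f"p_in_by_level needs {levels - 1} entries (shared levels "
            f"{levels - 1}..1, deepest first), got {len(p_in_by_level)}"
        )
    bad = [p for p in p_in_by_level if not (0 < p <= 1) or p <= p_out]
    if bad:
        raise ValueError(f"p_in values must lie in (0,1] and exceed p_out: {bad}")
    if any(nxt >= prev for prev, nxt in zip(p_in_by_level, p_in_by_level[1:])):
        # deepest-first ordering must strictly decrease
        raise ValueError(
            f"p_in_by_level must strictly decrease deepest-first: {p_in_by_level}"
        )

    rng = np.random.default_rng(seed)
    n_leaves = int(np.prod(branches_per_level))
    if n_regulators > n_leaves:
        raise ValueError(
            f"n_regulators={n_regulators} exceeds the number of leaves "
            f"({n_leaves}); one regulator is planted per leaf"
        )
    n_nodes = n_leaves * leaf_size
    nodes = [f"P{i:04d}" for i in range(n_nodes)]

    # block path of each leaf: tuple of branch indices, one per level
    leaf_paths = list(itertools.product(*(range(b) for b in branches_per_level)))
    leaf_members = {
        path: [nodes[i * leaf_size + j] for j in range(leaf_size)]
        for i, path in enumerate(leaf_paths)
    }
    path_of: dict[str, tuple] = {}
    for path, members in leaf_members.items():
        for m in members:
            path_of[m] = path

    planted_partitions = {
        lv: {n: path_of[n][:lv] for n in nodes} for lv in range(1, levels + 1)
    }

    G: nx.Graph = nx.Graph()
    G.add_nodes_from(nodes)
    for members in leaf_members.values():
        G.add_edges_from(_leaf_scaffold(list(members), n_bridges=leaf_bridges))

    # cross-leaf edges.  Sibling leaves (deepest shared block) are coupled by
    # a deterministic, evenly spread circulant pattern of round(p * pairs)
    # edges — at this finest scale random placement would make community
    # splits erratic.  Shallower shared ancestry gets randomly placed edges
    # with the *count* fixed at round(p * pairs), so block densities do not
    # fluctuate between seeds.
    for i, j in itertools.combinations(range(n_leaves), 2):
        pa, pb = leaf_paths[i], leaf_paths[j]
        shared = 0
        while shared < levels and pa[shared] == pb[shared]:
            shared += 1
        p = p_out if shared == 0 else p_in_by_level[levels - 1 - shared]
        n_pairs = leaf_size * leaf_size
        count = int(round(p * n_pairs))
        a = leaf_members[pa]
        b = leaf_members[pb]
        if shared == levels - 1:  # sibling leaves: deterministic circulant
            G.add_edges_from(
                (a[ii], b[jj]) for ii, jj in _circulant_pairs(leaf_size, count)
            )
            continue
        if count == 0 and rng.random() < p * n_pairs:
            count = 1  # keep sparse inter-block expectation unbiased
        if count == 0:
            continue
        # randomly rotated round-robin assignment: seeded, but each node's
        # external load differs by at most one edge, so no node is torn out
        # of its leaf by a chance concentration of cross edges
        perm_a = rng.permutation(leaf_size)
        perm_b = rng.permutation(leaf_size)
        G.add_edges_from(
            (a[perm_a[i]], b[perm_b[j]])
            for i, j in _circulant_pairs(leaf_size, min(count, n_pairs))
        )

    # plant regulators: one per distinct leaf, always a triangle member
    reg_leaves = [leaf_paths[i] for i in
                  rng.choice(n_leaves, size=n_regulators, replace=False)]
    regulators = [leaf_members[path][0] for path in reg_leaves]
    for reg in regulators:
        path = path_of[reg]
        same_l2 = [n for n in nodes
                   if path_of[n][:levels - 1] == path[:levels - 1]
                   and path_of[n] != path]
        same_l1 = [n for n in nodes
                   if path_of[n][:1] == path[:1]
                   and path_of[n][:levels - 1] != path[:levels - 1]]
        elsewhere = [n for n in nodes if path_of[n][:1] != path[:1]]
        for pool, count in zip((same_l2, same_l1, elsewhere), regulator_boost):
            pool = [n for n in pool if n != reg]
            if not pool:
                continue
            take = min(count, len(pool))
            targets = rng.choice(np.array(pool), size=take, replace=False)
            G.add_edges_from((reg, t) for t in targets)

    return GeneratedNetwork(
        graph=G,
        generator="planted_hierarchy",
        params={
            "levels": levels,
            "branches_per_level": tuple(branches_per_level),
            "leaf_size": leaf_size,
            "p_in_by_level": tuple(p_in_by_level),
            "p_out": p_out,
            "n_regulators": n_regulators,
            "regulator_boost": tuple(regulator_boost),
            "leaf_bridges": leaf_bridges,
        },
        seed=seed,
        planted_partitions=planted_partitions,
        planted_regulators=regulators,
    )


# ---------------------------------------------------------------------------
# control models
# ---------------------------------------------------------------------------

def make_control(model: str, n: int, param, seed: int = 0) -> GeneratedNetwork:
    """Scale-free or random control network without planted structure.

    ``model="preferential_attachment"``: Barabási–Albert growth with
    ``param`` edges per new node (power-law P(k), flat C(k)).
    ``model="random"``: Erdős–Rényi G(n, p) with ``param = p`` (Poisson-like
    degree distribution).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if model == "preferential_attachment":
        m = int(param)
        if not 1 <= m < n:
            raise ValueError(f"need 1 <= m < n, got m={param}")
        G = nx.barabasi_albert_graph(n, m, seed=seed)
    elif model == "random":
        p = float(param)
        if not 0 <= p <= 1:
            raise ValueError(f"need 0 <= p <= 1, got p={param}")
        G = nx.gnp_random_graph(n, p, seed=seed)
    else:
        raise ValueError(f"unknown control model: {model!r}")
    return GeneratedNetwork(
        graph=G,
        generator=model,
        params={"n": n, "param": param},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# quantitation tables
# ---------------------------------------------------------------------------

def make_quant_table(
    n_proteins: int = 434,
    n_deregulated: int = 65,
    n_up: int = 49,
    min_fold: float = 1.5,
    replicate_sd: float = 0.20,
    n_replicates: int = 4,
    seed: int = 3,
    effect_scale: float = 0.8,
    protein_ids: list | None = None,
    force_deregulated: list | None = None,
) -> GeneratedQuantTable:
    """iTRAQ-like replicate ratio table with a planted deregulated subset.

    Two groups are emitted, ``case`` and ``control``, each with
    ``n_replicates`` replicate ratios to a common reference.  Replicate
    noise is log-normal: log2 ratios are Gaussian with standard deviation
    ``replicate_sd``.  Planted proteins have a true |log2 fold change| of
    ``log2(min_fold)`` plus an exponential excess of mean ``effect_scale``
    (positive for the ``n_up`` upregulated, negative for the rest);
    everything else has expectation 1.0 on the ratio scale.

    ``protein_ids`` substitutes explicit identifiers (e.g. network node
    names); ``force_deregulated`` lists identifiers that must be in the
    planted subset.  Defaults mirror a 434-protein table with 65 planted
    (49 up, 16 down) at >= 1.5-fold.
    """
    if n_deregulated > n_proteins:
        raise ValueError("n_deregulated cannot exceed n_proteins")
    if n_up > n_deregulated:
        raise ValueError("n_up cannot exceed n_deregulated")
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be >= 0")
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")

    if protein_ids is None:
        protein_ids = [f"PROT{i:04d}" for i in range(n_proteins)]
    else:
        protein_ids = list(protein_ids)
        if len(protein_ids) != n_proteins:
            raise ValueError(
                f"got {len(protein_ids)} protein_ids for n_proteins={n_proteins}"
            )

    rng = np.random.default_rng(seed)
    forced = list(force_deregulated or [])
    unknown = [p for p in forced if p not in protein_ids]
    if unknown:
        raise ValueError(f"force_deregulated ids not in table: {unknown}")
    if len(forced) > n_deregulated:
        raise ValueError("more forced ids than n_deregulated")
    rest = [p for p in protein_ids if p not in forced]
    extra = rng.choice(np.array(rest), size=n_deregulated - len(forced),
                       replace=False) if n_deregulated > len(forced) else []
    dereg = forced + [str(x) for x in extra]

    lfc_min = np.log2(min_fold)
    true_lfc = {p: 0.0 for p in protein_ids}
    for idx, p in enumerate(dereg):
        magnitude = lfc_min + rng.exponential(effect_scale)
        true_lfc[p] = magnitude if idx < n_up else -magnitude

    rows = []
    for p in protein_ids:
        for group, shift in (("case", true_lfc[p]), ("control", 0.0)):
            noise = rng.normal(0.0, replicate_sd, size=n_replicates)
            for r in range(n_replicates):
                rows.append(
                    (p, group, r + 1, float(2.0 ** (shift + noise[r])))
                )
    data = pd.DataFrame(rows, columns=["protein_id", "group", "replicate",
                                       "ratio"])

    dereg_set = set(dereg)
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "deregulated": [p in dereg_set for p in protein_ids],
            "true_log2_fc": [true_lfc[p] for p in protein_ids],
            "direction": ["up" if true_lfc[p] > 0 else
                          ("down" if true_lfc[p] < 0 else "")
                          for p in protein_ids],
        }
    )
    return GeneratedQuantTable(
        table=QuantTable(data),
        truth=truth,
        params={
            "n_proteins": n_proteins,
            "n_deregulated": n_deregulated,
            "n_up": n_up,
            "min_fold": min_fold,
            "replicate_sd": replicate_sd,
            "n_replicates": n_replicates,
            "effect_scale": effect_scale,
        },
        seed=seed,
    )
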