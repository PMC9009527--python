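"""Hub selection and key-regulator tracing through the community hierarchy.

Hubs are the highest-degree nodes of the curated network.  Each hub is
followed through its containing community at every level of the
decomposition tree; a hub whose chain ends in a terminal triangle motif at
the tree's maximum depth is a *key regulator* — it is represented in modules
at every hierarchical level, down to the motif that forms the controlling
unit of the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .hierarchy import CommunityTree
from . import topology as _topology

__all__ = [
    "HubSet",
    "HubTrace",
    "KeyRegulatorReport",
    "select_hubs",
    "trace_hubs",
    "per_level_exponents",
]


@dataclass
class HubSet:
    """Top-degree nodes with the selection rule that produced them."""

    hubs: list[tuple]         # (node, degree), degree-descending
    rule: str                 # "top_n" | "min_degree"
    value: int

    @property
    def nodes(self) -> list:
        return [n for n, _ in self.hubs]

    def __len__(self) -> int:
        return len(self.hubs)


def select_hubs(net: nx.Graph, top_n: int | None = None,
                min_degree: int | None = None) -> HubSet:
    """Select hub nodes by degree rank or by a degree threshold.

    Exactly one of ``top_n`` and ``min_degree`` must be given; with neither,
    the default is ``top_n=65``.  Under ``top_n``, every node tied at the
    cut-off degree is included, so the set may exceed ``top_n``.  Ties are
    ordered by node label for reproducibility.
    """
    if top_n is not None and min_degree is not None:
        raise ValueError("give either top_n or min_degree, not both")
    if top_n is None and min_degree is None:
        top_n = 65

    ranked = sorted(net.degree(), key=lambda kv: (-kv[1], str(kv[0])))
    if top_n is not None:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        if top_n >= len(ranked):
            if top_n > len(ranked):
                import logging
                logging.getLogger("hubtrace").warning(
                    "top_n=%d exceeds network size %d; returning all nodes",
                    top_n, len(ranked),
                )
            chosen = ranked
        else:
            cutoff = ranked[top_n - 1][1]
            chosen = [kv for kv in ranked if kv[1] >= cutoff]
        return HubSet(hubs=chosen, rule="top_n", value=top_n)

    chosen = [kv for kv in ranked if kv[1] >= min_degree]
    return HubSet(hubs=chosen, rule="min_degree", value=min_degree)


@dataclass
class HubTrace:
    """Path of one hub through the community tree."""

    node: object
    degree: int
    chain: list[int]          # community ids, level 1 .. deepest
    deepest_level: int
    reached_motif: bool
    is_key_regulator: bool
    motif_partners: list = field(default_factory=list)


@dataclass
class KeyRegulatorReport:
    """Traces for every hub plus the derived key-regulator subset."""

    traces: list[HubTrace]
    max_depth: int

    @property
    def key_regulators(self) -> list:
        return sorted((t.node for t in self.traces if t.is_key_regulator), key=str)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hub": [t.node for t in self.traces],
                "degree": [t.degree for t in self.traces],
                "deepest_level": [t.deepest_level for t in self.traces],
                "reached_motif": [t.reached_motif for t in self.traces],
                "key_regulator": [t.is_key_regulator for t in self.traces],
                "motif_partners": [",".join(map(str, t.motif_partners))
                                   for t in self.traces],
            }
        )


def trace_hubs(tree: CommunityTree, hubs: HubSet) -> KeyRegulatorReport:
    """Trace each hub through every level of the community tree.

    A hub is a key regulator iff its chain of containing communities ends in
    a terminal motif community at the tree's maximum depth — the strictest
    reading of "represented in modules at all hierarchical levels".  For a
    key regulator, the motif partners are the other two members of its
    terminal triangle.
    """
    network_nodes = tree.nodes[tree.root].members
    max_depth = tree.max_depth
    traces = []
    for node, degree in hubs.hubs:
        if node not in network_nodes:
            raise KeyError(f"hub {node!r} is not a node of the decomposed network")
        chain = []
        cur = tree.nodes[tree.root]
        while cur.children:
            for cid in cur.children:
                if node in tree.nodes[cid].members:
                    cur = tree.nodes[cid]
                    break
            chain.append(cur.id)
        reached_motif = cur.is_motif
        is_kr = reached_motif and cur.level == max_depth
        partners = sorted((m for m in cur.members if m != node), key=str) \
            if reached_motif else []
        traces.append(
            HubTrace(
                node=node,
                degree=degree,
                chain=chain,
                deepest_level=cur.level,
                reached_motif=reached_motif,
                is_key_regulator=is_kr,
                motif_partners=partners,
            )
        )
    return KeyRegulatorReport(traces=traces, max_depth=max_depth)


def per_level_exponents(net: nx.Graph, tree: CommunityTree) -> pd.DataFrame:
    """Spectrum and centrality–degree exponents per first-level community.

    For each level-1 community's induced subgraph, fits power laws for
    P(k), C(k) and C_N(k) and for the degree dependence of betweenness,
    closeness and eigenvector centrality (per-degree means).  Communities
    with fewer than 3 distinct degrees are flagged and skipped.
    """
    if tree.max_depth < 1:
        raise ValueError("tree has no first-level communities")
    rows = []
    for com in tree.at_level(1):
        sub = net.subgraph(com.members)
        row: dict = {"community": com.id, "size": len(com.members)}
        degrees = {d for _, d in sub.degree()}
        if len(degrees) < 3:
            row["skipped"] = True
            rows.append(row)
            continue
        row["skipped"] = False
        spec = _topology.degree_spectra(sub)
        pdg = spec.per_degree
        k = pdg["degree"].to_numpy(dtype=float)
        for label, ys in (("P(k)", pdg["P"]), ("C(k)", pdg["C"]),
                          ("C_N(k)", pdg["C_N"])):
            try:
                fit = _topology.fit_power_law(k, ys.to_numpy())
                row[f"{label}_slope"] = fit.slope
                row[f"{label}_r2"] = fit.r_squared
            except ValueError:
                row[f"{label}_slope"] = float("nan")
                row[f"{label}_r2"] = float("nan")
        cent = _topology.centrality_table(sub).table
        by_deg = cent.groupby("degree")[["betweenness", "closeness",
                                         "eigenvector"]].mean()
        kk = by_deg.index.to_numpy(dtype=float)
        for col, label in (("betweenness", "C_B(k)"), ("closeness", "C_C(k)"),
                           ("eigenvector", "C_E(k)")):
            try:
                fit = _topology.fit_power_law(kk, by_deg[col].to_numpy())
                row[f"{label}_slope"] = fit.slope
                row[f"{label}_r2"] = fit.r_squared
            except ValueError:
                row[f"{label}_slope"] = float("nan")
                row[f"{label}_r2"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
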