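"""Reading, curation and writing of protein–protein interaction networks.

Networks are plain :class:`networkx.Graph` objects whose nodes are protein or
gene symbols (case-sensitive strings) and whose edges are unweighted physical
interactions.  Input formats are two-column TSV edge lists and Cytoscape SIF;
output formats are TSV and GraphML.  Curation removes self-loops and then
isolated nodes, matching the usual clean-up applied to interactome exports
before topological analysis.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import networkx as nx

logger = logging.getLogger("hubtrace")

PathLike = Union[str, Path]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


def read_edge_list(path: PathLike, format: str = "tsv") -> nx.Graph:
    """Read an undirected network from a TSV edge list or a SIF file.

    TSV: the first two tab-separated columns are the edge endpoints; lines
    starting with ``#`` are comments; a header row is auto-detected (its
    tokens must not reappear as endpoints elsewhere in the file).  Any extra
    columns (e.g. weights) are ignored with a warning.

    SIF: ``source<TAB>interaction_type<TAB>target[<TAB>target2 ...]``; the
    interaction type is discarded.

    Duplicate rows collapse to a single edge.  Self-loops are retained until
    :func:`curate` is called.

    Parameters
    ----------
    path
        File to read.
    format
        ``"tsv"`` or ``"sif"``.

    Returns
    -------
    networkx.Graph
        The uncurated network.
    """
    path = Path(path)
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {format!r}")

    rows: list[tuple[int, list[str]]] = []  # (lineno, fields)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if format == "tsv" and len(fields) == 1:
                # tolerate space-separated two-column files
                fields = line.split()
            rows.append((lineno, fields))

    if not rows:
        raise EdgeListParseError(f"{path}: no data rows found")

    G: nx.Graph = nx.Graph()
    extra_cols_warned = False

    if format == "tsv":
        data = []
        for lineno, fields in rows:
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}"
                )
            if len(fields) > 2 and not extra_cols_warned:
                logger.warning(
                    "%s: ignoring extra columns (edges are unweighted)", path
                )
                extra_cols_warned = True
            data.append((lineno, fields[0].strip(), fields[1].strip()))
        # header auto-detection: drop the first row iff its tokens never
        # recur as endpoints in the remaining rows
        if len(data) > 1:
            _, h1, h2 = data[0]
            rest_tokens = {t for _, a, b in data[1:] for t in (a, b)}
            if h1 not in rest_tokens and h2 not in rest_tokens:
                logger.info("%s: first row treated as header (%r, %r)", path, h1, h2)
                data = data[1:]
        for lineno, a, b in data:
            if not a or not b:
                raise EdgeListParseError(f"{path}:{lineno}: empty endpoint name")
            G.add_edge(a, b)
    else:  # sif
        for lineno, fields in rows:
            if len(fields) == 1:
                # SIF permits isolated nodes as single-token rows
                G.add_node(fields[0].strip())
                continue
            if len(fields) < 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: SIF row needs source, type, >=1 target"
                )
            src = fields[0].strip()
            for tgt in fields[2:]:
                G.add_edge(src, tgt.strip())

    return G


def curate(net: nx.Graph) -> nx.Graph:
    """Remove self-loops, then isolated nodes; return a curated copy.

    Idempotent.  The number of self-loops and isolated nodes removed is
    logged.  Raises ``ValueError`` if nothing remains after curation.
    """
    G = net.copy()
    loops = list(nx.selfloop_edges(G))
    G.remove_edges_from(loops)
    isolated = [n for n, d in G.degree() if d == 0]
    G.remove_nodes_from(isolated)
    if loops or isolated:
        logger.info(
            "curate: removed %d self-loop(s) and %d isolated node(s)",
            len(loops), len(isolated),
        )
    if G.number_of_nodes() == 0:
        raise ValueError("network is empty after curation")
    return G


def write_network(net: nx.Graph, path: PathLike, format: str = "tsv") -> None:
    """Write a curated network as a TSV edge list or GraphML.

    Round-trip guarantee: ``read_edge_list(write_network(net))`` reproduces
    the node and edge sets exactly.  Refuses networks that violate the
    curation invariant (isolated nodes or no edges), since a pure edge list
    cannot represent isolated nodes.
    """
    if net.number_of_edges() == 0:
        raise ValueError("refusing to write a network with no edges")
    if any(d == 0 for _, d in net.degree()):
        raise ValueError("refusing to write a network with isolated nodes")
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            # explicit header keeps the reader's header auto-detection
            # unambiguous even when an edge's endpoints occur only once
            fh.write("source\ttarget\n")
            for a, b in sorted(map(sorted, net.edges())):
                fh.write(f"{a}\t{b}\n")
    elif format == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ValueError(f"unknown output format: {format!r}")
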