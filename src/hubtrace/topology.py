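"""Topological characterisation of interaction networks.

Degree spectra
    For each observed degree ``k``: the count ``N_k``, the probability
    ``P(k) = N_k / N``, the mean clustering coefficient ``C(k)`` and the mean
    neighborhood connectivity ``C_N(k)``; per node the degree ``k_i``, the
    number of edges among nearest neighbors ``m_i`` and the local clustering
    ``c_i = 2 m_i / (k_i (k_i - 1))``.

Centralities
    Closeness is computed with the component size ``n`` in the numerator,
    ``C_C(i) = n / sum_j d_ij`` — a deliberate deviation from the
    conventional ``n - 1`` numerator, kept for comparability with the
    formula this pipeline mirrors.  Raw betweenness ``C_b(v)`` sums
    shortest-path pair dependencies over unordered pairs; the normalised
    form divides by ``M = (n-1)(n-2)/2``, the number of unordered pairs
    excluding ``v``, so that ``C_B`` lies in ``[0, 1]``.  Eigenvector
    centrality is the principal eigenvector of the adjacency matrix of the
    largest connected component, obtained by power iteration and
    L2-normalised.

Power-law fits
    Ordinary least squares of ``log10 y`` on ``log10 x``; a network is
    labelled hierarchical scale-free when both ``P(k)`` and ``C(k)`` decay
    as power laws, and assortative or disassortative according to the sign
    of the ``C_N(k)`` exponent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("hubtrace")

__all__ = [
    "DegreeSpectrum",
    "CentralityTable",
    "PowerLawFit",
    "TopologyLabel",
    "degree_spectra",
    "centrality_table",
    "fit_power_law",
    "fit_power_law_mle",
    "classify_topology",
]


# ---------------------------------------------------------------------------
# degree spectra
# ---------------------------------------------------------------------------

@dataclass
class DegreeSpectrum:
    """Per-node and per-degree distributions of an interaction network."""

    per_node: pd.DataFrame   # node, degree, m (edges among neighbors), clustering
    per_degree: pd.DataFrame  # degree, count, P, C, C_N

    def pk(self) -> pd.Series:
        """``P(k)`` indexed by degree."""
        return self.per_degree.set_index("degree")["P"]


def degree_spectra(net: nx.Graph) -> DegreeSpectrum:
    """Compute P(k), C(k) and C_N(k) together with per-node quantities.

    Local clustering of a degree-0 or degree-1 node is defined as 0 (the
    triangle ratio divides by ``k (k-1)``); neighborhood connectivity is the
    mean degree of a node's neighbors, averaged over nodes of equal degree.
    """
    nodes = list(net.nodes())
    deg = dict(net.degree())
    tri = nx.triangles(net)
    clus = nx.clustering(net)  # networkx uses the same 0-convention for k < 2
    nbr_conn = nx.average_neighbor_degree(net)

    per_node = pd.DataFrame(
        {
            "node": nodes,
            "degree": [deg[n] for n in nodes],
            "m": [tri[n] for n in nodes],
            "clustering": [clus[n] for n in nodes],
            "neighbor_connectivity": [nbr_conn[n] for n in nodes],
        }
    )

    N = len(nodes)
    grouped = per_node.groupby("degree", sort=True)
    per_degree = pd.DataFrame(
        {
            "degree": list(grouped.groups),
            "count": grouped.size().to_numpy(),
            "C": grouped["clustering"].mean().to_numpy(),
            "C_N": grouped["neighbor_connectivity"].mean().to_numpy(),
        }
    )
    per_degree.insert(2, "P", per_degree["count"] / N)
    return DegreeSpectrum(per_node=per_node, per_degree=per_degree)


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

@dataclass
class CentralityTable:
    """Per-node centralities plus the principal adjacency eigenvalue."""

    table: pd.DataFrame  # node, degree, closeness, betweenness_raw, betweenness, eigenvector
    lambda_max: float


def _power_iteration(A: np.ndarray, tol: float = 1e-13, max_iter: int = 10_000):
    """Principal eigenpair of a symmetric non-negative matrix.

    Iterates on ``A + I`` so bipartite adjacency spectra (where the +/- lambda
    pair would stall plain power iteration) still converge; the reported
    eigenvalue is the Rayleigh quotient of ``A`` itself.
    """
    n = A.shape[0]
    v = np.full(n, 1.0 / math.sqrt(n))
    shifted = A + np.eye(n)
    for _ in range(max_iter):
        w = shifted @ v
        w_norm = np.linalg.norm(w)
        if w_norm == 0.0:
            break
        w /= w_norm
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    lam = float(v @ A @ v)
    # Perron vector of a connected component is positive; fix the sign
    if v.sum() < 0:
        v = -v
    return lam, v


def centrality_table(net: nx.Graph) -> CentralityTable:
    """Closeness, raw and normalised betweenness, and eigenvector centrality.

    On a disconnected network, closeness and betweenness are computed within
    each connected component (each using its own component size), and
    eigenvector centrality is reported on the largest component with zeros
    elsewhere; a warning is logged.
    """
    components = [set(c) for c in nx.connected_components(net)]
    if len(components) > 1:
        logger.warning(
            "centrality_table: network has %d components; centralities are "
            "computed component-wise", len(components),
        )

    closeness: dict = {}
    raw_bt: dict = {}
    norm_bt: dict = {}
    eigen: dict = {n: 0.0 for n in net.nodes()}
    lambda_max = 0.0

    largest = max(components, key=len)
    for comp in components:
        sub = net.subgraph(comp)
        n = sub.number_of_nodes()
        # closeness, as-printed convention: numerator is the component size n
        for v in sub.nodes():
            dist = nx.single_source_shortest_path_length(sub, v)
            total = sum(dist.values())
            closeness[v] = n / total if total > 0 else 0.0
        # betweenness: networkx unnormalised = sum over unordered pairs
        bt = nx.betweenness_centrality(sub, normalized=False)
        M = (n - 1) * (n - 2) / 2
        for v, b in bt.items():
            raw_bt[v] = b
            norm_bt[v] = b / M if M >= 1 else 0.0
        if comp is largest and n >= 1:
            order = sorted(comp)
            A = nx.to_numpy_array(net.subgraph(order), nodelist=order)
            lam, vec = _power_iteration(A)
            lambda_max = lam
            for node, x in zip(order, vec):
                eigen[node] = float(x)

    nodes = list(net.nodes())
    deg = dict(net.degree())
    table = pd.DataFrame(
        {
            "node": nodes,
            "degree": [deg[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "betweenness_raw": [raw_bt[v] for v in nodes],
            "betweenness": [norm_bt[v] for v in nodes],
            "eigenvector": [eigen[v] for v in nodes],
        }
    )
    return CentralityTable(table=table, lambda_max=lambda_max)


# ---------------------------------------------------------------------------
# power-law fitting
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    """Result of a log–log least-squares fit ``y ~ x^slope``.

    ``exponent`` is the magnitude of the slope; ``sign`` its sign (+1, -1,
    or 0 for a flat fit).
    """

    slope: float
    exponent: float
    sign: int
    stderr: float
    r_squared: float
    n_points: int
    x_range: tuple[float, float]
    n_dropped: int = 0
    method: str = "ols"

    def __post_init__(self):
        assert 0.0 <= self.r_squared <= 1.0 + 1e-12


def fit_power_law(xs, ys) -> PowerLawFit:
    """OLS fit of ``log10(y)`` against ``log10(x)``.

    Non-positive ``y`` values are dropped (with a logged count) before
    fitting — e.g. degree-1 nodes whose clustering is exactly zero.  At
    least 3 usable points with distinct ``x`` are required; non-positive
    ``x`` is an error.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("xs and ys must have equal length")
    if np.any(xs <= 0):
        raise ValueError("x values must be strictly positive for a log-log fit")
    keep = ys > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("fit_power_law: dropped %d non-positive y value(s)", n_dropped)
    xs, ys = xs[keep], ys[keep]
    if len(xs) < 3 or len(np.unique(xs)) < 3:
        raise ValueError(
            f"need >= 3 points with distinct x to fit a power law, have {len(np.unique(xs))}"
        )
    lx, ly = np.log10(xs), np.log10(ys)
    res = stats.linregress(lx, ly)
    slope = float(res.slope)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0
    sign = 0 if slope == 0.0 else (1 if slope > 0 else -1)
    return PowerLawFit(
        slope=slope,
        exponent=abs(slope),
        sign=sign,
        stderr=float(res.stderr),
        r_squared=r2,
        n_points=len(xs),
        x_range=(float(xs.min()), float(xs.max())),
        n_dropped=n_dropped,
    )


def fit_power_law_mle(samples, xmin: float = 1.0) -> PowerLawFit:
    """Continuous-approximation maximum-likelihood exponent for samples.

    Hill-type estimator ``alpha = 1 + n / sum(ln(x_i / (xmin - 1/2)))`` for
    discrete samples (degrees) at a given ``xmin``.  Provided as an
    alternative to the default OLS spectrum fit; the two agree on clean
    power-law data but the MLE is preferable on heavy-tailed samples.
    """
    x = np.asarray(samples, dtype=float)
    x = x[x >= xmin]
    if len(x) < 3:
        raise ValueError("need >= 3 samples at or above xmin")
    alpha = 1.0 + len(x) / np.sum(np.log(x / (xmin - 0.5)))
    se = (alpha - 1.0) / math.sqrt(len(x))
    return PowerLawFit(
        slope=-alpha,
        exponent=float(alpha),
        sign=-1,
        stderr=float(se),
        r_squared=0.0,
        n_points=len(x),
        x_range=(float(x.min()), float(x.max())),
        method="mle",
    )


# ---------------------------------------------------------------------------
# topology classification
# ---------------------------------------------------------------------------

@dataclass
class TopologyLabel:
    """Classification of a network from its spectrum fits."""

    label: str          # "hierarchical scale-free" | "scale-free" | "unclassified"
    assortativity: str  # "assortative" | "disassortative" | "neutral"
    details: dict = field(default_factory=dict)


def classify_topology(
    fits: dict,
    r2_threshold: float = 0.5,
    slope_threshold: float = 0.05,
) -> TopologyLabel:
    """Classify a network from its ``P(k)``, ``C(k)`` and ``C_N(k)`` fits.

    "hierarchical scale-free" requires decaying power laws (negative slope,
    ``R^2`` at or above ``r2_threshold``) for both ``P(k)`` and ``C(k)``;
    a decaying ``P(k)`` alone yields "scale-free".  Assortativity is read
    from the sign of the ``C_N(k)`` slope: positive = assortative, negative
    = disassortative, and |slope| below ``slope_threshold`` (or exactly
    zero) = neutral.
    """
    for key in ("P(k)", "C(k)", "C_N(k)"):
        if key not in fits:
            raise ValueError(f"missing fit for {key}")
    pk, ck, cn = fits["P(k)"], fits["C(k)"], fits["C_N(k)"]

    def decays(f: PowerLawFit) -> bool:
        return (
            f.slope < 0
            and abs(f.slope) >= slope_threshold
            and f.r_squared >= r2_threshold
        )

    if decays(pk) and decays(ck):
        label = "hierarchical scale-free"
    elif decays(pk):
        label = "scale-free"
    else:
        label = "unclassified"

    if abs(cn.slope) < slope_threshold or cn.slope == 0.0:
        assort = "neutral"
    elif cn.slope > 0:
        assort = "assortative"
    else:
        assort = "disassortative"

    return TopologyLabel(
        label=label,
        assortativity=assort,
        details={
            "P(k)": (pk.slope, pk.r_squared),
            "C(k)": (ck.slope, ck.r_squared),
            "C_N(k)": (cn.slope, cn.r_squared),
            "r2_threshold": r2_threshold,
            "slope_threshold": slope_threshold,
        },
    )
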