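import math

import networkx as nx
import numpy as np
import pytest

from hubtrace import topology
from hubtrace.synthetic_data import make_control, make_deterministic_hierarchical

from conftest import (
    brute_betweenness,
    brute_closeness,
    connected_gnp,
    dense_principal_eigenvector,
)


class TestDegreeSpectra:
    def test_triangle(self):
        spec = topology.degree_spectra(nx.complete_graph(3))
        row = spec.per_degree.set_index("degree").loc[2]
        assert row["P"] == 1.0
        assert row["C"] == 1.0
        assert row["C_N"] == 2.0

    def test_path_three_nodes(self, path3):
        # P(1)=2/3, P(2)=1/3; no triangles; end nodes neighbor the hub
        spec = topology.degree_spectra(path3)
        pk = spec.pk()
        assert pk[1] == pytest.approx(2 / 3)
        assert pk[2] == pytest.approx(1 / 3)
        per = spec.per_degree.set_index("degree")
        assert (per["C"] == 0).all()
        assert per.loc[1, "C_N"] == 2.0
        assert per.loc[2, "C_N"] == 1.0

    def test_local_clustering_arithmetic(self):
        # a node with degree 4 whose neighbors share 3 edges: c = 2*3/(4*3)
        G = nx.star_graph(4)  # hub 0 with neighbors 1..4
        G.add_edges_from([(1, 2), (2, 3), (3, 4)])
        spec = topology.degree_spectra(G)
        hub = spec.per_node.set_index("node").loc[0]
        assert hub["m"] == 3
        assert hub["clustering"] == pytest.approx(0.5)

    def test_degree_one_clustering_defined_zero(self, path3):
        per_node = topology.degree_spectra(path3).per_node
        assert (per_node.loc[per_node["degree"] < 2, "clustering"] == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_pk_sums_to_one(self, seed):
        G = nx.gnp_random_graph(60, 0.08, seed=seed)
        spec = topology.degree_spectra(G)
        assert spec.per_degree["P"].sum() == pytest.approx(1.0, abs=1e-12)
        assert spec.per_degree["C"].between(0, 1).all()
        observed = spec.per_node["degree"]
        withdeg = spec.per_degree[spec.per_degree["degree"] > 0]
        assert withdeg["C_N"].between(observed.min(), observed.max()).all()


class TestCentralities:
    def test_path_closeness_as_printed(self, path3):
        # numerator is the component size n, not n-1
        tab = topology.centrality_table(path3).table.set_index("node")
        assert tab.loc["B", "closeness"] == pytest.approx(1.5)
        assert tab.loc["A", "closeness"] == pytest.approx(1.0)

    def test_closeness_convention_differs_from_networkx(self, path3):
        # regression guard: conventional closeness uses (n-1); ours is n/(n-1) larger
        ours = topology.centrality_table(path3).table.set_index("node")["closeness"]
        conv = nx.closeness_centrality(path3)
        for v in path3:
            assert ours[v] == pytest.approx(conv[v] * 3 / 2)

    def test_path_betweenness(self, path3):
        tab = topology.centrality_table(path3).table.set_index("node")
        assert tab.loc["B", "betweenness_raw"] == pytest.approx(1.0)
        assert tab.loc["B", "betweenness"] == pytest.approx(1.0)  # M = 1
        assert tab.loc["A", "betweenness"] == 0.0

    def test_triangle_eigenvector_symmetric(self):
        ct = topology.centrality_table(nx.complete_graph(3))
        assert ct.lambda_max == pytest.approx(2.0, abs=1e-9)
        vals = ct.table["eigenvector"]
        assert vals.std() == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.norm(vals) == pytest.approx(1.0)

    @pytest.mark.parametrize("n,p,seed", [(12, 0.25, 0), (25, 0.15, 3),
                                          (40, 0.1, 6), (50, 0.08, 9)])
    def test_agrees_with_brute_force(self, n, p, seed):
        G = connected_gnp(n, p, seed)
        tab = topology.centrality_table(G).table.set_index("node")
        bc = brute_closeness(G)
        bb = brute_betweenness(G)
        M = (n - 1) * (n - 2) / 2
        lam, vec = dense_principal_eigenvector(G)
        for v in G:
            assert tab.loc[v, "closeness"] == pytest.approx(bc[v], rel=1e-9)
            assert tab.loc[v, "betweenness"] == pytest.approx(bb[v] / M, abs=1e-9)
            assert abs(tab.loc[v, "eigenvector"]) == pytest.approx(abs(vec[v]), abs=1e-6)

    def test_disconnected_componentwise(self, caplog):
        G = nx.disjoint_union(nx.path_graph(3), nx.complete_graph(4))
        ct = topology.centrality_table(G)
        tab = ct.table.set_index("node")
        # path component uses its own n=3
        assert tab.loc[1, "closeness"] == pytest.approx(1.5)
        # eigenvector reported on the largest component only
        assert (tab.loc[[0, 1, 2], "eigenvector"] == 0).all()
        assert (tab.loc[[3, 4, 5, 6], "eigenvector"] != 0).all()
        assert ct.lambda_max == pytest.approx(3.0, abs=1e-9)


class TestFitPowerLaw:
    def test_exact_power_law(self):
        k = np.arange(1, 11, dtype=float)
        fit = topology.fit_power_law(k, k**-2.0)
        assert fit.exponent == pytest.approx(2.0, abs=1e-12)
        assert fit.sign == -1
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_ys_flat(self):
        fit = topology.fit_power_law([1, 2, 3, 4], [5.0] * 4)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_within_band(self):
        rng = np.random.default_rng(42)
        k = np.arange(1, 51, dtype=float)
        y = k**-1.0 * np.exp(rng.normal(0, 0.05, k.size))
        fit = topology.fit_power_law(k, y)
        assert abs(fit.exponent - 1.0) <= 0.15

    def test_zero_ys_dropped(self):
        fit = topology.fit_power_law([1, 2, 3, 4, 5], [1.0, 0.25, 0.0, 1 / 16, 1 / 25])
        assert fit.n_dropped == 1
        assert fit.n_points == 4
        assert fit.exponent == pytest.approx(2.0)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            topology.fit_power_law([1, 2], [1.0, 0.5])

    def test_nonpositive_x_error(self):
        with pytest.raises(ValueError, match="positive"):
            topology.fit_power_law([0, 1, 2], [1.0, 1.0, 1.0])

    def test_mle_matches_on_clean_samples(self):
        # the (xmin - 1/2) approximation is accurate from xmin >= 2 up
        rng = np.random.default_rng(1)
        samples = rng.zipf(2.5, size=50000)  # discrete power law, alpha=2.5
        fit = topology.fit_power_law_mle(samples, xmin=2.0)
        assert fit.exponent == pytest.approx(2.5, abs=0.15)
        assert fit.method == "mle"


def _fit(slope, r2=0.95):
    return topology.PowerLawFit(slope=slope, exponent=abs(slope),
                                sign=int(np.sign(slope)), stderr=0.01,
                                r_squared=r2, n_points=10, x_range=(1, 10))


class TestClassifyTopology:
    def test_hierarchical_scale_free_assortative(self):
        label = topology.classify_topology(
            {"P(k)": _fit(-2.0), "C(k)": _fit(-1.0), "C_N(k)": _fit(0.5)})
        assert label.label == "hierarchical scale-free"
        assert label.assortativity == "assortative"

    def test_scale_free_disassortative(self):
        label = topology.classify_topology(
            {"P(k)": _fit(-2.5), "C(k)": _fit(-0.01, r2=0.1), "C_N(k)": _fit(-0.3)})
        assert label.label == "scale-free"
        assert label.assortativity == "disassortative"

    def test_zero_cn_slope_is_neutral(self):
        label = topology.classify_topology(
            {"P(k)": _fit(-2.0), "C(k)": _fit(-1.0), "C_N(k)": _fit(0.0)})
        assert label.assortativity == "neutral"

    def test_missing_fit_errors(self):
        with pytest.raises(ValueError, match="C_N"):
            topology.classify_topology({"P(k)": _fit(-2), "C(k)": _fit(-1)})


class TestOnGeneratedNetworks:
    def test_hierarchical_network_ck_exponent_near_one(self):
        G = make_deterministic_hierarchical(4).graph
        pdg = topology.degree_spectra(G).per_degree
        fit = topology.fit_power_law(pdg["degree"].to_numpy(dtype=float),
                                     pdg["C"].to_numpy())
        assert abs(fit.exponent - 1.0) <= 0.2
        assert fit.sign == -1

    def test_preferential_attachment_flat_clustering(self):
        # scale-free control: P(k) decays, C(k) shows no strong power law
        G = make_control("preferential_attachment", 2000, 3, seed=1).graph
        pdg = topology.degree_spectra(G).per_degree
        k = pdg["degree"].to_numpy(dtype=float)
        fit_p = topology.fit_power_law(k, pdg["P"].to_numpy())
        fit_c = topology.fit_power_law(k, pdg["C"].to_numpy())
        assert fit_p.slope < 0
        assert fit_c.r_squared < 0.5
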