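"""Correlation primitives, network construction, hubs, export round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special

import lincnet as ln
from lincnet.coexpression import CoexpressionNetwork

from oracles import network_edges_oracle


class TestPearson:
    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert ln.pearson_r(x, 2 * x + 3) == pytest.approx(1.0)
        assert ln.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        xc = np.array(x) - np.mean(x)
        yc = np.array(y) - np.mean(y)
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert ln.pearson_r(x, y) == pytest.approx(expected)

    def test_zero_variance_undefined(self):
        assert np.isnan(ln.pearson_r([1, 1, 1], [1, 2, 3]))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="n >= 3"):
            ln.pearson_r([1, 2], [3, 4])
        with pytest.raises(ValueError, match="finite"):
            ln.pearson_r([1, 2, np.inf], [1, 2, 3])


class TestCorrelationPvalue:
    def test_null_and_perfect(self):
        assert ln.correlation_pvalue(0.0, 10) == pytest.approx(1.0)
        assert ln.correlation_pvalue(1.0, 10) == 0.0
        assert ln.correlation_pvalue(-1.0, 10) == 0.0

    def test_monotone_decreasing_in_abs_r(self):
        rs = np.linspace(0, 0.999, 50)
        ps = [ln.correlation_pvalue(r, 12) for r in rs]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_matches_t_density_quadrature(self):
        r, n = 0.9, 5
        t = r * np.sqrt((n - 2) / (1 - r * r))
        df = n - 2

        def density(u):
            c = special.gamma((df + 1) / 2) / (
                np.sqrt(df * np.pi) * special.gamma(df / 2))
            return c * (1 + u * u / df) ** (-(df + 1) / 2)

        tail, _ = integrate.quad(density, t, np.inf)
        assert ln.correlation_pvalue(r, n) == pytest.approx(2 * tail,
                                                            rel=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            ln.correlation_pvalue(0.5, 2)


class TestBuildNetwork:
    def test_zero_noise_hub_degree_equals_block_size(self):
        cfg = ln.SimulationConfig(
            n_lnc=60, n_mrna=200, n_de_lnc={"6wk": (0, 0), "20wk": (10, 5)},
            n_de_mrna={"6wk": (0, 0), "20wk": (40, 10)},
            n_shared_de_lnc=(0, 0), n_hubs=2, hub_block_size=10,
            hub_noise_sd=0.0, n_go_terms=5, n_pathway_terms=5,
            term_size_range=(5, 30), seed=9)
        catalog = ln.generate_catalog(cfg)
        study, truth = ln.simulate_expression(catalog, cfg)
        net = ln.build_network(sorted(truth.de_ids("20wk", "lncRNA")),
                               sorted(truth.de_ids("20wk", "mRNA")),
                               study, timepoint="20wk")
        for hub in truth.hub_ids:
            assert net.degree(hub) == 10

    def test_r_threshold_one_gives_empty_network(self, small_sim):
        _, study, truth, _ = small_sim
        net = ln.build_network(sorted(truth.de_ids("20wk", "lncRNA")),
                               sorted(truth.de_ids("20wk", "mRNA")),
                               study, timepoint="20wk", r_threshold=1.0)
        assert net.n_edges == 0

    def test_matches_bruteforce_all_pairs(self, small_sim):
        _, study, truth, _ = small_sim
        lnc = sorted(truth.de_ids("20wk", "lncRNA"))[:12]
        lnc += truth.hub_ids
        mrna = sorted(truth.de_ids("20wk", "mRNA"))[:60]
        net = ln.build_network(sorted(set(lnc)), mrna, study,
                               timepoint="20wk", r_threshold=0.9)
        expected = network_edges_oracle(study, sorted(set(lnc)), mrna,
                                        "20wk", r_threshold=0.9)
        got = {(e["lnc"], e["mrna"]) for _, e in net.edges.iterrows()}
        assert got == expected

    def test_degree_conservation(self, small_sim):
        _, study, truth, _ = small_sim
        net = ln.build_network(sorted(truth.de_ids("20wk", "lncRNA")),
                               sorted(truth.de_ids("20wk", "mRNA")),
                               study, timepoint="20wk")
        nodes = net.nodes
        lnc_sum = nodes.loc[nodes["role"] == "lncRNA", "degree"].sum()
        mrna_sum = nodes.loc[nodes["role"] == "mRNA", "degree"].sum()
        assert lnc_sum == mrna_sum == net.n_edges
        assert net.n_edges > 0

    def test_raising_threshold_never_adds_edges(self, small_sim):
        _, study, truth, _ = small_sim
        lnc = sorted(truth.de_ids("20wk", "lncRNA"))
        mrna = sorted(truth.de_ids("20wk", "mRNA"))
        edges = []
        for thr in (0.6, 0.9, 0.995, 0.999):
            net = ln.build_network(lnc, mrna, study, timepoint="20wk",
                                   r_threshold=thr)
            edges.append({(e["lnc"], e["mrna"])
                          for _, e in net.edges.iterrows()})
        for larger, smaller in zip(edges, edges[1:]):
            assert smaller <= larger

    def test_empty_de_sets_give_empty_network(self, small_sim):
        net = ln.build_network([], [], small_sim[1], timepoint="20wk")
        assert net.n_edges == 0 and net.nodes.empty

    def test_unknown_ids_rejected(self, small_sim):
        with pytest.raises(KeyError, match="absent"):
            ln.build_network(["nope"], ["alsono"], small_sim[1],
                             timepoint="20wk")


def _toy_network(degrees):
    edges = []
    for lnc, d in degrees.items():
        for j in range(d):
            edges.append((lnc, f"m{lnc}_{j}", 0.999, 1e-6, 24, "positive"))
    edges = pd.DataFrame(edges, columns=["lnc", "mrna", "r", "p", "n",
                                         "sign"])
    lnc_ids = list(degrees)
    mrna_ids = list(edges["mrna"])
    nodes = pd.DataFrame({
        "role": ["lncRNA"] * len(lnc_ids) + ["mRNA"] * len(mrna_ids),
        "degree": [degrees[k] for k in lnc_ids] + [1] * len(mrna_ids),
        "regulation": "up",
    }, index=pd.Index(lnc_ids + mrna_ids, name="id"))
    return CoexpressionNetwork(edges, nodes)


class TestRankHubs:
    def test_simple_ordering(self):
        rk = ln.rank_hubs(_toy_network({"a": 10, "b": 7, "c": 3}), k=2)
        assert rk.hubs == ["a", "b"]
        assert not rk.tied_at_k and not rk.shortfall

    def test_all_tied_lexicographic(self):
        rk = ln.rank_hubs(_toy_network({"b": 4, "c": 4, "a": 4}), k=2)
        assert rk.hubs == ["a", "b"]
        assert rk.tied_at_k

    def test_shortfall_flagged(self):
        rk = ln.rank_hubs(_toy_network({"a": 2}), k=5)
        assert rk.hubs == ["a"]
        assert rk.shortfall

    def test_planted_hub_recovery_over_seeds(self):
        """Low-noise recovery is perfect; recovery never improves as the
        residual noise around the latent factor grows."""
        noise_levels = [0.01, 0.3, 0.8]
        rates = []
        for noise in noise_levels:
            rec = []
            for seed in range(10):
                cfg = ln.SimulationConfig(
                    n_lnc=60, n_mrna=250,
                    n_de_lnc={"6wk": (0, 0), "20wk": (12, 6)},
                    n_de_mrna={"6wk": (0, 0), "20wk": (60, 20)},
                    n_shared_de_lnc=(0, 0), n_hubs=5, hub_block_size=10,
                    hub_noise_sd=noise, n_go_terms=5, n_pathway_terms=5,
                    term_size_range=(5, 30), seed=1000 + seed)
                catalog = ln.generate_catalog(cfg)
                study, truth = ln.simulate_expression(catalog, cfg)
                net = ln.build_network(
                    sorted(truth.de_ids("20wk", "lncRNA")),
                    sorted(truth.de_ids("20wk", "mRNA")),
                    study, timepoint="20wk")
                rk = ln.rank_hubs(net, k=5)
                rec.append(len(set(rk.hubs) & set(truth.hub_ids)) / 5)
            rates.append(np.mean(rec))
        assert rates[0] == 1.0
        assert rates[0] >= rates[1] >= rates[2]


class TestSubnetwork:
    def test_all_hubs_is_identity(self):
        net = _toy_network({"a": 3, "b": 2})
        sub, n_partners = ln.extract_subnetwork(net, ["a", "b"])
        assert sub.n_edges == net.n_edges
        assert n_partners == 5

    def test_single_hub_degree_edges(self):
        net = _toy_network({"a": 3, "b": 2})
        sub, n_partners = ln.extract_subnetwork(net, ["a"])
        assert sub.n_edges == 3 and n_partners == 3

    def test_shared_partners_counted_once(self):
        edges = pd.DataFrame(
            [("a", "m1", 0.999, 1e-6, 24, "positive"),
             ("a", "m2", 0.999, 1e-6, 24, "positive"),
             ("b", "m1", -0.999, 1e-6, 24, "negative")],
            columns=["lnc", "mrna", "r", "p", "n", "sign"])
        nodes = pd.DataFrame(
            {"role": ["lncRNA", "lncRNA", "mRNA", "mRNA"],
             "degree": [2, 1, 2, 1], "regulation": "up"},
            index=pd.Index(["a", "b", "m1", "m2"], name="id"))
        net = CoexpressionNetwork(edges, nodes)
        _, n_partners = ln.extract_subnetwork(net, ["a", "b"])
        assert n_partners == 2 < 3  # union, not sum of degrees

    def test_unknown_hub_rejected(self):
        with pytest.raises(KeyError, match="unknown hub"):
            ln.extract_subnetwork(_toy_network({"a": 1}), ["zz"])


class TestExport:
    def test_sif_line_per_edge(self, tmp_path):
        net = _toy_network({"a": 3})
        ln.export_network(net, tmp_path / "net.sif", "sif")
        lines = (tmp_path / "net.sif").read_text().strip().splitlines()
        assert len(lines) == 3
        assert all(parts.split("\t")[1] == "pos" for parts in lines)

    def test_empty_network_files_valid(self, tmp_path):
        empty = _toy_network({})
        ln.export_network(empty, tmp_path / "e.tsv", "tsv")
        back = ln.read_network(tmp_path / "e.tsv", "tsv")
        assert back.n_edges == 0

    def test_graphml_round_trip(self, tmp_path):
        net = _toy_network({"a": 2, "b": 1})
        ln.export_network(net, tmp_path / "n.graphml", "graphml")
        back = ln.read_network(tmp_path / "n.graphml", "graphml")
        got = {(e["lnc"], e["mrna"], round(e["r"], 6), e["sign"])
               for _, e in back.edges.iterrows()}
        want = {(e["lnc"], e["mrna"], round(e["r"], 6), e["sign"])
                for _, e in net.edges.iterrows()}
        assert got == want
        assert back.nodes.loc["a", "degree"] == net.nodes.loc["a", "degree"]

    def test_tsv_round_trip(self, tmp_path):
        net = _toy_network({"a": 2, "b": 1})
        ln.export_network(net, tmp_path / "n.tsv", "tsv")
        back = ln.read_network(tmp_path / "n.tsv", "tsv")
        pd.testing.assert_frame_equal(back.edges, net.edges,
                                      check_dtype=False)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            ln.export_network(_toy_network({"a": 1}), tmp_path / "x", "xml")
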