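"""Correlation networks, their properties, intersections, and SDNs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabnet.network import (
    NetworkProperties,
    build_network,
    correlation_matrix,
    intersect_networks,
    network_properties,
    symmetric_difference,
)
from metabnet.univariate import bh_fdr
from tests.conftest import make_normalized


def _toy_table(seed=0, n=8, p=5):
    rng = np.random.default_rng(seed)
    return make_normalized(np.exp(rng.standard_normal((n, p))))


class TestCorrelationMatrix:
    def test_perfect_correlation_gives_p_zero(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        values = np.column_stack([base, 2 * base, base + 1])
        r, p, n = correlation_matrix(make_normalized(values))
        assert r.loc["f0", "f1"] == pytest.approx(1.0)
        assert p.loc["f0", "f1"] == 0.0
        assert n == 5

    def test_p_value_formula_r09_n12(self):
        """r=0.9 at n=12 maps through the exact t transform to the value
        the R oracle 2*pt(-r*sqrt(10)/sqrt(1-r^2), 10) gives: 6.644e-5."""
        base = np.linspace(0, 1, 12)
        noise = np.array([0.35, -0.41, 0.12, -0.28, 0.31, -0.05,
                          0.22, -0.33, 0.08, -0.15, 0.27, -0.13])
        # calibrate second column so the sample r is 0.9 exactly
        resid = noise - np.polyval(np.polyfit(base, noise, 1), base)
        y = base + resid / np.std(resid) * np.std(base) * np.sqrt(1 / 0.81 - 1)
        table = make_normalized(np.column_stack([base + 1, y + 2]))
        r, p, n = correlation_matrix(table)
        assert r.loc["f0", "f1"] == pytest.approx(0.9, abs=1e-12)
        assert p.loc["f0", "f1"] == pytest.approx(6.644441e-5, rel=1e-5)

    def test_matches_pairwise_pearsonr_oracle(self):
        """The full matrix equals a double-loop scipy.stats.pearsonr scan."""
        table = _toy_table()
        r, p, n = correlation_matrix(table)
        cols = list(r.columns)
        for a, b in itertools.combinations(cols, 2):
            ref = stats.pearsonr(table.values[a], table.values[b])
            assert r.loc[a, b] == pytest.approx(ref.statistic, abs=1e-12)
            assert p.loc[a, b] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_feature_excluded(self, caplog):
        values = np.exp(np.random.default_rng(1).standard_normal((6, 3)))
        values[:, 2] = 1.0
        with caplog.at_level("WARNING", logger="metabnet.network"):
            r, _, _ = correlation_matrix(make_normalized(values))
        assert "f2" not in r.columns

    def test_group_selection_and_errors(self, study_table):
        from metabnet.io import normalize_internal_standard

        norm = normalize_internal_standard(study_table)
        r, p, n = correlation_matrix(norm, group=("WT", "S"))
        assert n == 12  # both timepoints x 6 replicates pooled
        r2, _, n2 = correlation_matrix(norm, group=("WT", "S"), timepoint="t2h")
        assert n2 == 6
        with pytest.raises(ValueError, match="absent"):
            correlation_matrix(norm, group=("WT", "nope"))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="need >= 4"):
            correlation_matrix(_toy_table(n=3))


class TestBuildNetwork:
    def test_independent_features_give_empty_network(self):
        rng = np.random.default_rng(2)
        table = make_normalized(np.exp(rng.standard_normal((12, 6))))
        net = build_network(*correlation_matrix(table)[:2])
        assert net.n_edges == 0
        assert net.n_nodes == 0  # nodes require >= 1 edge

    def test_edges_match_brute_force_threshold_filter(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(12)
        values = np.column_stack(
            [base + 0.05 * rng.standard_normal(12) for _ in range(4)]
            + [rng.standard_normal(12) for _ in range(4)]
        )
        table = make_normalized(np.exp(values / 4))
        r, p, _ = correlation_matrix(table)
        net = build_network(r, p, r_min=0.9, q_max=0.05)

        cols = list(r.columns)
        pairs = list(itertools.combinations(range(len(cols)), 2))
        q = bh_fdr([p.iloc[i, j] for i, j in pairs])
        expected = {
            tuple(sorted((cols[i], cols[j])))
            for (i, j), qv in zip(pairs, q)
            if abs(r.iloc[i, j]) > 0.9 and qv < 0.05
        }
        assert net.edge_set() == expected
        assert len(expected) > 0

    def test_edge_set_monotone_in_thresholds(self):
        table = _toy_table(seed=4, n=10, p=8)
        r, p, _ = correlation_matrix(table)
        loose = build_network(r, p, r_min=0.2, q_max=0.6)
        tight_r = build_network(r, p, r_min=0.5, q_max=0.6)
        tight_q = build_network(r, p, r_min=0.2, q_max=0.2)
        assert tight_r.edge_set() <= loose.edge_set()
        assert tight_q.edge_set() <= loose.edge_set()

    def test_planted_block_recovered_as_clique(self, flat_design):
        """A 6-feature block at population r=0.98 (n=12 samples) comes
        back as the complete 15-edge clique with no cross edges in at
        least 90% of 100 seeded simulations."""
        from metabnet.io import normalize_internal_standard
        from metabnet.simulate import (
            CorrelationBlock,
            CorrelationSpec,
            EffectSpec,
            generate_peak_table,
        )

        corr = CorrelationSpec((CorrelationBlock(tuple(range(6)), 0.98),))
        successes = 0
        for seed in range(100):
            table = generate_peak_table(flat_design, EffectSpec(), corr, seed=seed)
            norm = normalize_internal_standard(table)
            r, p, _ = correlation_matrix(norm, group=("G", "C"))
            net = build_network(r, p)
            block = set(norm.features[:6])
            within = {e for e in net.edge_set() if set(e) <= block}
            if len(within) == 15 and net.n_edges == 15:
                successes += 1
        assert successes >= 90

    def test_null_data_rarely_produces_edges(self):
        """Independent features at n=12, p=50: at most 5% of simulations
        yield any edge under the default thresholds."""
        with_edges = 0
        n_sims = 400
        for seed in range(n_sims):
            rng = np.random.default_rng(50_000 + seed)
            table = make_normalized(rng.standard_normal((12, 50)))
            net = build_network(*correlation_matrix(table)[:2])
            with_edges += net.n_edges > 0
        assert with_edges / n_sims <= 0.05


class TestNetworkProperties:
    def test_triangle_closed_form(self):
        from metabnet.network import CorrelationNetwork
        import networkx as nx

        g = nx.Graph()
        for a, b in [("x", "y"), ("y", "z"), ("x", "z")]:
            g.add_edge(a, b, r=1.0, p=0.0, q=0.0)
        props = network_properties(CorrelationNetwork(label="t", graph=g))
        assert props.average_degree == pytest.approx(2.0)
        assert props.density == pytest.approx(0.5)          # 3/(3*2)
        assert props.standard_density == pytest.approx(1.0)

    def test_published_cold_shock_summaries(self):
        """The printed group summaries are reproduced from their printed
        node/edge counts under the E/(n(n-1)) density convention."""
        adh1 = NetworkProperties.from_counts(68, 1410)
        assert adh1.density == pytest.approx(0.309, abs=5e-4)
        wt = NetworkProperties.from_counts(64, 2700)
        assert wt.average_degree == pytest.approx(84.4, abs=0.05)
        # 2700/4032 = 0.6696: the published 0.669 truncates, 0.670 rounds
        assert int(wt.density * 1000) / 1000 == 0.669
        assert round(wt.density, 3) == 0.670

    def test_convention_is_half_standard(self):
        props = NetworkProperties.from_counts(10, 13)
        assert props.density == pytest.approx(props.standard_density / 2)

    def test_empty_network_warns_and_zeroes(self, caplog):
        with caplog.at_level("WARNING", logger="metabnet.network"):
            props = NetworkProperties.from_counts(0, 0)
        assert props.average_degree == 0.0
        assert props.density == 0.0


def _random_net_pair(seed):
    import networkx as nx
    from metabnet.network import CorrelationNetwork

    rng = np.random.default_rng(seed)
    nodes = [f"m{i}" for i in range(8)]
    nets = []
    for label in ("A", "B"):
        g = nx.Graph()
        for i, j in itertools.combinations(range(8), 2):
            if rng.random() < 0.3:
                g.add_edge(nodes[i], nodes[j], r=float(rng.uniform(0.9, 1)),
                           p=1e-6, q=1e-4)
        nets.append(CorrelationNetwork(label=label, graph=g))
    return nets


class TestSetOperations:
    def test_intersection_identity_and_disjoint(self):
        a, b = _random_net_pair(0)
        assert intersect_networks(a, a).edge_set() == a.edge_set()
        import networkx as nx
        from metabnet.network import CorrelationNetwork

        empty = CorrelationNetwork(label="E", graph=nx.Graph())
        assert intersect_networks(a, empty).n_edges == 0

    def test_sdn_of_identical_networks_is_empty(self):
        a, _ = _random_net_pair(1)
        assert symmetric_difference(a, a).n_edges == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_set_operations_match_brute_force(self, seed):
        a, b = _random_net_pair(seed)
        ea, eb = a.edge_set(), b.edge_set()
        inter = intersect_networks(a, b)
        sdn = symmetric_difference(a, b)
        assert inter.edge_set() == (ea & eb)
        sdn_edges = {tuple(sorted(map(str, e))) for e in sdn.graph.edges}
        assert sdn_edges == (ea ^ eb)
        # tags partition the SDN
        assert sdn.edges_specific_to("A") == len(ea - eb)
        assert sdn.edges_specific_to("B") == len(eb - ea)
        assert sdn.n_edges == sdn.edges_specific_to("A") + sdn.edges_specific_to("B")
        # SDN and intersection partition the union
        assert sdn_edges | inter.edge_set() == (ea | eb)
        assert not (sdn_edges & inter.edge_set())

    def test_published_sdn_arithmetic(self):
        """290 and 1580 source-specific edges total 1870 at ratio 5.45."""
        import networkx as nx
        from metabnet.network import CorrelationNetwork

        rng = np.random.default_rng(6)
        universe = [f"m{i}" for i in range(132)]
        pairs = list(itertools.combinations(universe, 2))
        rng.shuffle(pairs)
        ga, gb = nx.Graph(), nx.Graph()
        for u, v in pairs[:290]:
            ga.add_edge(u, v, r=0.95, p=1e-8, q=1e-6)
        for u, v in pairs[290:290 + 1580]:
            gb.add_edge(u, v, r=0.95, p=1e-8, q=1e-6)
        sdn = symmetric_difference(
            CorrelationNetwork(label="adh1:S", graph=ga),
            CorrelationNetwork(label="WT:S", graph=gb),
        )
        assert sdn.n_edges == 1870
        assert sdn.edge_ratio == pytest.approx(5.45, abs=0.005)

    def test_node_specificity_counts(self):
        import networkx as nx
        from metabnet.network import CorrelationNetwork

        ga, gb = nx.Graph(), nx.Graph()
        ga.add_edge("x", "y")
        gb.add_edge("y", "z")
        sdn = symmetric_difference(
            CorrelationNetwork(label="A", graph=ga),
            CorrelationNetwork(label="B", graph=gb),
        )
        # x only touches A edges, z only B, y touches both
        assert sdn.nodes_specific_to("A") == 1
        assert sdn.nodes_specific_to("B") == 1
        tallies = sdn.node_tallies().set_index("node")
        assert tallies.loc["y", "edges_A"] == 1
        assert tallies.loc["y", "edges_B"] == 1
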