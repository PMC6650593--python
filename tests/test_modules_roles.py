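import networkx as nx
import numpy as np
import pytest

from mran.datamodel import (
    CYANOBACTERIAL,
    ENVIRONMENTAL,
    NON_CYANOBACTERIAL,
    ValidationError,
)
from mran.modules import (
    CONNECTOR,
    MODULE_HUB,
    NETWORK_HUB,
    PERIPHERAL,
    ModulePartition,
    compute_roles,
    label_blooms,
    louvain_partition,
    module_monthly_pattern,
    role_census,
)

from conftest import make_table


def brute_roles(g, labels):
    """Independent Zi/Pi by direct edge counting (oracle for compute_roles)."""
    out = {}
    modules = set(labels.values())
    within = {
        n: sum(labels[nb] == labels[n] for nb in g.neighbors(n)) for n in g.nodes
    }
    for n in g.nodes:
        k = g.degree(n)
        if k == 0:
            continue
        members = [m for m in g.nodes if labels[m] == labels[n]]
        vals = np.array([within[m] for m in members], dtype=float)
        sd = vals.std()
        zi = (within[n] - vals.mean()) / sd if sd > 0 else 0.0
        pi = 1.0 - sum(
            (sum(labels[nb] == s for nb in g.neighbors(n)) / k) ** 2 for s in modules
        )
        out[n] = (zi, pi)
    return out


class TestLouvain:
    def test_two_cliques_give_two_modules_and_half_modularity(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        part = louvain_partition(g, seed=0)
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5)

    def test_single_clique_is_one_module_with_zero_modularity(self):
        part = louvain_partition(nx.complete_graph(6), seed=0)
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0)

    def test_clique_ring_recovers_cliques_at_optimal_modularity(self):
        g = nx.ring_of_cliques(4, 5)
        part = louvain_partition(g, seed=1)
        assert part.n_modules == 4
        # module labels coincide with the cliques
        for c in range(4):
            labels = {part.labels[5 * c + i] for i in range(5)}
            assert len(labels) == 1
        clique_partition = [set(range(5 * c, 5 * c + 5)) for c in range(4)]
        q_clique = nx.community.modularity(g, clique_partition)
        assert part.q == pytest.approx(q_clique)

    def test_deterministic_given_seed(self):
        g = nx.gnm_random_graph(40, 120, seed=9)
        p1 = louvain_partition(g, seed=3)
        p2 = louvain_partition(g, seed=3)
        assert p1.labels == p2.labels and p1.q == p2.q

    def test_major_modules_cover_threshold(self):
        labels = {f"n{i}": (0 if i < 70 else (1 if i < 90 else i)) for i in range(100)}
        part = ModulePartition(labels, q=0.4, major_coverage=0.85)
        assert part.major_modules == [0, 1]

    def test_empty_graph_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            louvain_partition(nx.Graph())


class TestRoles:
    def test_all_internal_links_give_zero_participation(self):
        g = nx.complete_graph(5)
        part = ModulePartition({n: 0 for n in g.nodes}, q=0.0)
        roles = compute_roles(g, part)
        assert all(r.pi == 0.0 for r in roles)

    def test_balanced_split_participation(self):
        # degree-4 node with 2 links in each of two modules -> Pi = 0.5
        g = nx.star_graph(4)
        labels = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1}
        roles = {r.node: r for r in compute_roles(g, ModulePartition(labels, 0.0))}
        assert roles[0].pi == pytest.approx(0.5)

    def test_uniform_within_degree_means_no_module_hubs(self):
        g = nx.cycle_graph(6)
        part = ModulePartition({n: 0 for n in g.nodes}, q=0.0)
        roles = compute_roles(g, part)
        assert all(r.zi == 0.0 and r.category == PERIPHERAL for r in roles)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            n = int(rng.integers(5, 41))
            g = nx.gnm_random_graph(n, int(rng.integers(n, 3 * n)),
                                    seed=int(rng.integers(1 << 30)))
            labels = {v: int(rng.integers(0, 4)) for v in g.nodes}
            expected = brute_roles(g, labels)
            got = compute_roles(g, ModulePartition(labels, 0.0))
            assert {r.node for r in got} == set(expected)
            for r in got:
                zi, pi = expected[r.node]
                assert r.zi == pytest.approx(zi, abs=1e-12)
                assert r.pi == pytest.approx(pi, abs=1e-12)

    def test_hub_of_large_star_is_module_hub(self):
        g = nx.star_graph(30)
        g.add_edge("x", "y")  # second module
        labels = {n: 0 for n in g.nodes}
        labels["x"] = labels["y"] = 1
        roles = {r.node: r for r in compute_roles(g, ModulePartition(labels, 0.0))}
        # hand computation: within-degrees are (30, 1, ..., 1), mean 1.935, sd 5.7
        within = np.array([30] + [1] * 30, dtype=float)
        zi = (30 - within.mean()) / within.std()
        assert roles[0].zi == pytest.approx(zi)
        assert roles[0].category == (MODULE_HUB if zi > 2.5 else PERIPHERAL)
        assert zi > 2.5

    def test_uncovered_node_is_an_error(self):
        g = nx.path_graph(3)
        with pytest.raises(ValidationError, match="cover"):
            compute_roles(g, ModulePartition({0: 0, 1: 0}, 0.0))

    def test_census_sums_to_one(self):
        g = nx.star_graph(30)
        part = ModulePartition({n: 0 for n in g.nodes}, 0.0)
        census = role_census(compute_roles(g, part))
        four = [PERIPHERAL, MODULE_HUB, CONNECTOR, NETWORK_HUB]
        assert sum(census[c] for c in four) == pytest.approx(1.0)
        assert census["pi_zero_fraction"] == 1.0


class TestMonthlyPattern:
    def test_single_otu_module_min_max_scaled(self):
        t = make_table([[0.2, 0.8], [0.4, 0.6], [0.6, 0.4]], ["A", "B"],
                       [NON_CYANOBACTERIAL] * 2)
        part = ModulePartition({"A": 0, "B": 1}, 0.0)
        pat = module_monthly_pattern(t, part)
        np.testing.assert_allclose(pat.loc[0].to_numpy(), [0.0, 0.5, 1.0])
        np.testing.assert_allclose(pat.loc[1].to_numpy(), [1.0, 0.5, 0.0])

    def test_constant_series_maps_to_zero(self):
        t = make_table([[0.5, 0.5]] * 3, ["A", "B"], [NON_CYANOBACTERIAL] * 2)
        pat = module_monthly_pattern(t, ModulePartition({"A": 0, "B": 0}, 0.0))
        np.testing.assert_array_equal(pat.loc[0].to_numpy(), 0.0)

    def test_mirrored_ramps_average_to_flat_half(self):
        t = make_table([[0.2, 0.8], [0.4, 0.6], [0.6, 0.4]], ["A", "B"],
                       [NON_CYANOBACTERIAL] * 2)
        pat = module_monthly_pattern(t, ModulePartition({"A": 0, "B": 0}, 0.0))
        np.testing.assert_allclose(pat.loc[0].to_numpy(), 0.5)

    def test_cyanobacterial_members_are_excluded(self):
        t = make_table([[0.2, 0.8], [0.4, 0.6]], ["A", "B"],
                       [CYANOBACTERIAL, NON_CYANOBACTERIAL])
        pat = module_monthly_pattern(t, ModulePartition({"A": 0, "B": 0}, 0.0))
        # only B (non-cyanobacterial, decreasing 0.8 -> 0.6) contributes
        np.testing.assert_allclose(pat.loc[0].to_numpy(), [1.0, 0.0])

    def test_module_without_members_warns_and_is_nan(self):
        t = make_table([[1.0], [1.0]], ["A"], [CYANOBACTERIAL])
        with pytest.warns(UserWarning, match="no non-cyanobacterial"):
            pat = module_monthly_pattern(t, ModulePartition({"A": 0}, 0.0))
        assert pat.loc[0].isna().all()


class TestBloomLabeling:
    def _table(self, prop, chl):
        vals = [[prop, 1.0 - prop, chl]]
        return make_table(vals, ["CY", "OTH", "chl_a"],
                          [CYANOBACTERIAL, NON_CYANOBACTERIAL, ENVIRONMENTAL],
                          dates=["2016-08"])

    @pytest.mark.parametrize(
        "prop,chl,is_bloom,rule",
        [
            (0.12, 20.0, True, "proportion+chl"),
            (0.12, 10.0, False, "none"),
            (0.85, 10.0, True, "dominance_override"),
        ],
    )
    def test_bloom_rule_truth_table(self, prop, chl, is_bloom, rule):
        (call,) = label_blooms(self._table(prop, chl), ["CY"])
        assert call.is_bloom is is_bloom
        assert call.rule_fired == rule

    def test_thresholds_are_strict(self):
        (call,) = label_blooms(self._table(0.10, 20.0), ["CY"])
        assert not call.is_bloom
        (call,) = label_blooms(self._table(0.12, 15.0), ["CY"])
        assert not call.is_bloom

    def test_monotone_in_thresholds(self):
        t = self._table(0.12, 20.0)
        base = label_blooms(t, ["CY"])[0].is_bloom
        for kw in ({"prop_threshold": 0.15}, {"chl_threshold": 25.0}):
            raised = label_blooms(t, ["CY"], **kw)[0].is_bloom
            assert base or not raised  # raising a threshold never creates blooms

    def test_negative_chl_is_an_error(self):
        with pytest.raises(ValidationError, match="negative chl"):
            label_blooms(self._table(0.5, -1.0), ["CY"])
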