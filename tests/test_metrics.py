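"""Temporal community metrics against hand-counted fixtures.

The six hand-written partitions below cover the canonical narratives:
plain switches, the community split (cohesion > 0, disjointedness = 0),
the community merge (same), lone switchers, and constant partitions.
"""

import numpy as np
import pytest

from longnet import (
    MultilayerPartition,
    allegiance,
    cohesion_matrix,
    node_cohesion_strength,
    node_disjointedness,
    node_flexibility,
    node_promiscuity,
    recruitment,
    summarize,
)
from longnet.metrics import metrics_long_table
from longnet.modularity import ModularityParams, ModularityResult, OptimizationEnsemble

from conftest import labels


def P(rows):
    return MultilayerPartition(np.array(rows))


# -- hand fixtures -----------------------------------------------------------

CONSTANT = P([[0, 0, 0, 0], [0, 0, 0, 0], [1, 1, 1, 1]])

ONE_SWITCH = P([[1, 1, 2, 2], [1, 1, 1, 1], [2, 2, 2, 2]])  # node 0: [1,1,2,2]

ALTERNATING = P([[1, 2, 1, 2], [1, 1, 1, 1], [2, 2, 2, 2]])

# nodes 0,1 jointly move 0 -> 1 at the single transition; node 2 stays
JOINT_MOVE = P([[0, 1], [0, 1], [2, 2]])

# split: community 0 = {0,1,2,3} splits, {0,1} -> 1 and {2,3} -> 2
SPLIT = P([[0, 1], [0, 1], [0, 2], [0, 2], [3, 3]])

# merge: all of community 1 joins community 0
MERGE = P([[0, 0], [0, 0], [1, 0], [1, 0]])

# node 0 moves alone at transition 1 of 3
LONE = P([[0, 0, 1, 1], [0, 0, 0, 0], [1, 1, 1, 1], [2, 2, 2, 2]])


class TestFlexibility:
    def test_hand_counts(self):
        assert node_flexibility(ONE_SWITCH)[0] == pytest.approx(1 / 3)
        assert node_flexibility(ALTERNATING)[0] == 1.0
        assert np.all(node_flexibility(CONSTANT) == 0.0)

    def test_needs_two_layers(self):
        with pytest.raises(ValueError):
            node_flexibility(P([[0], [1]]))


class TestPromiscuity:
    def test_visited_over_total_communities(self):
        # ONE_SWITCH partition has K = 2 communities total
        prom = node_promiscuity(ONE_SWITCH)
        assert prom[0] == pytest.approx(2 / 2)
        assert prom[1] == pytest.approx(1 / 2)

    def test_constant_node_in_partition_with_four_communities(self):
        g = P([[0, 0], [1, 1], [2, 2], [3, 3]])
        assert np.all(node_promiscuity(g) == 0.25)

    def test_single_community_partition_gives_one_everywhere(self):
        assert np.all(node_promiscuity(CONSTANT.canonicalized()) <= 1.0)
        one_comm = P([[0, 0], [0, 0]])
        assert np.all(node_promiscuity(one_comm) == 1.0)


class TestCohesionAndDisjointedness:
    def test_joint_move_counts_once_per_pair(self):
        coh = cohesion_matrix(JOINT_MOVE)
        assert coh[0, 1] == 1.0 and coh[1, 0] == 1.0
        assert coh.sum() == 2.0
        assert np.array_equal(node_cohesion_strength(JOINT_MOVE), [1.0, 1.0, 0.0])
        assert np.all(node_disjointedness(JOINT_MOVE) == 0.0)

    def test_split_has_cohesion_without_disjointedness(self):
        strength = node_cohesion_strength(SPLIT)
        assert np.array_equal(strength, [1.0, 1.0, 1.0, 1.0, 0.0])
        assert np.all(node_disjointedness(SPLIT) == 0.0)
        coh = cohesion_matrix(SPLIT)
        assert coh[0, 2] == 0.0  # different subgroups do not cohere

    def test_merge_has_cohesion_without_disjointedness(self):
        assert np.array_equal(node_cohesion_strength(MERGE), [0.0, 0.0, 1.0, 1.0])
        assert np.all(node_disjointedness(MERGE) == 0.0)

    def test_lone_switcher_counts(self):
        dis = node_disjointedness(LONE)
        assert dis[0] == pytest.approx(1 / 3)
        assert np.all(dis[1:] == 0.0)
        assert np.all(node_cohesion_strength(LONE) == 0.0)

    def test_lone_switch_over_single_transition_is_one(self):
        g = P([[0, 1], [0, 0], [1, 1]])
        assert node_disjointedness(g)[0] == 1.0

    def test_no_switches_give_zero_matrix(self):
        assert cohesion_matrix(CONSTANT).sum() == 0.0

    def test_every_switch_classified_at_most_once(self):
        # disjoint + cohesive switch counts never exceed total switches
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = P(rng.integers(0, 4, size=(10, 5)))
            switches = (g.assignments[:, :-1] != g.assignments[:, 1:]).sum(1)
            lone = node_disjointedness(g) * 4
            # cohesive transition count per node: transitions with >=1 partner
            coh_transitions = np.zeros(10)
            from longnet.metrics import _moves_by_transition

            for _, groups in _moves_by_transition(g.assignments):
                for members in groups.values():
                    if len(members) >= 2:
                        coh_transitions[np.array(members)] += 1
            assert np.all(lone + coh_transitions <= switches + 1e-12)

    def test_zero_flexibility_implies_inactive_metrics(self):
        flex = node_flexibility(ONE_SWITCH)
        still = np.flatnonzero(flex == 0)
        assert np.all(node_cohesion_strength(ONE_SWITCH)[still] == 0)
        assert np.all(node_disjointedness(ONE_SWITCH)[still] == 0)
        k = ONE_SWITCH.n_communities
        assert np.all(node_promiscuity(ONE_SWITCH)[still] == 1 / k)


class TestAllegiance:
    def test_fraction_of_shared_layers(self):
        g = P([[0, 0, 0, 0], [0, 0, 0, 1]])
        a = allegiance(g)
        assert a[0, 1] == pytest.approx(0.75)
        assert np.all(np.diag(a) == 1.0)

    def test_constant_partition_gives_block_zero_one_matrix(self):
        a = allegiance(CONSTANT)
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        assert np.array_equal(a, expected)

    def test_pools_layers_and_reps(self):
        p1 = P([[0, 0], [0, 1]])  # together 1 of 2 layers
        p2 = P([[0, 0], [0, 0]])  # together 2 of 2 layers
        a = allegiance([p1, p2])
        assert a[0, 1] == pytest.approx(3 / 4)


class TestRecruitment:
    def test_all_ones_allegiance_gives_one(self):
        a = np.ones((4, 4))
        node, net, glob = recruitment(a, np.array(["S", "S", "T", "T"]))
        assert np.all(node == 1.0) and glob == 1.0

    def test_partition_equal_to_networks_gives_self_recruitment_one(self):
        names = np.array(["S"] * 3 + ["T"] * 2)
        g = P([[0, 0], [0, 0], [0, 0], [1, 1], [1, 1]])
        a = allegiance(g)
        node, per_net, glob = recruitment(a, names)
        assert np.all(node == 1.0)
        assert per_net["S"] == 1.0 and per_net["T"] == 1.0
        # no cross-network allegiance
        assert a[0, 3] == 0.0

    def test_pairwise_value_passes_through(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.5
        node, _, _ = recruitment(a, np.array(["S", "S", "T", "T"]))
        assert node[0] == pytest.approx(0.5)

    def test_singleton_network_flagged_missing(self):
        a = np.ones((3, 3))
        node, per_net, glob = recruitment(a, np.array(["S", "S", "solo"]))
        assert np.isnan(node[2])
        assert np.isnan(per_net["solo"])
        assert glob == pytest.approx(1.0)  # excluded from the mean


class TestSummarize:
    def _ensemble(self, partitions, Qs):
        params = ModularityParams()
        results = [
            ModularityResult(p, q, params, i, 0) for i, (p, q) in enumerate(zip(partitions, Qs))
        ]
        return OptimizationEnsemble(results)

    def test_two_reps_average_per_node(self):
        p1 = P([[0, 0, 0, 0], [0, 0, 0, 0]])  # flexibility 0
        p2 = P([[0, 0, 1, 1], [0, 0, 0, 0]])  # node 0 flexibility 1/3
        ens = self._ensemble([p1, p2], [0.3, 0.5])
        ms = summarize(ens, ["a", "b"], np.array(["S", "S"]))
        assert ms.per_node.loc["a", "flexibility"] == pytest.approx(1 / 6)
        assert ms.Q_mean == pytest.approx(0.4)
        assert ms.module_count_mean == pytest.approx(1.5)

    def test_network_and_global_means_recompute_from_nodes(self):
        rng = np.random.default_rng(9)
        parts = [P(rng.integers(0, 3, (6, 4))) for _ in range(3)]
        names = np.array(["S", "S", "S", "T", "T", "T"])
        ms = summarize(self._ensemble(parts, [0.1] * 3), labels(6), names)
        for m in ms.per_network.columns:
            col = ms.per_node[m].to_numpy()
            assert ms.per_network.loc["S", m] == pytest.approx(np.nanmean(col[:3]))
            assert ms.global_means[m] == pytest.approx(np.nanmean(col))

    def test_long_table_has_all_scopes(self):
        p = P([[0, 0], [0, 1]])
        ms = summarize(self._ensemble([p], [0.2]), ["a", "b"], np.array(["S", "S"]))
        tbl = metrics_long_table(ms, subject="sub1")
        assert set(tbl["scope"]) == {"node", "network", "global"}
        assert (tbl["subject"] == "sub1").all()
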