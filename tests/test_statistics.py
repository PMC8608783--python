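import numpy as np
import pytest

from ergmotif.model import EffectSpec, ModelSpec
from ergmotif.network import AttributeSet, Network
from ergmotif.statistics import (change_statistic, simple_count_statistic,
                                 statistic, statistics_vector)
from ergmotif.synthetic import (AttributePlan, assign_attributes, generate_er)

import oracles
from conftest import make_net

DIRECTED_EFFECTS = ["Arc", "Sink", "Source", "Reciprocity", "AltInStars",
                    "AltOutStars", "AltTwoPathsT", "AltKTrianglesT",
                    "AltKTrianglesC"]
UNDIRECTED_EFFECTS = ["Edge", "AS", "A2P", "AT"]


def _attrs_for(net, seed=0):
    plan = AttributePlan(binary={"b": 0.4}, categorical={"c": (3, 0.2)})
    return assign_attributes(net, plan, seed=seed)


class TestSimpleCounts:
    def test_path_has_one_sink_one_source(self):
        net = make_net([(0, 1), (1, 2)])
        assert simple_count_statistic(net, "sink") == 1
        assert simple_count_statistic(net, "source") == 1

    def test_mutual_dyad_reciprocity(self):
        net = make_net([(0, 1), (1, 0)])
        assert simple_count_statistic(net, "reciprocity") == 1

    def test_loop_count(self):
        net = make_net([(0, 0)], n=2, allow_loops=True)
        assert simple_count_statistic(net, "loop") == 1

    def test_loop_without_permission_warns_zero(self):
        net = make_net([(0, 1)])
        with pytest.warns(UserWarning):
            assert simple_count_statistic(net, "loop") == 0


class TestWorkedExamples:
    """The hand-derivable values of each statistic family."""

    def test_in_three_star(self):
        net = make_net([(1, 0), (2, 0), (3, 0)])
        assert statistic(net, EffectSpec("AltInStars")) == pytest.approx(2.5)

    def test_single_edge_no_stars(self):
        net = make_net([(0, 1)], directed=False)
        assert statistic(net, EffectSpec("AS")) == pytest.approx(0.0)

    def test_undirected_two_path_one_star(self):
        net = make_net([(0, 1), (1, 2)], directed=False)
        assert statistic(net, EffectSpec("AS")) == pytest.approx(1.0)
        assert statistic(net, EffectSpec("A2P")) == pytest.approx(1.0)

    def test_transitive_triad(self):
        net = make_net([(0, 1), (1, 2), (0, 2)])
        assert statistic(net, EffectSpec("AltTwoPathsT")) == pytest.approx(1.0)
        assert statistic(net, EffectSpec("AltKTrianglesT")) == pytest.approx(1.0)

    def test_directed_three_cycle(self):
        net = make_net([(0, 1), (1, 2), (2, 0)])
        assert statistic(net, EffectSpec("AltKTrianglesC")) == pytest.approx(3.0)

    def test_undirected_triangle(self):
        net = make_net([(0, 1), (1, 2), (0, 2)], directed=False)
        assert statistic(net, EffectSpec("AT")) == pytest.approx(3.0)

    def test_empty_network_all_zero(self):
        net = Network(5, directed=True)
        model = ModelSpec([EffectSpec(n) for n in DIRECTED_EFFECTS])
        assert statistics_vector(net, model).tolist() == [0.0] * len(DIRECTED_EFFECTS)


class TestAttributeStatistics:
    def test_sender_receiver_interaction(self):
        net = make_net([(0, 1), (0, 2)])
        attrs = AttributeSet()
        attrs.add_binary("a", [1, 0, 0])
        assert statistic(net, EffectSpec("Sender", attribute="a"), attrs) == 2
        assert statistic(net, EffectSpec("Receiver", attribute="a"), attrs) == 0
        assert statistic(net, EffectSpec("Interaction", attribute="a"), attrs) == 0

    def test_interaction_needs_both_endpoints(self):
        net = make_net([(0, 1)])
        attrs = AttributeSet()
        attrs.add_binary("a", [1, 1])
        assert statistic(net, EffectSpec("Interaction", attribute="a"), attrs) == 1

    def test_na_never_matches(self):
        net = make_net([(0, 1), (0, 2)], directed=False)
        attrs = AttributeSet()
        attrs.add_categorical("c", [0, 0, -1])
        assert statistic(net, EffectSpec("Match", attribute="c"), attrs) == 1
        # NA against NA is still no match
        attrs.add_categorical("c", [-1, -1, -1])
        assert statistic(net, EffectSpec("Match", attribute="c"), attrs) == 0

    def test_missing_attribute_errors(self):
        net = make_net([(0, 1)])
        with pytest.raises(ValueError, match="not found"):
            statistic(net, EffectSpec("Sender", attribute="zzz"), AttributeSet())

    def test_bounds_on_random_graphs(self, random_networks):
        for k, net in enumerate(n for n in random_networks if n.directed):
            attrs = _attrs_for(net, seed=k)
            arcs = net.n_ties
            sender = statistic(net, EffectSpec("Sender", attribute="b"), attrs)
            inter = statistic(net, EffectSpec("Interaction", attribute="b"), attrs)
            match = statistic(net, EffectSpec("Match", attribute="c"), attrs)
            assert 0 <= inter <= sender <= arcs
            assert 0 <= match <= arcs


class TestAlternatingOracles:
    """Closed forms equal explicit alternating sums."""

    @pytest.mark.parametrize("lam", [1.5, 2.0, 3.7])
    def test_random_graphs(self, lam, random_networks):
        for net in random_networks:
            if net.directed:
                pairs = [("AltInStars", oracles.alt_star_sum(net, "in", lam)),
                         ("AltOutStars", oracles.alt_star_sum(net, "out", lam)),
                         ("AltTwoPathsT", oracles.alt_twopath_sum(net, "T", lam)),
                         ("AltKTrianglesT", oracles.alt_triangle_sum(net, "T", lam)),
                         ("AltKTrianglesC", oracles.alt_triangle_sum(net, "C", lam))]
            else:
                pairs = [("AS", oracles.alt_star_sum(net, "und", lam)),
                         ("A2P", oracles.alt_twopath_sum(net, "A2P", lam)),
                         ("AT", oracles.alt_triangle_sum(net, "AT", lam))]
            for name, expected in pairs:
                got = statistic(net, EffectSpec(name, lam=lam))
                assert got == pytest.approx(expected, abs=1e-9), name

    def test_exhaustive_three_node_digraphs(self):
        for arcs in oracles.enumerate_three_node_digraphs():
            net = make_net(list(arcs), n=3)
            for name, oracle in [("AltInStars", oracles.alt_star_sum(net, "in", 2.0)),
                                 ("AltKTrianglesT", oracles.alt_triangle_sum(net, "T", 2.0)),
                                 ("AltKTrianglesC", oracles.alt_triangle_sum(net, "C", 2.0))]:
                assert statistic(net, EffectSpec(name)) == pytest.approx(oracle, abs=1e-9)


class TestChangeStatistics:
    def test_arc_change_is_one(self):
        net = make_net([(0, 1)], n=3)
        assert change_statistic(net, EffectSpec("Arc"), 1, 2) == 1.0

    def test_closing_a_path_adds_one_transitive_triangle(self):
        net = make_net([(0, 1), (1, 2)])
        assert change_statistic(net, EffectSpec("AltKTrianglesT"), 0, 2) == \
            pytest.approx(1.0)

    def test_loop_dyad_touches_only_loop_effect(self):
        net = make_net([(0, 1)], n=3, allow_loops=True)
        assert change_statistic(net, EffectSpec("Loop"), 2, 2) == 1.0
        assert change_statistic(net, EffectSpec("AltKTrianglesT"), 2, 2) == 0.0

    def test_equals_full_recount_on_random_toggles(self, random_networks):
        rng = np.random.default_rng(3)
        for net in random_networks:
            names = DIRECTED_EFFECTS if net.directed else UNDIRECTED_EFFECTS
            attrs = _attrs_for(net)
            names = names + (["Sender", "Receiver", "Interaction", "Match"]
                             if net.directed else ["Match"])
            for _ in range(8):
                i, j = rng.integers(0, net.n_nodes, size=2)
                if i == j:
                    continue
                i, j = int(i), int(j)
                if not net.directed and i > j:
                    i, j = j, i
                for name in names:
                    attr = ("c" if name == "Match" else
                            "b" if name in ("Sender", "Receiver", "Interaction")
                            else None)
                    eff = EffectSpec(name, attribute=attr)
                    delta = change_statistic(net, eff, i, j, attrs)
                    plus, minus = net.copy(), net.copy()
                    if not plus.has_edge(i, j):
                        plus.add_edge(i, j)
                    if minus.has_edge(i, j):
                        minus.remove_edge(i, j)
                    full = statistic(plus, eff, attrs) - statistic(minus, eff, attrs)
                    assert delta == pytest.approx(full, abs=1e-9), name


class TestInvariances:
    def test_statistics_invariant_under_relabeling(self, random_networks):
        rng = np.random.default_rng(5)
        for net in random_networks[:10]:
            perm = rng.permutation(net.n_nodes)
            relabeled = Network(net.n_nodes, net.directed)
            for i, j in net.edge_set():
                relabeled.add_edge(int(perm[i]), int(perm[j]))
            names = DIRECTED_EFFECTS if net.directed else UNDIRECTED_EFFECTS
            for name in names:
                a = statistic(net, EffectSpec(name))
                b = statistic(relabeled, EffectSpec(name))
                assert a == pytest.approx(b, abs=1e-9)

    def test_vector_matches_individual_statistics(self, random_networks):
        for net in random_networks[:6]:
            names = DIRECTED_EFFECTS if net.directed else UNDIRECTED_EFFECTS
            model = ModelSpec([EffectSpec(n) for n in names])
            vec = statistics_vector(net, model)
            for k, name in enumerate(names):
                assert vec[k] == pytest.approx(statistic(net, EffectSpec(name)))

    def test_loops_touch_only_the_loop_statistic(self):
        base = make_net([(0, 1), (1, 2), (0, 2)], n=4)
        with_loop = make_net([(0, 1), (1, 2), (0, 2), (3, 3)], n=4,
                             allow_loops=True)
        for name in DIRECTED_EFFECTS:
            assert statistic(base, EffectSpec(name)) == \
                pytest.approx(statistic(with_loop, EffectSpec(name)))
        assert simple_count_statistic(with_loop, "loop") == 1
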