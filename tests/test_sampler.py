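import math

import numpy as np
import pytest
from scipy import stats as sps

from ergmotif.model import EffectSpec, ModelSpec
from ergmotif.network import Network
from ergmotif.sampler import Chain, Ensemble, SamplerSettings, simulate_ensemble
from ergmotif.statistics import statistics_vector
from ergmotif.synthetic import generate_er

from conftest import make_net


def _chain(net, model, theta, seed=0, proposal="toggle"):
    return Chain(net, model, np.asarray(theta, dtype=float),
                 np.random.default_rng(seed), proposal=proposal)


class TestSettings:
    def test_validation(self):
        with pytest.raises(ValueError):
            SamplerSettings(burnin=-1)
        with pytest.raises(ValueError):
            SamplerSettings(interval=0)
        with pytest.raises(ValueError):
            SamplerSettings(proposal="gibbs")

    def test_defaults_scale_with_dyads(self):
        s = SamplerSettings()
        assert s.resolved_burnin(90) == 900
        assert s.resolved_interval(90) == 90


class TestToggleChain:
    def test_zero_theta_accepts_every_legal_proposal(self):
        net = generate_er(12, p=0.3, directed=True, seed=0)
        chain = _chain(net, ModelSpec([EffectSpec("Arc")]), [0.0])
        assert chain.run(500) == 500

    def test_incremental_statistics_track_full_recount(self):
        net = generate_er(15, p=0.2, directed=True, seed=1)
        model = ModelSpec([EffectSpec("Arc"), EffectSpec("AltKTrianglesT"),
                           EffectSpec("AltInStars")])
        chain = _chain(net, model, [-1.0, 0.3, 0.1], seed=2)
        chain.run(5000)
        assert np.allclose(chain.z, statistics_vector(chain.state, model),
                           atol=1e-9)

    def test_arc_only_stationary_density_is_logistic(self):
        theta = -1.2
        p_target = 1.0 / (1.0 + math.exp(-theta))
        net = generate_er(15, p=p_target, directed=True, seed=3)
        chain = _chain(net, ModelSpec([EffectSpec("Arc")]), [theta], seed=4)
        n_dyads = chain.n_dyads
        chain.run(10 * n_dyads)
        stats, _ = chain.sample(200, n_dyads)
        mean_m = stats[:, 0].mean()
        # independent dyads: m ~ Binomial(n_dyads, p); allow 3 MC SEs of
        # the autocorrelated sample mean
        exp_m = n_dyads * p_target
        sd = math.sqrt(n_dyads * p_target * (1 - p_target))
        assert abs(mean_m - exp_m) < 3 * sd / math.sqrt(200 / 4)

    def test_loops_never_proposed_when_forbidden(self):
        net = generate_er(10, p=0.3, directed=True, seed=5)
        chain = _chain(net, ModelSpec([EffectSpec("Arc")]), [0.0], seed=6)
        chain.run(3000)
        assert not chain.state.loops

    def test_loop_model_visits_loops(self):
        net = Network(6, directed=True, allow_loops=True)
        net.add_edge(0, 1)
        model = ModelSpec([EffectSpec("Arc"), EffectSpec("Loop")],
                          allow_loops=True)
        chain = _chain(net, model, [0.0, 0.0], seed=7)
        chain.run(2000)
        stats, _ = chain.sample(50, 50)
        assert stats[:, 1].max() > 0  # loop statistic moves


class TestConstraints:
    def test_forbid_reciprocity_never_creates_mutual_dyads(self):
        net = generate_er(12, p=0.2, directed=True, seed=8)
        for i, j in list(net.edge_set()):
            if net.has_edge(j, i) and net.has_edge(i, j):
                net.remove_edge(i, j)
        model = ModelSpec([EffectSpec("Arc"), EffectSpec("Reciprocity")],
                          forbid_reciprocity=True)
        chain = _chain(net, model, [0.5, 2.0], seed=9)
        for _ in range(60):
            chain.run(100)
            st = chain.state
            mutual = sum(1 for a in range(st.n_nodes) for b in st._out[a]
                         if b > a and a in st._out[b])
            assert mutual == 0

    def test_fixed_density_conserves_edge_count_every_step(self):
        net = generate_er(12, p=0.25, directed=True, seed=10)
        m0 = net.n_ties
        chain = _chain(net, ModelSpec([EffectSpec("Arc"),
                                       EffectSpec("AltKTrianglesT")]),
                       [0.0, 0.5], seed=11, proposal="fixed_density_swap")
        for _ in range(2000):
            chain.run(1)
            assert chain.state.n_ties == m0

    def test_swap_needs_nonempty_and_nonfull(self):
        empty = Network(5, directed=True)
        with pytest.raises(ValueError, match="at least one tie"):
            _chain(empty, ModelSpec([EffectSpec("Arc")]), [0.0],
                   proposal="fixed_density_swap")

    def test_swap_delta_matches_full_recount(self):
        net = generate_er(10, p=0.3, directed=True, seed=12)
        model = ModelSpec([EffectSpec("Arc"), EffectSpec("AltKTrianglesT")])
        chain = _chain(net, model, [0.0, 0.2], seed=13,
                       proposal="fixed_density_swap")
        chain.run(3000)
        assert np.allclose(chain.z, statistics_vector(chain.state, model),
                           atol=1e-9)


class TestExactness:
    def test_toggle_chain_matches_enumerated_distribution(self):
        """Empirical visit frequencies on the 64 three-node digraphs
        match the exact model probabilities (chi-square)."""
        import oracles

        theta = np.array([0.4, 0.6])
        model = ModelSpec([EffectSpec("Arc"), EffectSpec("Reciprocity")])
        # exact probabilities by enumeration
        weights = {}
        for arcs in oracles.enumerate_three_node_digraphs():
            net = make_net(list(arcs), n=3)
            z = statistics_vector(net, model)
            weights[frozenset(arcs)] = math.exp(float(theta @ z))
        total = sum(weights.values())
        start = Network(3, directed=True)
        chain = _chain(start, model, theta, seed=14)
        chain.run(2000)
        counts = dict.fromkeys(weights, 0)
        n_samples = 6000
        for _ in range(n_samples):
            chain.run(25)
            counts[frozenset(chain.state.edge_set())] += 1
        observed = np.array(list(counts.values()))
        expected = np.array([weights[k] / total for k in counts]) * n_samples
        stat, p = sps.chisquare(observed, expected)
        assert p > 0.01

    def test_identical_seeds_identical_ensembles(self):
        model = ModelSpec([EffectSpec("Arc")])
        kwargs = dict(n_nodes=15, init=0.3, n_samples=10,
                      settings=SamplerSettings(seed=99, burnin=500, interval=50))
        a = simulate_ensemble(model, [-1.0], **kwargs)
        b = simulate_ensemble(model, [-1.0], **kwargs)
        assert np.array_equal(a.statistics, b.statistics)


class TestSimulateEnsemble:
    def test_fixed_density_samples_all_conserve_edges(self):
        net = generate_er(12, p=0.2, directed=True, seed=15)
        model = ModelSpec([EffectSpec("Arc")], fixed_density=True)
        ens = simulate_ensemble(model, [0.0], init=net, n_samples=20,
                                settings=SamplerSettings(
                                    seed=1, burnin=500, interval=100,
                                    proposal="fixed_density_swap"),
                                keep_networks=True)
        assert all(s.n_ties == net.n_ties for s in ens.networks)

    def test_zero_theta_mean_arc_count_is_half_dyads(self):
        model = ModelSpec([EffectSpec("Arc")])
        ens = simulate_ensemble(model, [0.0], n_nodes=20, init=0.5,
                                n_samples=60,
                                settings=SamplerSettings(seed=2))
        d = 20 * 19
        sd = math.sqrt(d * 0.25)
        assert abs(ens.statistics[:, 0].mean() - d / 2) < 3 * sd / math.sqrt(60 / 4)

    def test_forbid_reciprocity_samples_have_zero_reciprocity(self):
        net = generate_er(12, p=0.1, directed=True, seed=16)
        for i, j in list(net.edge_set()):
            if i < j and net.has_edge(j, i) and net.has_edge(i, j):
                net.remove_edge(i, j)
        model = ModelSpec([EffectSpec("Arc"), EffectSpec("Reciprocity")],
                          forbid_reciprocity=True)
        ens = simulate_ensemble(model, [0.0, 1.0], init=net, n_samples=20,
                                settings=SamplerSettings(seed=3, burnin=2000,
                                                         interval=200))
        assert (ens.statistics[:, 1] == 0).all()

    def test_ensemble_frame_has_effect_labels(self):
        model = ModelSpec([EffectSpec("Arc"), EffectSpec("AltInStars")])
        ens = simulate_ensemble(model, [0.0, 0.0], n_nodes=8, init=0.2,
                                n_samples=5,
                                settings=SamplerSettings(seed=4, burnin=100,
                                                         interval=20))
        assert list(ens.to_frame().columns) == ["Arc", "AltInStars"]
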