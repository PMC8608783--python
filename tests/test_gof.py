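import numpy as np
import pytest

from ergmotif.gof import (GofVector, enumerate_lambda_grid, gof_report,
                          gof_summary_vector, lambda_grid_search,
                          mahalanobis_distance, plot_gof, summary_statistics)
from ergmotif.model import EffectSpec, ModelSpec
from ergmotif.network import Network
from ergmotif.synthetic import generate_er

from conftest import make_net


class TestSummaryStatistics:
    def test_undirected_triangle_clusters_perfectly(self):
        net = make_net([(0, 1), (1, 2), (0, 2)], directed=False)
        gv = summary_statistics(net)
        assert gv.global_clustering == pytest.approx(1.0)
        assert gv.mean_local_clustering == pytest.approx(1.0)
        assert gv.giant_component == 3

    def test_two_disjoint_arcs_weak_component(self):
        net = make_net([(0, 1), (2, 3)])
        assert summary_statistics(net).giant_component == 2

    def test_directed_path_geodesics(self):
        net = make_net([(0, 1), (1, 2)])
        gv = summary_statistics(net)
        # ordered reachable pairs: two at distance 1, one at distance 2,
        # remaining ordered pairs unreachable
        assert gv.geodesic_hist[1] == 2
        assert gv.geodesic_hist[2] == 1
        assert gv.geodesic_hist[-1] == 3 * 2 - 3

    def test_histogram_mass_conservation(self, random_networks):
        for net in random_networks:
            gv = summary_statistics(net)
            n = net.n_nodes
            if net.directed:
                assert gv.in_degree_hist.sum() == n
                assert gv.out_degree_hist.sum() == n
                assert gv.geodesic_hist.sum() == n * (n - 1)
                assert gv.esp_hist.sum() == net.n_ties
                assert gv.dsp_hist.sum() == n * (n - 1)
                assert sum(gv.triad_census.values()) == n * (n - 1) * (n - 2) // 6
            else:
                assert gv.degree_hist.sum() == n
                assert gv.geodesic_hist.sum() == n * (n - 1) // 2
                assert gv.esp_hist.sum() == net.n_ties
                assert gv.dsp_hist.sum() == n * (n - 1) // 2

    def test_census_agrees_with_motifs_module(self):
        from ergmotif.motifs import triad_census

        net = generate_er(25, p=0.15, directed=True, seed=1)
        assert summary_statistics(net).triad_census == triad_census(net).counts


class TestGofReport:
    def _vectors(self, seed=0, n=12, k=20):
        rng = np.random.default_rng(seed)
        obs = summary_statistics(generate_er(n, p=0.3, directed=True, seed=1))
        sims = [summary_statistics(generate_er(n, p=0.3, directed=True,
                                               seed=int(rng.integers(2 ** 31))))
                for _ in range(k)]
        return obs, sims

    def test_report_covers_every_statistic_family(self):
        obs, sims = self._vectors()
        rep = gof_report(obs, sims)
        assert set(rep.scalars) == {"reciprocity", "giant_component",
                                    "global_clustering", "mean_local_clustering"}
        assert {"geodesic", "esp", "dsp", "in_degree", "out_degree",
                "triad_census"} <= set(rep.histograms)

    def test_observed_equal_to_mean_gives_zero_t(self):
        obs, sims = self._vectors()
        recip = float(np.mean([g.reciprocity for g in sims]))
        obs.reciprocity = recip
        rep = gof_report(obs, sims)
        assert rep.scalars["reciprocity"]["t_ratio"] == pytest.approx(0.0)

    def test_zero_variance_statistic_flagged_but_report_produced(self):
        obs, sims = self._vectors()
        for g in sims:
            g.reciprocity = 5
        obs.reciprocity = 4
        rep = gof_report(obs, sims)
        assert np.isnan(rep.scalars["reciprocity"]["t_ratio"])

    def test_small_ensemble_rejected(self):
        obs, sims = self._vectors()
        with pytest.raises(ValueError, match="at least 2"):
            gof_report(obs, sims[:1])

    def test_plots_written(self, tmp_path):
        obs, sims = self._vectors()
        paths = plot_gof(gof_report(obs, sims), tmp_path)
        assert all(p.exists() for p in paths)
        assert len(paths) >= 5


class TestMahalanobis:
    def test_zero_at_ensemble_mean(self, rng):
        mat = rng.normal(size=(50, 4))
        assert mahalanobis_distance(mat.mean(axis=0), mat) == pytest.approx(0.0)

    def test_identity_covariance_equals_euclidean(self, rng):
        # standardized coordinates with (near) identity sample covariance
        mat = rng.normal(size=(4000, 3))
        mat = (mat - mat.mean(0)) / mat.std(0, ddof=1)
        obs = mat.mean(axis=0) + np.array([3.0, 0.0, 4.0])
        d = mahalanobis_distance(obs, mat)
        assert d == pytest.approx(5.0, rel=0.05)

    def test_singular_covariance_matches_brute_force_pinv(self, rng):
        base = rng.normal(size=(30, 2))
        mat = np.column_stack([base, base[:, 0]])  # duplicated column
        obs = np.array([1.0, -0.5, 1.0])
        diff = obs - mat.mean(axis=0)
        expected = np.sqrt(diff @ np.linalg.pinv(np.cov(mat, rowvar=False)) @ diff)
        assert mahalanobis_distance(obs, mat) == pytest.approx(expected)

    def test_affine_rescaling_invariance(self, rng):
        mat = rng.normal(size=(200, 3))
        obs = rng.normal(size=3)
        scale = np.array([2.0, 0.5, 10.0])
        d1 = mahalanobis_distance(obs, mat)
        d2 = mahalanobis_distance(obs * scale, mat * scale)
        assert d1 == pytest.approx(d2, rel=1e-6)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            mahalanobis_distance(np.zeros(3), rng.normal(size=(10, 4)))


class TestLambdaGrid:
    def _template(self):
        return ModelSpec([EffectSpec("Arc"), EffectSpec("AltInStars"),
                          EffectSpec("AltOutStars"), EffectSpec("AltTwoPathsT"),
                          EffectSpec("AltKTrianglesT")])

    def test_two_tied_dimensions_give_64_models(self):
        values = [1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0]
        groups = [(["AltOutStars"], values),
                  (["AltTwoPathsT", "AltKTrianglesT"], values)]
        models = enumerate_lambda_grid(self._template(), groups)
        assert len(models) == 64
        # tied decays really are tied within each candidate
        for m in models:
            lams = {e.name: e.lam for e in m.effects if e.alternating}
            assert lams["AltTwoPathsT"] == lams["AltKTrianglesT"]

    def test_single_point_grid(self):
        models = enumerate_lambda_grid(self._template(),
                                       [(["AltOutStars"], [3.0])])
        assert len(models) == 1
        assert dict((e.name, e.lam) for e in models[0].effects)["AltOutStars"] == 3.0

    def test_unknown_effect_rejected(self):
        with pytest.raises(ValueError, match="not in model"):
            enumerate_lambda_grid(self._template(), [(["AT"], [2.0])])

    def test_search_ranks_ascending_with_failures_recorded(self):
        from ergmotif.estimation import EstimationSettings
        from ergmotif.sampler import SamplerSettings

        net = generate_er(30, m=60, directed=True, seed=5)
        template = ModelSpec([EffectSpec("Arc"), EffectSpec("AltKTrianglesT")])
        settings = EstimationSettings(n_runs=1, n_phases=2,
                                      updates_per_phase=10, servo_updates=80,
                                      se_samples=30, polish_rounds=1, seed=1)
        points = lambda_grid_search(net, template,
                                    [(["AltKTrianglesT"], [2.0, 3.0])],
                                    settings, n_samples=8,
                                    sampler_settings=SamplerSettings(
                                        burnin=500, interval=200),
                                    seed=2)
        assert len(points) == 2
        ok = sorted((p for p in points if not p.failed),
                    key=lambda p: p.rank)
        assert [p.rank for p in ok] == list(range(1, len(ok) + 1))
        assert all(a.distance <= b.distance for a, b in zip(ok, ok[1:]))

    def test_summary_vector_layout(self):
        net = generate_er(20, p=0.2, directed=True, seed=0)
        vec = gof_summary_vector(summary_statistics(net))
        assert vec.shape == (8,)  # 2x degree moments + 4 scalars
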