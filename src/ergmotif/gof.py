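"""Simulation-based goodness-of-fit and the Mahalanobis λ grid search.

A fitted model is judged by simulating an ensemble of networks at the
estimated parameters and overlaying the observed network's summary
statistics on the simulated distributions: degree distributions,
reciprocity, giant (weakly) connected component size, global and mean
local clustering, geodesic distances, edge-wise and dyad-wise shared
partners, and (for directed networks) the triad census.

The decay parameters λ of the alternating statistics can be chosen by
grid search: each candidate model is fitted, simulated, and scored by
the Mahalanobis distance between the observed summary vector and the
simulated ensemble's, smaller being better.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats as sps

from .estimation import EstimationSettings, estimate
from .model import ModelSpec
from .network import AttributeSet, Network
from .sampler import Ensemble, SamplerSettings, simulate_ensemble
from .statistics import statistics_vector

__all__ = ["GofVector", "GofReport", "summary_statistics", "gof_report",
           "mahalanobis_distance", "gof_summary_vector",
           "enumerate_lambda_grid", "lambda_grid_search", "GridPoint"]


@dataclass
class GofVector:
    """Summary statistics of one network, as used in fit assessment.

    Histograms conserve mass: degree histograms sum to n, the geodesic
    histogram (with its infinite bin) to the number of ordered (or
    unordered) node pairs, the edge-wise shared-partner histogram to the
    tie count, the dyad-wise one to the dyad count, and the triad census
    to C(n,3).
    """

    directed: bool
    n_nodes: int
    reciprocity: int
    giant_component: int
    global_clustering: float
    mean_local_clustering: float
    in_degree_hist: np.ndarray | None
    out_degree_hist: np.ndarray | None
    degree_hist: np.ndarray | None
    geodesic_hist: np.ndarray   # index = distance, last bin = unreachable
    esp_hist: np.ndarray        # edge-wise shared partners
    dsp_hist: np.ndarray        # dyad-wise shared partners
    triad_census: dict[str, int] | None

    def scalars(self) -> dict[str, float]:
        return {
            "reciprocity": float(self.reciprocity),
            "giant_component": float(self.giant_component),
            "global_clustering": self.global_clustering,
            "mean_local_clustering": self.mean_local_clustering,
        }


def _hist(values, length=None) -> np.ndarray:
    values = np.asarray(values, dtype=np.int64)
    n = int(values.max()) + 1 if values.size else 1
    if length is not None:
        n = max(n, length)
    h = np.zeros(n, dtype=np.int64)
    np.add.at(h, values, 1)
    return h


def _shared_partner_hists(net: Network):
    """ESP / DSP histograms.

    Directed networks use the transitive convention: the shared partners
    of an ordered pair (i, j) are the intermediaries k with i->k->j,
    matching the two-path and transitive-triangle model statistics.
    Dyad-wise runs over all ordered (directed) or unordered (undirected)
    pairs; edge-wise over tied pairs only.
    """
    a = net.to_numpy()
    np.fill_diagonal(a, False)
    ai = a.astype(np.int32)
    if net.directed:
        tp = ai @ ai  # tp[i, j] = #{k: i->k->j}
        off = ~np.eye(net.n_nodes, dtype=bool)
        dsp = tp[off]
        esp = tp[a]
    else:
        tp = ai @ ai
        iu = np.triu_indices(net.n_nodes, k=1)
        dsp = tp[iu]
        esp = tp[iu][a[iu]]
    return _hist(esp), _hist(dsp)


def summary_statistics(net: Network) -> GofVector:
    """Compute the full summary vector of one simplified network.

    Clustering coefficients of a directed network are computed on its
    underlying undirected simple graph; geodesics use directed paths,
    with unreachable pairs in a separate final bin; the giant component
    of a directed network is the largest weakly connected one.
    """
    g = net.to_networkx()
    g.remove_edges_from(nx.selfloop_edges(g))
    und = g.to_undirected() if net.directed else g
    n = net.n_nodes

    if n >= 1:
        comps = (nx.weakly_connected_components(g) if net.directed
                 else nx.connected_components(g))
        giant = max((len(c) for c in comps), default=0)
    else:
        giant = 0
    global_c = nx.transitivity(und) if n >= 3 else 0.0
    mean_c = nx.average_clustering(und) if n >= 1 else 0.0

    # geodesic histogram over ordered (directed) / unordered pairs
    n_pairs = n * (n - 1) if net.directed else n * (n - 1) // 2
    lengths = []
    for src, dd in nx.all_pairs_shortest_path_length(g):
        for dst, d in dd.items():
            if dst == src:
                continue
            if net.directed or dst > src:
                lengths.append(d)
    finite = _hist(lengths) if lengths else np.zeros(1, dtype=np.int64)
    geodesic = np.append(finite, n_pairs - len(lengths))

    esp, dsp = _shared_partner_hists(net)

    if net.directed:
        from .motifs import triad_census

        reciprocity = sum(1 for i in range(n) for j in net._out[i]
                          if j > i and i in net._out[j])
        census = triad_census(net).counts
        return GofVector(True, n, reciprocity, giant, global_c, mean_c,
                         _hist(net.in_degrees()), _hist(net.out_degrees()),
                         None, geodesic, esp, dsp, census)
    return GofVector(False, n, 0, giant, global_c, mean_c, None, None,
                     _hist(net.degrees()), geodesic, esp, dsp, None)


# ---------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------

_QUANTS = (0.0, 0.025, 0.5, 0.975, 1.0)


@dataclass
class GofReport:
    """Observed-vs-ensemble comparison for every statistic family.

    ``scalars`` maps a statistic name to observed value, ensemble
    quantiles (min, 2.5%, median, 97.5%, max) and t-ratio (NaN when the
    ensemble is degenerate).  ``histograms`` maps a family name to
    per-bin observed counts and quantile rows.
    """

    n_ensemble: int
    scalars: dict[str, dict]
    histograms: dict[str, dict]

    def to_json_dict(self) -> dict:
        out = {"n_ensemble": self.n_ensemble, "scalars": {}, "histograms": {}}
        for name, e in self.scalars.items():
            out["scalars"][name] = {
                "observed": e["observed"],
                "quantiles": list(map(float, e["quantiles"])),
                "t_ratio": None if np.isnan(e["t_ratio"]) else e["t_ratio"],
            }
        for name, e in self.histograms.items():
            out["histograms"][name] = {
                "observed": [int(v) for v in e["observed"]],
                "median": list(map(float, e["quantiles"][2])),
            }
        return out


def _pad(hists: list[np.ndarray]) -> np.ndarray:
    width = max(h.shape[0] for h in hists)
    return np.vstack([np.pad(h, (0, width - h.shape[0])) for h in hists])


def gof_report(observed: GofVector, ensemble: list[GofVector]) -> GofReport:
    """Build the fit report from one observed and >= 2 simulated vectors."""
    if len(ensemble) < 2:
        raise ValueError("goodness-of-fit needs an ensemble of at least 2")
    scalars: dict[str, dict] = {}
    obs_scalars = observed.scalars()
    for name in obs_scalars:
        sims = np.array([g.scalars()[name] for g in ensemble])
        sd = sims.std(ddof=1)
        t = (sims.mean() - obs_scalars[name]) / sd if sd > 0 else float("nan")
        scalars[name] = {
            "observed": obs_scalars[name],
            "quantiles": np.quantile(sims, _QUANTS),
            "t_ratio": float(t),
        }

    histograms: dict[str, dict] = {}
    fams = [("geodesic", "geodesic_hist"), ("esp", "esp_hist"),
            ("dsp", "dsp_hist")]
    if observed.directed:
        fams += [("in_degree", "in_degree_hist"), ("out_degree", "out_degree_hist")]
    else:
        fams += [("degree", "degree_hist")]
    for fam, attr in fams:
        rows = _pad([getattr(observed, attr)] +
                    [getattr(g, attr) for g in ensemble])
        obs_h, sim_h = rows[0], rows[1:]
        histograms[fam] = {
            "observed": obs_h,
            "quantiles": np.quantile(sim_h, _QUANTS, axis=0),
        }
    if observed.directed and observed.triad_census is not None:
        from .motifs import TRIAD_LABELS

        obs_h = np.array([observed.triad_census[l] for l in TRIAD_LABELS])
        sim_h = np.array([[g.triad_census[l] for l in TRIAD_LABELS]
                          for g in ensemble])
        histograms["triad_census"] = {
            "observed": obs_h,
            "quantiles": np.quantile(sim_h, _QUANTS, axis=0),
            "labels": list(TRIAD_LABELS),
        }
    return GofReport(len(ensemble), scalars, histograms)


def plot_gof(report: GofReport, outdir) -> list:
    """Write one boxplot-style panel per statistic family; returns paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(report.scalars)
    obs = [report.scalars[n]["observed"] for n in names]
    qs = np.array([report.scalars[n]["quantiles"] for n in names])
    ax.errorbar(range(len(names)), qs[:, 2],
                yerr=[qs[:, 2] - qs[:, 1], qs[:, 3] - qs[:, 2]],
                fmt="ks", capsize=3, label="simulated (2.5-97.5%)")
    ax.plot(range(len(names)), obs, "rD", label="observed")
    ax.set_xticks(range(len(names)), names, rotation=30, ha="right")
    ax.legend()
    fig.tight_layout()
    p = outdir / "gof_scalars.png"
    fig.savefig(p)
    plt.close(fig)
    paths.append(p)
    for fam, e in report.histograms.items():
        fig, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(len(e["observed"]))
        q = e["quantiles"]
        ax.fill_between(x, q[1], q[3], color="0.8", label="simulated 2.5-97.5%")
        ax.plot(x, q[2], "k-", label="simulated median")
        ax.plot(x, e["observed"], "r-o", ms=3, label="observed")
        if "labels" in e:
            ax.set_xticks(x, e["labels"], rotation=60)
        ax.set_xlabel(fam)
        ax.legend()
        fig.tight_layout()
        p = outdir / f"gof_{fam}.png"
        fig.savefig(p)
        plt.close(fig)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------
# Mahalanobis distance and λ grid search
# ---------------------------------------------------------------------

def mahalanobis_distance(observed, ensemble_matrix) -> float:
    """Distance of one vector from an ensemble under its sample covariance.

    The pseudo-inverse handles singular covariances (e.g. a statistic
    held constant by a sampling constraint).
    """
    obs = np.asarray(observed, dtype=float)
    mat = np.asarray(ensemble_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("ensemble matrix needs at least 2 rows")
    if mat.shape[1] != obs.shape[0]:
        raise ValueError("dimension mismatch between observed and ensemble")
    diff = obs - mat.mean(axis=0)
    cov = np.cov(mat, rowvar=False).reshape(obs.shape[0], obs.shape[0])
    d2 = float(diff @ np.linalg.pinv(cov) @ diff)
    return float(np.sqrt(max(d2, 0.0)))


def gof_summary_vector(gv: GofVector) -> np.ndarray:
    """The summary vector the λ grid search scores.

    Degree distributions enter as standard deviation and skewness of
    the in- and out-degree (or degree) sequences — their means being
    pinned by density — alongside reciprocity, giant component size,
    and the two clustering coefficients.
    """
    def moments(hist):
        degs = np.repeat(np.arange(len(hist)), hist)
        return [float(degs.std()), float(sps.skew(degs)) if degs.size > 2 else 0.0]

    if gv.directed:
        vec = moments(gv.in_degree_hist) + moments(gv.out_degree_hist)
    else:
        vec = moments(gv.degree_hist)
    vec += [float(gv.reciprocity), float(gv.giant_component),
            gv.global_clustering, gv.mean_local_clustering]
    return np.asarray(vec)


def enumerate_lambda_grid(model_template: ModelSpec,
                          groups: list[tuple[list[str], list[float]]]
                          ) -> list[ModelSpec]:
    """All candidate models from per-group λ value lists.

    Each group ties one λ value to a set of alternating effects (the
    two-path and triangle decays are conventionally tied).  Two groups
    over {1.5, 2.0, ..., 5.0} yield the classic 64-model grid.
    """
    names = {e.name for e in model_template.effects}
    for effs, _ in groups:
        for name in effs:
            if name not in names:
                raise ValueError(f"grid effect {name!r} not in model")
    models = []
    for combo in itertools.product(*(vals for _, vals in groups)):
        lam_by_effect = {}
        for (effs, _), lam in zip(groups, combo):
            for name in effs:
                lam_by_effect[name] = lam
        models.append(model_template.with_lambdas(lam_by_effect))
    return models


@dataclass
class GridPoint:
    model: ModelSpec
    lambdas: dict[str, float]
    distance: float | None
    rank: int | None
    failed: bool = False
    error: str | None = None


def lambda_grid_search(net: Network, model_template: ModelSpec,
                       groups: list[tuple[list[str], list[float]]],
                       est_settings: EstimationSettings | None = None,
                       n_samples: int = 100,
                       sampler_settings: SamplerSettings | None = None,
                       attrs: AttributeSet | None = None,
                       seed: int | None = None) -> list[GridPoint]:
    """Fit every grid model and rank by Mahalanobis fit distance.

    Each candidate is re-estimated in full, an ensemble is simulated at
    its pooled estimate, and the observed summary vector is scored
    against the simulated ones.  Failed estimations are recorded and
    excluded from the ranking; ties in distance keep grid order.
    """
    est_settings = est_settings or EstimationSettings()
    rng = np.random.default_rng(seed)
    obs_vec = gof_summary_vector(summary_statistics(net))
    points = []
    for model in enumerate_lambda_grid(model_template, groups):
        lambdas = {e.name: e.lam for e in model.effects if e.alternating}
        try:
            import dataclasses

            st = dataclasses.replace(est_settings,
                                     seed=int(rng.integers(2 ** 31)))
            estimates, _ = estimate(net, model, st, attrs)
            theta = np.array([e.theta for e in estimates])
            ss = sampler_settings or SamplerSettings()
            ss = dataclasses.replace(ss, seed=int(rng.integers(2 ** 31)))
            ens = simulate_ensemble(model, theta, init=net,
                                    n_samples=n_samples, settings=ss,
                                    attrs=attrs, keep_networks=True)
            sim_vecs = np.array([gof_summary_vector(summary_statistics(s))
                                 for s in ens.networks])
            dist = mahalanobis_distance(obs_vec, sim_vecs)
            points.append(GridPoint(model, lambdas, dist, None))
        except Exception as exc:  # estimation failure is data, not a crash
            points.append(GridPoint(model, lambdas, None, None,
                                    failed=True, error=str(exc)))
    ok = [p for p in points if not p.failed]
    for rank, p in enumerate(sorted(ok, key=lambda p: p.distance), start=1):
        p.rank = rank
    return points
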