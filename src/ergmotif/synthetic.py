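"""Synthetic networks and attributes emulating the study systems.

Real regulatory and protein-interaction networks are sparse (densities
a few per thousand), with skewed in- or out-degree, substantial
transitive closure, essentially no reciprocated arcs in the regulatory
case, and node classes (functional categories, subcellular locations)
that carry homophily.  The generators here reproduce those regimes at
reduced size (defaults around 100-500 nodes) so that estimation,
goodness-of-fit and motif tests exercise the same structure the real
analyses face, in seconds rather than cluster-minutes.

Everything is reproducible by seed; the preset helpers serialize their
generating model alongside the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import EffectSpec, ModelSpec
from .network import AttributeSet, Network

__all__ = ["AttributePlan", "generate_er", "generate_from_model",
           "assign_attributes", "plant_bifans",
           "regulatory_like_model", "ppi_like_model"]


def _pair_from_index(idx: int, n: int, directed: bool) -> tuple[int, int]:
    if directed:
        i, r = divmod(idx, n - 1)
        return (i, r if r < i else r + 1)
    import math

    i = int((1 + math.isqrt(1 + 8 * idx)) // 2)
    return (idx - i * (i - 1) // 2, i)


def generate_er(n: int, m: int | None = None, p: float | None = None,
                directed: bool = True, seed: int | None = None,
                allow_loops: bool = False) -> Network:
    """Uniform random simple graph with exactly ``m`` ties or tie
    probability ``p`` (loops never generated).

    With ``m`` given, dyads are drawn without replacement by rejection,
    which stays cheap at the low densities of interest.
    """
    if (m is None) == (p is None):
        raise ValueError("give exactly one of m and p")
    rng = np.random.default_rng(seed)
    n_dyads = n * (n - 1) if directed else n * (n - 1) // 2
    net = Network(n, directed=directed, allow_loops=allow_loops)
    if m is not None:
        if m > n_dyads:
            raise ValueError(f"m={m} exceeds dyad count {n_dyads}")
        chosen: set[int] = set()
        while len(chosen) < m:
            draw = rng.integers(0, n_dyads, size=max(64, m - len(chosen)))
            for idx in draw:
                if len(chosen) >= m:
                    break
                chosen.add(int(idx))
        for idx in sorted(chosen):
            net.add_edge(*_pair_from_index(idx, n, directed))
        return net
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0,1]")
    hits = np.nonzero(rng.random(n_dyads) < p)[0]
    for idx in hits:
        net.add_edge(*_pair_from_index(int(idx), n, directed))
    return net


def generate_from_model(model: ModelSpec, theta, n: int,
                        seed: int | None = None,
                        attrs: AttributeSet | None = None,
                        burnin_factor: int = 50) -> Network:
    """One long-run Metropolis sample from an ERGM.

    Starts from an Erdős–Rényi graph at the density implied by the
    model's density parameter (logistic of θ_Arc/θ_Edge) and runs
    ``burnin_factor`` sweeps of toggle proposals.  Used as ground truth
    for parameter-recovery experiments.

    Models that combine density with positive closure have no proper
    equilibrium in their sparse phase — the sparse region is metastable
    and leaks slowly toward a dense, clustered phase — so for them the
    burn-in length is a sampling convention rather than an equilibration
    requirement.  The default sits inside the window where the sparse
    draws are stable, emulating the sparse regime the real regulatory
    and interaction networks occupy.
    """
    from .sampler import Chain

    theta = np.asarray(theta, dtype=float)
    rng = np.random.default_rng(seed)
    k = model.density_effect_index()
    p0 = 1.0 / (1.0 + np.exp(-theta[k])) if k is not None else 0.5
    directed = any(e.directed_only is True for e in model.effects) or \
        model.forbid_reciprocity
    net = generate_er(n, p=float(p0), directed=directed,
                      seed=int(rng.integers(2 ** 31)),
                      allow_loops=model.allow_loops)
    if model.forbid_reciprocity:
        for i in range(n):
            for j in [j for j in net._out[i] if j > i and i in net._out[j]]:
                net.remove_edge(i, j)
    chain = Chain(net, model, theta, rng)
    chain.run(burnin_factor * chain.n_dyads)
    return net


@dataclass
class AttributePlan:
    """I.i.d. attribute assignment: binary prevalences, categorical
    category counts with an NA fraction."""

    binary: dict[str, float] = field(default_factory=dict)
    categorical: dict[str, tuple[int, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name, prev in self.binary.items():
            if not 0.0 <= prev <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0,1]")
        for name, (k, na) in self.categorical.items():
            if k < 1:
                raise ValueError(f"{name!r} needs >= 1 category")
            if not 0.0 <= na <= 1.0:
                raise ValueError(f"NA fraction of {name!r} outside [0,1]")


def assign_attributes(net: Network, plan: AttributePlan,
                      seed: int | None = None) -> AttributeSet:
    """Draw node attributes per the plan (emulating functional classes
    or location annotations with missing values)."""
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    attrs = AttributeSet()
    for name, prev in plan.binary.items():
        attrs.add_binary(name, (rng.random(n) < prev).astype(np.int8))
    for name, (k, na_frac) in plan.categorical.items():
        codes = rng.integers(0, k, size=n)
        codes[rng.random(n) < na_frac] = -1
        attrs.add_categorical(name, codes, [str(c) for c in range(k)])
    return attrs


def plant_bifans(net: Network, k: int, seed: int | None = None) -> Network:
    """Add ``k`` bi-fans on isolated 4-tuples; returns a new network.

    Tuples are drawn from currently isolated nodes (no ties at all), so
    each placement contributes exactly one induced bi-fan and cannot
    disturb any existing one — a clean power fixture for ensemble motif
    tests.  Raises if fewer than 4k isolated nodes exist.
    """
    if not net.directed:
        raise ValueError("bi-fans are directed motifs")
    if k < 0:
        raise ValueError("k must be >= 0")
    out = net.copy()
    if k == 0:
        return out
    isolated = [v for v in range(net.n_nodes)
                if not net._out[v] and not net._in[v] and v not in net.loops]
    if len(isolated) < 4 * k:
        raise ValueError(
            f"need {4 * k} isolated nodes to plant {k} bi-fans, "
            f"have {len(isolated)}")
    rng = np.random.default_rng(seed)
    picked = rng.permutation(isolated)[:4 * k]
    for t in range(k):
        a, b, c, d = (int(v) for v in picked[4 * t:4 * t + 4])
        for src, dst in ((a, c), (a, d), (b, c), (b, d)):
            out.add_edge(src, dst)
    return out


# ---------------------------------------------------------------------
# Presets mirroring the two study regimes at reduced size
# ---------------------------------------------------------------------

def regulatory_like_model(arc: float = -5.0, alt_k_triangles_t: float = 1.2,
                          lam: float = 2.0) -> tuple[ModelSpec, np.ndarray]:
    """Sparse digraph with transitive closure and no reciprocated arcs."""
    model = ModelSpec([EffectSpec("Arc"),
                       EffectSpec("AltKTrianglesT", lam=lam)],
                      forbid_reciprocity=True)
    return model, np.array([arc, alt_k_triangles_t])


def ppi_like_model(edge: float = -4.5, at: float = 1.0,
                   match: float = 0.5, lam: float = 2.0,
                   attr_name: str = "class") -> tuple[ModelSpec, np.ndarray]:
    """Undirected, high-transitivity graph with categorical homophily."""
    model = ModelSpec([EffectSpec("Edge"), EffectSpec("AT", lam=lam),
                       EffectSpec("Match", attribute=attr_name)])
    return model, np.array([edge, at, match])
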