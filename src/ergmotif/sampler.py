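"""Metropolis–Hastings simulation of networks from an ERGM.

Two symmetric proposals are provided: a uniform dyad toggle, and a
fixed-density swap that deletes one uniformly chosen present tie and
adds one uniformly chosen absent dyad, so the edge count is conserved
exactly at every step.  The swap targets the ERGM conditional on the
observed tie count, which is what density-conditioned ("IFD"-style)
estimation asks of its sampler.  Moves that would create a reciprocated
arc under the no-reciprocity constraint are rejected outright, and loop
dyads enter the proposal space only when the model permits them.

Acceptance uses min(1, exp(θ·Δz)), where Δz is the signed change-
statistic vector of the proposal — the Metropolis ratio that follows
directly from the exponential form of the model, with the intractable
normalizing constant cancelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import ModelSpec
from .network import AttributeSet, Network
from .statistics import make_change_funcs, statistics_vector

__all__ = ["SamplerSettings", "Ensemble", "Chain", "simulate_ensemble"]

_BLOCK = 8192  # pre-drawn random numbers per refill


@dataclass
class SamplerSettings:
    """Chain control parameters.

    ``burnin`` and ``interval`` default to 10 × dyad-count and one
    dyad-count of proposals respectively — one nominal sweep between
    retained samples.
    """

    burnin: int | None = None
    interval: int | None = None
    seed: int | None = None
    proposal: str = "toggle"

    def __post_init__(self):
        if self.burnin is not None and self.burnin < 0:
            raise ValueError("burnin must be >= 0")
        if self.interval is not None and self.interval < 1:
            raise ValueError("interval must be >= 1")
        if self.proposal not in ("toggle", "fixed_density_swap"):
            raise ValueError(f"unknown proposal {self.proposal!r}")

    def resolved_burnin(self, n_dyads: int) -> int:
        return 10 * n_dyads if self.burnin is None else self.burnin

    def resolved_interval(self, n_dyads: int) -> int:
        return max(1, n_dyads) if self.interval is None else self.interval


@dataclass
class Ensemble:
    """Retained samples: statistics matrix plus optional networks."""

    labels: list[str]
    statistics: np.ndarray  # (n_samples, n_effects)
    networks: list[Network] | None = None
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.statistics.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.statistics, columns=self.labels)


class Chain:
    """A Metropolis chain over networks, mutated in place.

    Keeps the current statistics vector incrementally up to date; the
    defining identity (incremental z equals a full recount) is part of
    the test suite.
    """

    def __init__(self, state: Network, model: ModelSpec, theta,
                 rng: np.random.Generator,
                 proposal: str = "toggle",
                 attrs: AttributeSet | None = None):
        model.check_compatible(state)
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (model.n_effects,):
            raise ValueError("theta length must equal the effect count")
        self.state = state
        self.model = model
        self.rng = rng
        self.proposal = proposal
        self.attrs = attrs
        self._funcs = make_change_funcs(state, model, attrs)
        self._z = list(statistics_vector(state, model, attrs).astype(float))
        self._theta = [float(v) for v in theta]
        self._dz = [0.0] * model.n_effects
        self._loop_idx = next((k for k, e in enumerate(model.effects)
                               if e.name == "Loop"), None)
        n = state.n_nodes
        self._n = n
        self._loops_allowed = state.allow_loops and model.allow_loops
        base = n * (n - 1) if state.directed else n * (n - 1) // 2
        self._n_dyads = base + (n if self._loops_allowed else 0)
        if proposal == "fixed_density_swap":
            self._edge_list = list(state.edges())
            self._edge_pos = {e: k for k, e in enumerate(self._edge_list)}
            if not self._edge_list:
                raise ValueError("fixed-density swap needs at least one tie")
            if len(self._edge_list) >= self._n_dyads:
                raise ValueError("fixed-density swap needs at least one empty dyad")
        self._u_block = np.empty(0)
        self._u_pos = 0
        # optional full-path accumulation of z (every step, accepted or
        # not): a cheap variance reduction for moment residuals
        self.accumulate = False
        self._z_sum = [0.0] * model.n_effects
        self.z_count = 0

    # -- statistics and parameters as arrays ---------------------------

    @property
    def z(self) -> np.ndarray:
        """Current statistics vector (kept incrementally)."""
        return np.array(self._z)

    @property
    def theta(self) -> np.ndarray:
        return np.array(self._theta)

    @theta.setter
    def theta(self, value) -> None:
        self._theta = [float(v) for v in np.asarray(value).ravel()]

    def reset_accumulator(self) -> None:
        self._z_sum = [0.0] * self.model.n_effects
        self.z_count = 0
        self.accumulate = True

    def path_mean(self) -> np.ndarray:
        if self.z_count == 0:
            raise ValueError("no accumulated steps")
        return np.array(self._z_sum) / self.z_count

    # -- proposal machinery -------------------------------------------

    @property
    def n_dyads(self) -> int:
        return self._n_dyads

    def _uniform(self) -> float:
        if self._u_pos >= self._u_block.shape[0]:
            self._u_block = self.rng.random(_BLOCK)
            self._u_pos = 0
        u = self._u_block[self._u_pos]
        self._u_pos += 1
        return u

    def _random_dyad(self) -> tuple[int, int]:
        n = self._n
        idx = int(self._uniform() * self._n_dyads)
        if self._loops_allowed and idx >= self._n_dyads - n:
            i = idx - (self._n_dyads - n)
            return (i, i)
        if self.state.directed:
            i, r = divmod(idx, n - 1)
            return (i, r if r < i else r + 1)
        # unordered pair from the lower-triangular index
        i = int((1 + math.isqrt(1 + 8 * idx)) // 2)
        j = idx - i * (i - 1) // 2
        return (j, i)

    def _delta_into(self, i: int, j: int) -> float:
        """Fill the proposal buffer with change stats; return theta . dz."""
        buf, th = self._dz, self._theta
        if i == j:
            for k in range(len(buf)):
                buf[k] = 0.0
            if self._loop_idx is not None:
                buf[self._loop_idx] = 1.0
                return th[self._loop_idx]
            return 0.0
        s = 0.0
        funcs = self._funcs
        for k in range(len(funcs)):
            d = funcs[k](i, j)
            buf[k] = d
            s += th[k] * d
        return s

    def _apply(self, i: int, j: int, add: bool) -> None:
        st = self.state
        if add:
            st.add_edge(i, j)
        else:
            st.remove_edge(i, j)
        if self.proposal == "fixed_density_swap":
            key = (i, j) if (st.directed or i <= j) else (j, i)
            if add:
                self._edge_pos[key] = len(self._edge_list)
                self._edge_list.append(key)
            else:
                pos = self._edge_pos.pop(key)
                last = self._edge_list.pop()
                if last != key:
                    self._edge_list[pos] = last
                    self._edge_pos[last] = pos

    # -- steps ---------------------------------------------------------

    def _step_toggle(self) -> bool:
        st = self.state
        i, j = self._random_dyad()
        if i == j:
            present = i in st.loops
        else:
            present = j in st._out[i]
            if (not present and self.model.forbid_reciprocity
                    and i in st._out[j]):
                return False  # would create a mutual dyad
        logr = self._delta_into(i, j)
        sign = 1.0 if not present else -1.0
        logr *= sign
        if logr >= 0.0 or self._uniform() < math.exp(logr):
            self._apply(i, j, add=not present)
            z, buf = self._z, self._dz
            for k in range(len(z)):
                z[k] += sign * buf[k]
            return True
        return False

    def _step_swap(self) -> bool:
        st = self.state
        # uniformly chosen present tie to delete
        eidx = int(self._uniform() * len(self._edge_list))
        ei, ej = self._edge_list[eidx]
        # uniformly chosen absent dyad to add (rejection over dyads)
        while True:
            ai, aj = self._random_dyad()
            if not st.has_edge(ai, aj):
                break
        if (self.model.forbid_reciprocity and ai != aj
                and ai in st._out[aj] and not (aj == ei and ai == ej)):
            return False  # addition would reciprocate a surviving arc
        s_del = self._delta_into(ei, ej)
        dz_del = list(self._dz)
        self._apply(ei, ej, add=False)
        s_add = self._delta_into(ai, aj)
        logr = s_add - s_del
        if logr >= 0.0 or self._uniform() < math.exp(logr):
            self._apply(ai, aj, add=True)
            z, buf = self._z, self._dz
            for k in range(len(z)):
                z[k] += buf[k] - dz_del[k]
            return True
        self._apply(ei, ej, add=True)  # reject: restore
        return False

    def run(self, n_steps: int) -> int:
        """Advance the chain; returns the number of accepted moves."""
        step = (self._step_swap if self.proposal == "fixed_density_swap"
                else self._step_toggle)
        accepted = 0
        if self.accumulate:
            z_sum, z = self._z_sum, self._z
            ne = len(z)
            for _ in range(n_steps):
                if step():
                    accepted += 1
                for k in range(ne):
                    z_sum[k] += z[k]
            self.z_count += n_steps
        else:
            for _ in range(n_steps):
                if step():
                    accepted += 1
        return accepted

    def sample(self, n_samples: int, interval: int,
               keep_networks: bool = False):
        """Retain ``n_samples`` statistic vectors, ``interval`` steps apart."""
        stats = np.empty((n_samples, self.model.n_effects))
        nets = [] if keep_networks else None
        for s in range(n_samples):
            self.run(interval)
            stats[s] = self.z
            if keep_networks:
                nets.append(self.state.copy())
        return stats, nets


def _initial_network(model: ModelSpec, n_nodes: int, init,
                     rng: np.random.Generator) -> Network:
    from .synthetic import generate_er  # local import: avoid cycle

    if isinstance(init, Network):
        net = init.copy()
    else:
        p = 0.5 if init is None else float(init)
        directed = any(e.directed_only is True for e in model.effects) or \
            model.forbid_reciprocity
        undirected = any(e.directed_only is False for e in model.effects)
        if undirected and directed:
            raise ValueError("model mixes directed and undirected effects")
        net = generate_er(n_nodes, p=p, directed=not undirected,
                          seed=int(rng.integers(2 ** 31)),
                          allow_loops=model.allow_loops)
    if model.forbid_reciprocity:
        mutual = [(i, j) for i in range(net.n_nodes) for j in net._out[i]
                  if j > i and i in net._out[j]]
        for i, j in mutual:
            net.remove_edge(i, j)
    return net


def simulate_ensemble(model: ModelSpec, theta, n_nodes: int | None = None,
                      init=None, n_samples: int = 100,
                      settings: SamplerSettings | None = None,
                      attrs: AttributeSet | None = None,
                      keep_networks: bool = False) -> Ensemble:
    """Simulate an ensemble of networks from a fitted (or chosen) model.

    ``init`` may be a Network (the usual choice for goodness-of-fit,
    starting from the observed graph) or a target density for an
    Erdős–Rényi start.  The default of 100 retained samples matches the
    size of the simulated reference ensembles used in goodness-of-fit
    and motif testing.
    """
    settings = settings or SamplerSettings()
    rng = np.random.default_rng(settings.seed)
    if n_nodes is None:
        if not isinstance(init, Network):
            raise ValueError("n_nodes required unless init is a Network")
        n_nodes = init.n_nodes
    state = _initial_network(model, n_nodes, init, rng)
    chain = Chain(state, model, theta, rng, proposal=settings.proposal,
                  attrs=attrs)
    chain.run(settings.resolved_burnin(chain.n_dyads))
    interval = settings.resolved_interval(chain.n_dyads)
    stats, nets = chain.sample(n_samples, interval, keep_networks)
    return Ensemble(model.labels, stats, nets, seed=settings.seed)
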