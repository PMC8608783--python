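"""Graph statistics z_A(x) and their change statistics.

Implements every configuration statistic used in the directed
(regulatory) and undirected (protein interaction) models: simple
counts, geometrically weighted ("alternating") stars, two-paths and
triangles with decay λ, and attribute-based effects.  The closed forms
are the standard Snijders/Robins parameterizations:

* alternating k-stars      z = λ² Σ_i [(1-1/λ)^{d_i} - 1 + d_i/λ]
* alternating k-two-paths  z = λ Σ_{pairs}  [1 - (1-1/λ)^{tp}]
* alternating k-triangles  z = λ Σ_{ties}   [1 - (1-1/λ)^{sp}]

where d_i is the relevant degree, tp the number of two-paths joining a
pair, and sp the number of partners closing a tie.  Each closed form
equals the corresponding alternating sum over explicit k-star /
k-two-path / k-triangle counts, which is how the test suite audits
them.  Self-loops never contribute to any of these; they are counted
only by the dedicated Loop statistic.

Change statistics return z(x + ij) - z(x - ij) computed from local
neighbourhoods, never by full recount — the quantity the Metropolis
acceptance ratio needs.
"""

from __future__ import annotations

import warnings

import numpy as np

from .model import EffectSpec, ModelSpec
from .network import NA_CODE, AttributeSet, Network

__all__ = [
    "simple_count_statistic",
    "alt_star_statistic",
    "alt_twopath_statistic",
    "alt_triangle_statistic",
    "attribute_statistic",
    "statistic",
    "change_statistic",
    "statistics_vector",
    "make_change_funcs",
]


# ---------------------------------------------------------------------
# Full graph statistics
# ---------------------------------------------------------------------

def simple_count_statistic(net: Network, which: str) -> int:
    """Edge/arc, reciprocity, sink, source and loop counts.

    A sink has at least one incoming and no outgoing arcs; a source the
    reverse.  Reciprocity is the number of mutual dyads.  Self-loops are
    excluded from all degree-based counts.
    """
    if which in ("edge", "arc"):
        return net.n_ties
    if which == "loop":
        if not net.allow_loops:
            warnings.warn("loop statistic requested but loops are not allowed; 0")
            return 0
        return len(net.loops)
    if not net.directed:
        raise ValueError(f"statistic {which!r} requires a directed network")
    if which == "reciprocity":
        return sum(1 for i in range(net.n_nodes)
                   for j in net._out[i] if j > i and i in net._out[j])
    if which == "sink":
        return sum(1 for i in range(net.n_nodes)
                   if net._in[i] and not net._out[i])
    if which == "source":
        return sum(1 for i in range(net.n_nodes)
                   if net._out[i] and not net._in[i])
    raise ValueError(f"unknown simple statistic {which!r}")


def alt_star_statistic(net: Network, direction: str, lam: float) -> float:
    """Alternating k-star statistic over in-, out- or undirected degrees."""
    if lam <= 1.0:
        raise ValueError("lambda must be > 1")
    if direction == "in":
        if not net.directed:
            raise ValueError("in-stars require a directed network")
        degs = net.in_degrees()
    elif direction == "out":
        if not net.directed:
            raise ValueError("out-stars require a directed network")
        degs = net.out_degrees()
    elif direction == "undirected":
        if net.directed:
            raise ValueError("undirected stars require an undirected network")
        degs = net.degrees()
    else:
        raise ValueError(f"unknown direction {direction!r}")
    rho = 1.0 - 1.0 / lam
    return float(lam * lam * np.sum(rho ** degs - 1.0 + degs / lam))


def _twopath_counts_directed(net: Network):
    """Ordered-pair two-path counts: tp(i,j) = #{k : i->k->j}, i != j."""
    counts: dict[tuple[int, int], int] = {}
    for k in range(net.n_nodes):
        for i in net._in[k]:
            for j in net._out[k]:
                if i != j:
                    p = (i, j)
                    counts[p] = counts.get(p, 0) + 1
    return counts


def _twopath_counts_undirected(net: Network):
    """Unordered-pair shared-partner counts over all dyads with tp > 0."""
    counts: dict[tuple[int, int], int] = {}
    for k in range(net.n_nodes):
        nbrs = sorted(net._out[k])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                p = (nbrs[a], nbrs[b])
                counts[p] = counts.get(p, 0) + 1
    return counts


def alt_twopath_statistic(net: Network, variant: str, lam: float) -> float:
    """Alternating k-two-paths: A2P (undirected) or the directed T form."""
    if lam <= 1.0:
        raise ValueError("lambda must be > 1")
    rho = 1.0 - 1.0 / lam
    if variant == "A2P":
        if net.directed:
            raise ValueError("A2P requires an undirected network")
        counts = _twopath_counts_undirected(net)
    elif variant == "T":
        if not net.directed:
            raise ValueError("AltTwoPathsT requires a directed network")
        counts = _twopath_counts_directed(net)
    else:
        raise ValueError(f"unknown two-path variant {variant!r}")
    return float(sum(lam * (1.0 - rho ** t) for t in counts.values()))


def alt_triangle_statistic(net: Network, variant: str, lam: float) -> float:
    """Alternating k-triangles: AT (undirected), transitive T or cyclic C.

    The partner count sp of a tie is the number of undirected shared
    partners of an edge (AT), of directed two-paths i->k->j for an arc
    i->j (T), or of return paths j->k->i (C).
    """
    if lam <= 1.0:
        raise ValueError("lambda must be > 1")
    rho = 1.0 - 1.0 / lam
    total = 0.0
    if variant == "AT":
        if net.directed:
            raise ValueError("AT requires an undirected network")
        for i in range(net.n_nodes):
            for j in net._out[i]:
                if i < j:
                    sp = len(net._out[i] & net._out[j])
                    total += lam * (1.0 - rho ** sp)
    elif variant in ("T", "C"):
        if not net.directed:
            raise ValueError(f"variant {variant} requires a directed network")
        for i in range(net.n_nodes):
            for j in net._out[i]:
                if variant == "T":
                    sp = len(net._out[i] & net._in[j])
                else:
                    sp = len(net._out[j] & net._in[i])
                total += lam * (1.0 - rho ** sp)
    else:
        raise ValueError(f"unknown triangle variant {variant!r}")
    return float(total)


def attribute_statistic(net: Network, which: str, attrs: AttributeSet,
                        attr_name: str) -> float:
    """Sender/receiver/interaction (binary) and matching (categorical).

    Matching counts ties whose endpoints carry equal non-NA categories;
    NA matches nothing, not even another NA.
    """
    if which in ("sender", "receiver", "interaction"):
        if not net.directed:
            raise ValueError(f"{which} requires a directed network")
        if attr_name not in attrs.binary:
            raise ValueError(f"binary attribute {attr_name!r} not found")
        a = attrs.binary[attr_name]
        total = 0
        for i in range(net.n_nodes):
            for j in net._out[i]:
                if which == "sender":
                    total += a[i]
                elif which == "receiver":
                    total += a[j]
                else:
                    total += a[i] * a[j]
        return float(total)
    if which == "match":
        if attr_name not in attrs.categorical:
            raise ValueError(f"categorical attribute {attr_name!r} not found")
        c = attrs.categorical[attr_name]
        total = 0
        for i in range(net.n_nodes):
            for j in net._out[i]:
                if (net.directed or i < j) and c[i] == c[j] and c[i] != NA_CODE:
                    total += 1
        return float(total)
    raise ValueError(f"unknown attribute statistic {which!r}")


_SIMPLE = {"Edge": "edge", "Arc": "arc", "Reciprocity": "reciprocity",
           "Sink": "sink", "Source": "source", "Loop": "loop"}
_ATTR = {"Sender": "sender", "Receiver": "receiver",
         "Interaction": "interaction", "Match": "match"}


def statistic(net: Network, effect: EffectSpec,
              attrs: AttributeSet | None = None) -> float:
    """Evaluate one effect's full graph statistic z_A(x)."""
    effect.check_compatible(net.directed)
    name = effect.name
    if name in _SIMPLE:
        return float(simple_count_statistic(net, _SIMPLE[name]))
    if name == "AS":
        return alt_star_statistic(net, "undirected", effect.lam)
    if name == "AltInStars":
        return alt_star_statistic(net, "in", effect.lam)
    if name == "AltOutStars":
        return alt_star_statistic(net, "out", effect.lam)
    if name == "A2P":
        return alt_twopath_statistic(net, "A2P", effect.lam)
    if name == "AltTwoPathsT":
        return alt_twopath_statistic(net, "T", effect.lam)
    if name == "AT":
        return alt_triangle_statistic(net, "AT", effect.lam)
    if name == "AltKTrianglesT":
        return alt_triangle_statistic(net, "T", effect.lam)
    if name == "AltKTrianglesC":
        return alt_triangle_statistic(net, "C", effect.lam)
    if name in _ATTR:
        if attrs is None:
            raise ValueError(f"effect {name} needs an AttributeSet")
        return attribute_statistic(net, _ATTR[name], attrs, effect.attribute)
    raise ValueError(f"unknown effect {name!r}")  # pragma: no cover


def statistics_vector(net: Network, model: ModelSpec,
                      attrs: AttributeSet | None = None) -> np.ndarray:
    """z_A(x) for every effect in model order."""
    model.check_compatible(net)
    vec = np.array([statistic(net, e, attrs) for e in model.effects])
    if not np.isfinite(vec).all():
        raise ValueError("non-finite statistic")
    return vec


# ---------------------------------------------------------------------
# Change statistics
# ---------------------------------------------------------------------
#
# Each closure below returns z(x+ij) - z(x-ij) for a non-loop dyad,
# reading the live adjacency sets.  The expressions are exact whether or
# not the tie is currently present: counts that would include the
# toggled tie itself are corrected by a `present` indicator.  The test
# suite checks them against full recounts over random toggles.

def make_change_funcs(net: Network, model: ModelSpec,
                      attrs: AttributeSet | None = None):
    """Compile one ``f(i, j) -> float`` per effect, bound to ``net``.

    The closures remain valid as ``net`` is mutated in place, which is
    what the sampler relies on.
    """
    model.check_compatible(net)
    out, in_ = net._out, net._in
    om, im = net._om, net._im
    funcs = []
    for effect in model.effects:
        name = effect.name

        if name in ("Edge", "Arc"):
            funcs.append(lambda i, j: 1.0)

        elif name == "Loop":
            funcs.append(lambda i, j: 0.0)  # loop dyads are special-cased

        elif name == "Reciprocity":
            def f(i, j, out=out):
                return 1.0 if i in out[j] else 0.0
            funcs.append(f)

        elif name == "Sink":
            def f(i, j, out=out, in_=in_):
                present = 1 if j in out[i] else 0
                gain = 1.0 if (not out[j] and len(in_[j]) - present == 0) else 0.0
                loss = 1.0 if (in_[i] and len(out[i]) - present == 0) else 0.0
                return gain - loss
            funcs.append(f)

        elif name == "Source":
            def f(i, j, out=out, in_=in_):
                present = 1 if j in out[i] else 0
                gain = 1.0 if (not in_[i] and len(out[i]) - present == 0) else 0.0
                loss = 1.0 if (out[j] and len(in_[j]) - present == 0) else 0.0
                return gain - loss
            funcs.append(f)

        elif name in ("AS", "AltInStars", "AltOutStars"):
            lam = effect.lam
            rho = 1.0 - 1.0 / lam
            if name == "AltInStars":
                def f(i, j, out=out, in_=in_, lam=lam, rho=rho):
                    d = len(in_[j]) - (1 if j in out[i] else 0)
                    return lam * (1.0 - rho ** d)
            elif name == "AltOutStars":
                def f(i, j, out=out, lam=lam, rho=rho):
                    d = len(out[i]) - (1 if j in out[i] else 0)
                    return lam * (1.0 - rho ** d)
            else:  # AS: both endpoints' degrees move
                def f(i, j, out=out, lam=lam, rho=rho):
                    present = 1 if j in out[i] else 0
                    di = len(out[i]) - present
                    dj = len(out[j]) - present
                    return lam * (2.0 - rho ** di - rho ** dj)
            funcs.append(f)

        elif name == "A2P":
            lam = effect.lam
            rho = 1.0 - 1.0 / lam

            def f(i, j, out=out, om=om, rho=rho):
                present = 1 if j in out[i] else 0
                total = 0.0
                mi, mj = om[i], om[j]
                for l in out[j]:  # new two-path i-j-l for pair {i,l}
                    if l != i:
                        total += rho ** ((mi & om[l]).bit_count() - present)
                for k in out[i]:  # new two-path k-i-j for pair {j,k}
                    if k != j:
                        total += rho ** ((mj & om[k]).bit_count() - present)
                return total
            funcs.append(f)

        elif name == "AltTwoPathsT":
            lam = effect.lam
            rho = 1.0 - 1.0 / lam

            def f(i, j, out=out, in_=in_, om=om, im=im, rho=rho):
                present = 1 if j in out[i] else 0
                total = 0.0
                mi, mj_in = om[i], im[j]
                for l in out[j]:  # path i->j->l for ordered pair (i,l)
                    if l != i:
                        total += rho ** ((mi & im[l]).bit_count() - present)
                for k in in_[i]:  # path k->i->j for ordered pair (k,j)
                    if k != j:
                        total += rho ** ((om[k] & mj_in).bit_count() - present)
                return total
            funcs.append(f)

        elif name == "AT":
            lam = effect.lam
            rho = 1.0 - 1.0 / lam

            def f(i, j, out=out, om=om, lam=lam, rho=rho):
                present = 1 if j in out[i] else 0
                mi, mj = om[i], om[j]
                cm = mi & mj
                total = lam * (1.0 - rho ** cm.bit_count())
                while cm:
                    ml = om[(cm & -cm).bit_length() - 1]
                    cm &= cm - 1
                    total += rho ** ((mi & ml).bit_count() - present)
                    total += rho ** ((mj & ml).bit_count() - present)
                return total
            funcs.append(f)

        elif name == "AltKTrianglesT":
            lam = effect.lam
            rho = 1.0 - 1.0 / lam

            def f(i, j, out=out, om=om, im=im, lam=lam, rho=rho):
                present = 1 if j in out[i] else 0
                mi, mj_in = om[i], im[j]
                # the toggled arc as a base, closed by paths i->k->j
                total = lam * (1.0 - rho ** (mi & mj_in).bit_count())
                cm = mi & om[j]         # base arc i->l gains partner j
                while cm:
                    ml = im[(cm & -cm).bit_length() - 1]
                    cm &= cm - 1
                    total += rho ** ((mi & ml).bit_count() - present)
                cm = im[i] & mj_in      # base arc k->j gains partner i
                while cm:
                    mk = om[(cm & -cm).bit_length() - 1]
                    cm &= cm - 1
                    total += rho ** ((mk & mj_in).bit_count() - present)
                return total
            funcs.append(f)

        elif name == "AltKTrianglesC":
            lam = effect.lam
            rho = 1.0 - 1.0 / lam

            def f(i, j, out=out, om=om, im=im, lam=lam, rho=rho):
                present = 1 if j in out[i] else 0
                mi, mj_in = om[i], im[j]
                ret = om[j] & im[i]  # u with j->u->i
                total = lam * (1.0 - rho ** ret.bit_count())
                while ret:
                    u = (ret & -ret).bit_length() - 1
                    ret &= ret - 1
                    total += rho ** ((mi & im[u]).bit_count() - present)
                    total += rho ** ((om[u] & mj_in).bit_count() - present)
                return total
            funcs.append(f)

        elif name in ("Sender", "Receiver", "Interaction"):
            a = attrs.binary[effect.attribute] if attrs else None
            if a is None:
                raise ValueError(f"effect {name} needs a binary attribute")
            if name == "Sender":
                funcs.append(lambda i, j, a=a: float(a[i]))
            elif name == "Receiver":
                funcs.append(lambda i, j, a=a: float(a[j]))
            else:
                funcs.append(lambda i, j, a=a: float(a[i] * a[j]))

        elif name == "Match":
            if attrs is None or effect.attribute not in attrs.categorical:
                raise ValueError("Match needs a categorical attribute")
            c = attrs.categorical[effect.attribute]

            def f(i, j, c=c):
                return 1.0 if (c[i] == c[j] and c[i] != NA_CODE) else 0.0
            funcs.append(f)

        else:  # pragma: no cover
            raise ValueError(f"no change statistic for {name!r}")
    return funcs


def change_statistic(net: Network, effect: EffectSpec, i: int, j: int,
                     attrs: AttributeSet | None = None) -> float:
    """z(x + ij) - z(x - ij) for one dyad, computed locally.

    For a loop dyad (i == i) the only nonzero change is the Loop
    effect's, which is always 1; every structural and attribute effect
    ignores self-edges.
    """
    effect.check_compatible(net.directed)
    net._check_node(i)
    net._check_node(j)
    if i == j:
        if not net.allow_loops:
            raise ValueError("loop dyad on a network that forbids loops")
        return 1.0 if effect.name == "Loop" else 0.0
    model = ModelSpec([effect], allow_loops=net.allow_loops)
    return float(make_change_funcs(net, model, attrs)[0](i, j))
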