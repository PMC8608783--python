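"""Triad census, four-node motif counting, and ensemble significance.

Triads are classified with the MAN convention: counts of mutual,
asymmetric and null dyads in the triple, plus a letter for orientation
(up, down, transitive, cyclic) where the dyad census is ambiguous.  The
transitive triangle 030T is the feed-forward loop; 030C is the
three-node feedback loop.

Four-node motifs use the induced-subgraph convention of the classical
motif counters: a 4-set counts only if its induced subgraph is
isomorphic to the motif, extra arcs disqualify it.  This deliberately
differs from ERGM configurations, which are counted wherever their arcs
occur regardless of surrounding ties; both semantics coexist here
because the model statistics and the motif tests ask different
questions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .network import Network

__all__ = ["TRIAD_LABELS", "TriadCensus", "MotifSpec", "BIFAN", "BIPARALLEL",
           "classify_triad", "triad_census", "count_four_node_motif",
           "motif_significance"]

TRIAD_LABELS = ("003", "012", "102", "021D", "021U", "021C", "111D", "111U",
                "030T", "030C", "201", "120D", "120U", "120C", "210", "300")


@dataclass
class TriadCensus:
    """Counts of the 16 triad isomorphism classes."""

    counts: dict[str, int]

    def __getitem__(self, label: str) -> int:
        return self.counts[label]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[l] for l in TRIAD_LABELS], dtype=np.int64)


def classify_triad(net: Network, i: int, j: int, k: int) -> str:
    """MAN label of the induced subgraph on three distinct nodes.

    Orientation suffixes: D when two asymmetric arcs diverge from one
    node (out-star), U when they converge (in-star), C for paths and
    cycles, T for the transitive triangle.  Self-loops are ignored.
    """
    if not net.directed:
        raise ValueError("triad census applies to directed networks")
    if len({i, j, k}) != 3:
        raise ValueError("triad nodes must be distinct")
    out = net._out
    arcs = []
    for a, b in ((i, j), (j, i), (i, k), (k, i), (j, k), (k, j)):
        if b in out[a]:
            arcs.append((a, b))
    mutual = asym = 0
    asym_arcs = []
    for a, b in ((i, j), (i, k), (j, k)):
        ab, ba = (b in out[a]), (a in out[b])
        if ab and ba:
            mutual += 1
        elif ab or ba:
            asym += 1
            asym_arcs.append((a, b) if ab else (b, a))
    null = 3 - mutual - asym

    if mutual == 0:
        if asym == 0:
            return "003"
        if asym == 1:
            return "012"
        if asym == 2:
            heads = [b for _, b in asym_arcs]
            tails = [a for a, _ in asym_arcs]
            if tails[0] == tails[1]:
                return "021D"  # out-star
            if heads[0] == heads[1]:
                return "021U"  # in-star
            return "021C"      # directed path
        # three asymmetric dyads: cycle or transitive triangle
        heads = {b for _, b in asym_arcs}
        return "030C" if len(heads) == 3 else "030T"
    if mutual == 1:
        if null == 2:
            return "102"
        if asym == 1:
            # which way does the lone arc point relative to the mutual dyad?
            (a, b), = asym_arcs
            third = next(v for v in (i, j, k)
                         if not any(u in out[v] and v in out[u]
                                    for u in (i, j, k) if u != v))
            return "111D" if a == third else "111U"
        # mutual == 1, asym == 2
        third = next(v for v in (i, j, k)
                     if not any(u in out[v] and v in out[u]
                                for u in (i, j, k) if u != v))
        outgoing = sum(1 for a, _ in asym_arcs if a == third)
        if outgoing == 2:
            return "120D"
        if outgoing == 0:
            return "120U"
        return "120C"
    if mutual == 2:
        return "201" if asym == 0 else "210"
    return "300"


def triad_census(net: Network) -> TriadCensus:
    """Census over all C(n,3) triples of a directed network.

    Adjacency-driven: triples with no ties are counted by subtraction,
    so the cost is governed by the number of connected triples rather
    than n³.  Loops are ignored.
    """
    if not net.directed:
        raise ValueError("triad census applies to directed networks")
    n = net.n_nodes
    counts = dict.fromkeys(TRIAD_LABELS, 0)
    # every triple containing at least one tied dyad; triples of three
    # pairwise-null dyads are counted by subtraction at the end
    tied_pairs = set()
    for i in range(n):
        for j in net._out[i]:
            if i != j:
                tied_pairs.add((i, j) if i < j else (j, i))
    done: set[tuple[int, int, int]] = set()
    for (a, b) in tied_pairs:
        for c in range(n):
            if c == a or c == b:
                continue
            tri = (a, b, c) if c > b else ((a, c, b) if c > a else (c, a, b))
            if tri in done:
                continue
            done.add(tri)
            counts[classify_triad(net, *tri)] += 1
    counts["003"] += n * (n - 1) * (n - 2) // 6 - len(done)
    return TriadCensus(counts)


# ---------------------------------------------------------------------
# Four-node motifs
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSpec:
    """A canonical loop-free simple digraph on 4 labelled nodes."""

    name: str
    arcs: tuple[tuple[int, int], ...]


#: two sources each pointing at the same two targets
BIFAN = MotifSpec("bifan", ((0, 2), (0, 3), (1, 2), (1, 3)))
#: two parallel directed 2-paths sharing endpoints
BIPARALLEL = MotifSpec("biparallel", ((0, 1), (0, 2), (1, 3), (2, 3)))

_ALL_ORDERED_4 = tuple((a, b) for a in range(4) for b in range(4) if a != b)


def _induced_matches(net: Network, nodes: tuple[int, ...],
                     motif: MotifSpec) -> bool:
    """Is the induced subgraph on ``nodes`` isomorphic to the motif?"""
    out = net._out
    arc_set = frozenset(motif.arcs)
    present = {(a, b) for a, b in _ALL_ORDERED_4
               if nodes[b] in out[nodes[a]]}
    if len(present) != len(arc_set):
        return False
    for perm in permutations(range(4)):
        if {(perm[a], perm[b]) for a, b in present} == arc_set:
            return True
    return False


def count_four_node_motif(net: Network, motif: MotifSpec) -> int:
    """Induced count of a 4-node motif (loops ignored).

    Fast paths exist for the bi-fan and bi-parallel patterns; other
    motifs fall back to scanning 4-sets around each tied pair.
    """
    if not net.directed:
        raise ValueError("four-node motif counting applies to directed networks")
    if motif.name == "bifan":
        return _count_bifan(net)
    if motif.name == "biparallel":
        return _count_biparallel(net)
    return _count_generic(net, motif)


def _no_extra(net: Network, absences) -> bool:
    out = net._out
    return not any(b in out[a] for a, b in absences)


def _count_bifan(net: Network) -> int:
    out, in_ = net._out, net._in
    n = net.n_nodes
    count = 0
    for a in range(n):
        if len(out[a]) < 2:
            continue
        for b in range(a + 1, n):
            if len(out[b]) < 2:
                continue
            targets = sorted((out[a] & out[b]) - {a, b})
            for x in range(len(targets)):
                c = targets[x]
                for y in range(x + 1, len(targets)):
                    d = targets[y]
                    if _no_extra(net, ((a, b), (b, a), (c, d), (d, c),
                                       (c, a), (c, b), (d, a), (d, b))):
                        count += 1
    return count


def _count_biparallel(net: Network) -> int:
    out, in_ = net._out, net._in
    n = net.n_nodes
    count = 0
    for a in range(n):
        if len(out[a]) < 2:
            continue
        for d in range(n):
            if d == a or len(in_[d]) < 2:
                continue
            mids = sorted((out[a] & in_[d]) - {a, d})
            for x in range(len(mids)):
                b = mids[x]
                for y in range(x + 1, len(mids)):
                    c = mids[y]
                    if _no_extra(net, ((a, d), (d, a), (b, c), (c, b),
                                       (b, a), (c, a), (d, b), (d, c))):
                        count += 1
    return count


def _count_generic(net: Network, motif: MotifSpec) -> int:
    from itertools import combinations

    n = net.n_nodes
    count = 0
    for nodes in combinations(range(n), 4):
        if _induced_matches(net, nodes, motif):
            count += 1
    return count


# ---------------------------------------------------------------------
# Significance against a simulated ensemble
# ---------------------------------------------------------------------

def motif_significance(observed: int, ensemble_counts):
    """z-score and upper-tail empirical p against a null ensemble.

    z = (observed − mean)/sd when the ensemble varies, NaN otherwise;
    p = (1 + #{sim ≥ observed}) / (N + 1), the add-one estimator that
    never reports an exact zero.
    """
    counts = np.asarray(ensemble_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty ensemble")
    mean, sd = counts.mean(), counts.std(ddof=1) if counts.size > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p = (1.0 + np.sum(counts >= observed)) / (counts.size + 1.0)
    return float(z), float(p)
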