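"""Independent brute-force oracles used by the test suite.

Everything here works from a network's public edge set only, rebuilding
its own adjacency structures, and computes the alternating statistics
as explicit alternating sums over k-star / k-two-path / k-triangle
counts — deliberately not the closed forms the package implements.
Four-node motif counts come from full 4-subset enumeration with a
24-permutation isomorphism check.
"""

from __future__ import annotations

from itertools import combinations, permutations
from math import comb


def _adj(net):
    n = net.n_nodes
    out = [set() for _ in range(n)]
    in_ = [set() for _ in range(n)]
    for i, j in net.edge_set():
        if i == j:
            continue
        out[i].add(j)
        in_[j].add(i)
        if not net.directed:
            out[j].add(i)
            in_[i].add(j)
    return out, in_


def alt_star_sum(net, direction: str, lam: float) -> float:
    """Σ_{k>=2} (-1)^k S_k / λ^{k-2} over explicit k-star counts."""
    out, in_ = _adj(net)
    if direction == "in":
        degs = [len(s) for s in in_]
    elif direction == "out":
        degs = [len(s) for s in out]
    else:
        degs = [len(s) for s in out]
    kmax = max(degs, default=0)
    total = 0.0
    for k in range(2, kmax + 1):
        s_k = sum(comb(d, k) for d in degs)
        total += (-1) ** k * s_k / lam ** (k - 2)
    return total


def _pair_twopath_counts(net, variant: str):
    out, in_ = _adj(net)
    n = net.n_nodes
    counts = []
    if variant in ("A2P",):
        for i, j in combinations(range(n), 2):
            counts.append(len(out[i] & out[j]))
    else:  # directed ordered pairs
        for i in range(n):
            for j in range(n):
                if i != j:
                    counts.append(len(out[i] & in_[j]))
    return counts


def alt_twopath_sum(net, variant: str, lam: float) -> float:
    """Σ_{k>=1} (-1)^{k+1} P_k / λ^{k-1} with P_k = Σ_pairs C(tp, k)."""
    counts = _pair_twopath_counts(net, variant)
    kmax = max(counts, default=0)
    total = 0.0
    for k in range(1, kmax + 1):
        p_k = sum(comb(t, k) for t in counts)
        total += (-1) ** (k + 1) * p_k / lam ** (k - 1)
    return total


def alt_triangle_sum(net, variant: str, lam: float) -> float:
    """Σ_{k>=1} (-1)^{k+1} T_k / λ^{k-1} with T_k = Σ_ties C(sp, k)."""
    out, in_ = _adj(net)
    sps = []
    if variant == "AT":
        for i, j in net.edge_set():
            if i != j:
                sps.append(len(out[i] & out[j]))
    else:
        for i, j in net.edge_set():
            if i == j:
                continue
            if variant == "T":
                sps.append(len(out[i] & in_[j]))
            else:  # C
                sps.append(len(out[j] & in_[i]))
    kmax = max(sps, default=0)
    total = 0.0
    for k in range(1, kmax + 1):
        t_k = sum(comb(sp, k) for sp in sps)
        total += (-1) ** (k + 1) * t_k / lam ** (k - 1)
    return total


def brute_force_motif_count(net, canonical_arcs) -> int:
    """Induced count over all 4-subsets with explicit isomorphism check."""
    out, _ = _adj(net)
    target = frozenset(canonical_arcs)
    count = 0
    for nodes in combinations(range(net.n_nodes), 4):
        present = {(a, b) for a in range(4) for b in range(4)
                   if a != b and nodes[b] in out[nodes[a]]}
        if len(present) != len(target):
            continue
        for perm in permutations(range(4)):
            if {(perm[a], perm[b]) for a, b in present} == target:
                count += 1
                break
    return count


def enumerate_three_node_digraphs():
    """All 64 labelled loop-free digraphs on 3 nodes, as arc tuples."""
    dyads = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
    for bits in range(64):
        yield tuple(d for k, d in enumerate(dyads) if bits >> k & 1)
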