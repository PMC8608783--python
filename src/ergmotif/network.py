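"""Graph data model, node attributes, file I/O and preprocessing.

Networks are simple directed or undirected graphs on a fixed node set
``0..n-1``.  Self-loops are stored separately from ordinary ties so that
structural statistics (stars, two-paths, triangles, sinks/sources) never
see them; only the dedicated Loop statistic and the loop-permitting
sampler read them.  Raw inputs may carry multi-edges, which are recorded
as multiplicities until :func:`simplify_network` collapses them.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Network",
    "AttributeSet",
    "read_edge_list",
    "read_weighted_edge_list",
    "read_pajek",
    "write_network",
    "simplify_network",
    "binarize_weighted_edges",
    "density",
    "read_attributes",
    "write_attributes",
    "NA_CODE",
]

#: Code used for a missing categorical value.  NA never matches anything,
#: including another NA.
NA_CODE = -1


class Network:
    """A simple directed or undirected graph with integer node ids.

    Parameters
    ----------
    n_nodes:
        Number of nodes; ids are ``0..n_nodes-1``.
    directed:
        Whether ties are ordered pairs (arcs).
    allow_loops:
        Whether self-edges may be present.

    Notes
    -----
    Adjacency is held as per-node successor/predecessor sets, which gives
    O(1) tie queries and O(degree) neighbourhood intersections -- the two
    operations the Metropolis sampler and the change statistics live on.
    For undirected networks the successor and predecessor structures are
    the same object.
    """

    __slots__ = ("n_nodes", "directed", "allow_loops", "_out", "_in",
                 "_om", "_im", "loops", "_m", "multiplicity")

    def __init__(self, n_nodes: int, directed: bool, allow_loops: bool = False):
        if n_nodes < 0:
            raise ValueError("n_nodes must be non-negative")
        self.n_nodes = int(n_nodes)
        self.directed = bool(directed)
        self.allow_loops = bool(allow_loops)
        self._out = [set() for _ in range(self.n_nodes)]
        self._in = [set() for _ in range(self.n_nodes)] if directed else self._out
        # bitmask mirrors of the adjacency sets: neighbourhood
        # intersections via int.bit_count are what the change
        # statistics and the sampler hot loop run on
        self._om = [0] * self.n_nodes
        self._im = self._om if not directed else [0] * self.n_nodes
        self.loops: set[int] = set()
        self._m = 0  # non-loop tie count
        # multiplicities > 1 recorded by readers; empty once simplified
        self.multiplicity: dict[tuple[int, int], int] = {}

    # -- basic queries -------------------------------------------------

    @property
    def n_edges(self) -> int:
        """Total tie count, loops included."""
        return self._m + len(self.loops)

    @property
    def n_ties(self) -> int:
        """Non-loop tie count (arcs or undirected edges)."""
        return self._m

    @property
    def is_simple(self) -> bool:
        return not self.multiplicity

    def dyad_count(self) -> int:
        """Number of distinct dyads, loops included iff permitted."""
        n = self.n_nodes
        base = n * (n - 1) if self.directed else n * (n - 1) // 2
        return base + (n if self.allow_loops else 0)

    def _key(self, i: int, j: int) -> tuple[int, int]:
        if self.directed or i <= j:
            return (i, j)
        return (j, i)

    def has_edge(self, i: int, j: int) -> bool:
        if i == j:
            return i in self.loops
        return j in self._out[i]

    def successors(self, i: int) -> set:
        return self._out[i]

    def predecessors(self, i: int) -> set:
        return self._in[i]

    def neighbors(self, i: int) -> set:
        if self.directed:
            raise ValueError("neighbors() is for undirected networks")
        return self._out[i]

    def out_degree(self, i: int) -> int:
        return len(self._out[i])

    def in_degree(self, i: int) -> int:
        return len(self._in[i])

    def degree(self, i: int) -> int:
        if self.directed:
            raise ValueError("degree() is for undirected networks")
        return len(self._out[i])

    def out_degrees(self) -> np.ndarray:
        return np.fromiter((len(s) for s in self._out), dtype=np.int64,
                           count=self.n_nodes)

    def in_degrees(self) -> np.ndarray:
        return np.fromiter((len(s) for s in self._in), dtype=np.int64,
                           count=self.n_nodes)

    def degrees(self) -> np.ndarray:
        if self.directed:
            raise ValueError("degrees() is for undirected networks")
        return self.out_degrees()

    # -- mutation ------------------------------------------------------

    def _check_node(self, i: int) -> None:
        if not (0 <= i < self.n_nodes):
            raise ValueError(f"node id {i} outside 0..{self.n_nodes - 1}")

    def add_edge(self, i: int, j: int) -> None:
        """Add a tie; repeated additions accumulate multiplicity."""
        self._check_node(i)
        self._check_node(j)
        if i == j:
            if not self.allow_loops:
                raise ValueError(f"self-loop ({i},{i}) but allow_loops is False")
            if i in self.loops:
                k = self._key(i, j)
                self.multiplicity[k] = self.multiplicity.get(k, 1) + 1
            else:
                self.loops.add(i)
            return
        if j in self._out[i]:
            k = self._key(i, j)
            self.multiplicity[k] = self.multiplicity.get(k, 1) + 1
            return
        self._out[i].add(j)
        self._in[j].add(i)
        self._om[i] |= 1 << j
        self._im[j] |= 1 << i
        self._m += 1

    def remove_edge(self, i: int, j: int) -> None:
        if i == j:
            self.loops.remove(i)
            return
        self._out[i].remove(j)
        self._in[j].discard(i)
        self._om[i] &= ~(1 << j)
        self._im[j] &= ~(1 << i)
        self._m -= 1

    # -- iteration / export --------------------------------------------

    def edges(self):
        """Iterate ties as tuples; undirected pairs come out as (min, max)."""
        if self.directed:
            for i, succ in enumerate(self._out):
                for j in succ:
                    yield (i, j)
        else:
            for i, succ in enumerate(self._out):
                for j in succ:
                    if i < j:
                        yield (i, j)
        for i in self.loops:
            yield (i, i)

    def edge_set(self) -> set:
        return set(self.edges())

    def copy(self) -> "Network":
        new = Network(self.n_nodes, self.directed, self.allow_loops)
        new._out = [set(s) for s in self._out]
        new._in = new._out if not self.directed else [set(s) for s in self._in]
        new._om = list(self._om)
        new._im = new._om if not self.directed else list(self._im)
        new.loops = set(self.loops)
        new._m = self._m
        new.multiplicity = dict(self.multiplicity)
        return new

    def to_numpy(self) -> np.ndarray:
        """Dense boolean adjacency matrix (loops on the diagonal)."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, succ in enumerate(self._out):
            for j in succ:
                a[i, j] = True
                if not self.directed:
                    a[j, i] = True
        for i in self.loops:
            a[i, i] = True
        return a

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges())
        return g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "directed" if self.directed else "undirected"
        return (f"<Network {kind} n={self.n_nodes} ties={self._m} "
                f"loops={len(self.loops)}>")


# ---------------------------------------------------------------------
# Node attributes
# ---------------------------------------------------------------------

@dataclass
class AttributeSet:
    """Binary and categorical node attributes.

    Binary attributes are 0/1 arrays; categorical attributes are integer
    code arrays with :data:`NA_CODE` marking a missing value.  Under the
    matching statistic NA equals nothing, not even another NA.
    """

    binary: dict[str, np.ndarray] = field(default_factory=dict)
    categorical: dict[str, np.ndarray] = field(default_factory=dict)
    categories: dict[str, list[str]] = field(default_factory=dict)

    def validate(self, n_nodes: int) -> None:
        for name, arr in self.binary.items():
            if len(arr) != n_nodes:
                raise ValueError(f"binary attribute {name!r} has wrong length")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"binary attribute {name!r} has values outside {{0,1}}")
        for name, arr in self.categorical.items():
            if len(arr) != n_nodes:
                raise ValueError(f"categorical attribute {name!r} has wrong length")

    def add_binary(self, name: str, values) -> None:
        arr = np.asarray(values, dtype=np.int8)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"binary attribute {name!r} has values outside {{0,1}}")
        self.binary[name] = arr

    def add_categorical(self, name: str, codes, categories=None) -> None:
        self.categorical[name] = np.asarray(codes, dtype=np.int64)
        if categories is not None:
            self.categories[name] = list(categories)


# ---------------------------------------------------------------------
# Readers and writers
# ---------------------------------------------------------------------

_NNODES_RE = re.compile(r"#\s*n_nodes\s*[:=]\s*(\d+)")


def _parse_id(token: str, one_based: bool, lineno: int) -> int:
    try:
        v = int(token)
    except ValueError:
        raise ValueError(f"line {lineno}: malformed node id {token!r}") from None
    if one_based:
        v -= 1
    if v < 0:
        raise ValueError(f"line {lineno}: negative node id {token!r}")
    return v


def read_edge_list(path, directed: bool, one_based: bool = False,
                   n_nodes: int | None = None) -> Network:
    """Read a whitespace-separated edge list into a (possibly multi-)network.

    Lines may carry ``#`` comments and an optional third (score) column,
    which is ignored here (see :func:`read_weighted_edge_list`).  Duplicate
    lines are recorded as multiplicities for :func:`simplify_network` to
    collapse.  A comment of the form ``# n_nodes: k`` (as written by
    :func:`write_network`) declares trailing isolated nodes; an explicit
    ``n_nodes`` argument wins over it.
    """
    pairs: list[tuple[int, int]] = []
    declared = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            m = _NNODES_RE.search(raw)
            if m and declared is None:
                declared = int(m.group(1))
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) not in (2, 3):
                raise ValueError(
                    f"line {lineno}: expected 2 node ids, got {len(tokens)} fields")
            i = _parse_id(tokens[0], one_based, lineno)
            j = _parse_id(tokens[1], one_based, lineno)
            pairs.append((i, j))
    if n_nodes is None:
        n_nodes = declared
    max_id = max((max(i, j) for i, j in pairs), default=-1)
    if n_nodes is None:
        n_nodes = max_id + 1
    elif n_nodes < max_id + 1:
        raise ValueError(f"declared n_nodes {n_nodes} smaller than max id {max_id}")
    net = Network(n_nodes, directed=directed, allow_loops=True)
    for i, j in pairs:
        net.add_edge(i, j)
    return net


def read_weighted_edge_list(path, one_based: bool = False):
    """Read ``i j score`` rows into a list of tuples for thresholding."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 3:
                raise ValueError(f"line {lineno}: expected 'i j score'")
            i = _parse_id(tokens[0], one_based, lineno)
            j = _parse_id(tokens[1], one_based, lineno)
            try:
                score = float(tokens[2])
            except ValueError:
                raise ValueError(f"line {lineno}: malformed score {tokens[2]!r}") from None
            rows.append((i, j, score))
    return rows


def read_pajek(path) -> Network:
    """Read the Pajek subset written by :func:`write_network`.

    Recognizes ``*Vertices n`` followed by optional vertex lines, then
    one ``*Arcs`` (directed) or ``*Edges`` (undirected) section of
    1-based id pairs.  The header node count wins over the maximum
    observed id, so trailing isolated nodes survive a round-trip.
    """
    n_nodes = None
    directed = None
    pairs: list[tuple[int, int]] = []
    section = "header"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                tokens = line.split()
                if len(tokens) < 2:
                    raise ValueError(f"line {lineno}: malformed *Vertices header")
                n_nodes = int(tokens[1])
                section = "vertices"
                continue
            if low.startswith("*arcs"):
                directed, section = True, "ties"
                continue
            if low.startswith("*edges"):
                directed, section = False, "ties"
                continue
            if section == "vertices":
                continue  # vertex definition lines (id "label")
            if section == "ties":
                tokens = line.split()
                if len(tokens) < 2:
                    raise ValueError(f"line {lineno}: malformed tie line")
                i = _parse_id(tokens[0], True, lineno)
                j = _parse_id(tokens[1], True, lineno)
                pairs.append((i, j))
            else:
                raise ValueError(f"line {lineno}: unexpected content before *Vertices")
    if n_nodes is None or directed is None:
        raise ValueError("missing *Vertices or *Arcs/*Edges section")
    net = Network(n_nodes, directed=directed, allow_loops=True)
    for i, j in pairs:
        net.add_edge(i, j)
    return net


def write_network(net: Network, path, format: str = "edgelist") -> None:
    """Write a network as a plain edge list or Pajek ``.net`` file.

    Both formats round-trip node count and edge set exactly through
    :func:`read_edge_list` / :func:`read_pajek`.
    """
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write(f"# n_nodes: {net.n_nodes}\n")
            for i, j in sorted(net.edge_set()):
                fh.write(f"{i} {j}\n")
    elif format == "pajek":
        with open(path, "w") as fh:
            fh.write(f"*Vertices {net.n_nodes}\n")
            for i in range(net.n_nodes):
                fh.write(f'{i + 1} "{i + 1}"\n')
            fh.write("*Arcs\n" if net.directed else "*Edges\n")
            for i, j in sorted(net.edge_set()):
                fh.write(f"{i + 1} {j + 1}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------

def simplify_network(net: Network, keep_loops: bool = False):
    """Collapse multi-edges and handle self-loops.

    Multi-edges are collapsed to single ties.  If ``keep_loops`` is false,
    loops are removed; in either case a binary "self" attribute is
    returned that is 1 exactly for nodes that had a loop, mirroring the
    treatment of self-regulation as a nodal covariate.

    Returns
    -------
    (Network, numpy.ndarray)
        The simplified network and the 0/1 self-loop indicator.
    """
    out = Network(net.n_nodes, net.directed, allow_loops=keep_loops)
    for i, succ in enumerate(net._out):
        for j in succ:
            if net.directed or i < j:
                out._out[i].add(j)
                out._in[j].add(i)
                out._om[i] |= 1 << j
                out._im[j] |= 1 << i
                out._m += 1
    self_attr = np.zeros(net.n_nodes, dtype=np.int8)
    for i in net.loops:
        self_attr[i] = 1
        if keep_loops:
            out.loops.add(i)
    return out, self_attr


def binarize_weighted_edges(rows, threshold: float, directed: bool,
                            n_nodes: int | None = None) -> Network:
    """Threshold scored edges (HIPPIE-style) into a simple binary network.

    An edge is kept iff ``score >= threshold`` (the boundary is
    inclusive).  Scores outside [0, 1] draw a warning but the row is
    still considered.  The result is simplified; loops are dropped.
    """
    if n_nodes is None:
        n_nodes = max((max(i, j) for i, j, _ in rows), default=-1) + 1
    raw = Network(n_nodes, directed=directed, allow_loops=True)
    for i, j, score in rows:
        if not (0.0 <= score <= 1.0):
            warnings.warn(f"score {score} for edge ({i},{j}) outside [0,1]; row kept")
        if score >= threshold:
            raw.add_edge(i, j)
    simplified, _ = simplify_network(raw, keep_loops=False)
    return simplified


def density(net: Network) -> float:
    """Tie density of a simplified network.

    Directed without loops: ``arcs / (n (n-1))``; undirected without
    loops: ``2 m / (n (n-1))``.  When loops are permitted the diagonal
    joins the dyad space, giving denominators ``n^2`` (directed) and
    ``n (n+1) / 2`` (undirected), with loops counted in the numerator.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("density undefined for n < 2")
    if net.directed:
        if net.allow_loops:
            return (net._m + len(net.loops)) / (n * n)
        return net._m / (n * (n - 1))
    if net.allow_loops:
        return (net._m + len(net.loops)) / (n * (n - 1) // 2 + n)
    return 2.0 * net._m / (n * (n - 1))


# ---------------------------------------------------------------------
# Attribute files (TSV: one header row of names, one row per node in id
# order, literal "NA" for missing values)
# ---------------------------------------------------------------------

def read_attributes(path, n_nodes: int | None = None) -> AttributeSet:
    """Read an attribute TSV.

    A column whose non-NA values are all 0/1 (and that has no NA) is
    treated as binary; every other column is categorical, with codes
    assigned in sorted order of the distinct values and NA mapped to
    :data:`NA_CODE`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    if n_nodes is not None and len(df) != n_nodes:
        raise ValueError(f"attribute file has {len(df)} rows, expected {n_nodes}")
    attrs = AttributeSet()
    for name in df.columns:
        col = df[name]
        values = col[col.notna()]
        if col.notna().all() and values.isin(["0", "1"]).all():
            attrs.add_binary(name, values.astype(np.int8).to_numpy())
            continue
        cats = sorted(values.unique())
        mapping = {c: k for k, c in enumerate(cats)}
        codes = np.full(len(col), NA_CODE, dtype=np.int64)
        for idx, v in enumerate(col):
            if pd.notna(v):
                codes[idx] = mapping[v]
        attrs.add_categorical(name, codes, cats)
    return attrs


def write_attributes(attrs: AttributeSet, path, n_nodes: int) -> None:
    """Write attributes to the TSV layout read by :func:`read_attributes`."""
    attrs.validate(n_nodes)
    data = {}
    for name, arr in attrs.binary.items():
        data[name] = [str(int(v)) for v in arr]
    for name, codes in attrs.categorical.items():
        cats = attrs.categories.get(name)
        vals = []
        for c in codes:
            if c == NA_CODE:
                vals.append("NA")
            else:
                vals.append(str(cats[c]) if cats is not None else str(int(c)))
        data[name] = vals
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
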