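"""Population-structure graphs: scale-free generators, degree-preserving
rewiring operators, clustering coefficient, connectivity, edge-list I/O.

Graphs are undirected simple :class:`networkx.Graph` objects whose nodes are
the integers ``0 .. N-1``.  Every rewiring operator returns a **new** graph and
leaves its input untouched, so rejected proposals need no rollback.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._kernels import local_clustering_sum

__all__ = [
    "RewireProposal",
    "generate_ba",
    "generate_hk",
    "clustering_coefficient",
    "simple_edge_swap",
    "simple_edge_swapping",
    "node_select",
    "edge_switch",
    "is_connected",
    "graph_to_arrays",
    "validate_graph",
    "read_edgelist",
    "write_edgelist",
    "degree_sequence",
]


@dataclass(frozen=True)
class RewireProposal:
    """An edge-switching move around a hub ``u``.

    ``u`` is adjacent to ``i`` and ``j``; the move removes the edges
    ``(j, k)`` and ``(i, m)`` and adds ``(j, i)`` and ``(k, m)``, which
    preserves every node's degree.  All five nodes are pairwise distinct.
    """

    u: int
    i: int
    j: int
    k: int
    m: int

    @property
    def removed(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.j, self.k), (self.i, self.m)

    @property
    def added(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.j, self.i), (self.k, self.m)

    def nodes(self) -> tuple[int, ...]:
        return (self.u, self.i, self.j, self.k, self.m)


# ---------------------------------------------------------------------------
# generators

def _grow_preferential(n: int, m_attach: int, p_triad: float,
                       rng: np.random.Generator) -> nx.Graph:
    # Seed: an m_attach-clique (a lone node for m_attach = 1), then each
    # newcomer attaches m_attach edges.  Preferential choice is implemented
    # with the repeated-endpoints list; with probability p_triad an edge after
    # the first instead closes a triangle through a neighbor of the previous
    # target (Holme-Kim triad step), falling back to preferential attachment
    # when no eligible neighbor exists.
    g = nx.empty_graph(m_attach)
    if m_attach >= 2:
        g.add_edges_from(
            (a, b) for a in range(m_attach) for b in range(a + 1, m_attach))
    repeated: list[int] = []
    for u, v in g.edges():
        repeated.append(u)
        repeated.append(v)
    for v in range(m_attach, n):
        targets: set[int] = set()
        prev_target = -1
        while len(targets) < m_attach:
            candidate = -1
            if prev_target >= 0 and len(targets) < m_attach and \
                    rng.random() < p_triad:
                nbrs = [w for w in g.neighbors(prev_target)
                        if w != v and w not in targets]
                if nbrs:
                    candidate = nbrs[int(rng.integers(len(nbrs)))]
            if candidate < 0:
                if repeated:
                    candidate = repeated[int(rng.integers(len(repeated)))]
                else:
                    candidate = int(rng.integers(g.number_of_nodes()))
                if candidate == v or candidate in targets:
                    continue
            targets.add(candidate)
            prev_target = candidate
        for t in targets:
            g.add_edge(v, t)
            repeated.append(v)
            repeated.append(t)
    return g


def generate_ba(n: int, m_attach: int, rng: np.random.Generator) -> nx.Graph:
    """Barabasi-Albert scale-free network: an ``m_attach``-clique seed grown
    by preferential attachment, each new node adding ``m_attach`` edges.
    Requires ``n > m_attach >= 1``; always connected."""
    if m_attach < 1 or n <= m_attach:
        raise ValueError(
            f"need n > m_attach >= 1, got n={n}, m_attach={m_attach}")
    return _grow_preferential(n, m_attach, 0.0, rng)


def generate_hk(n: int, m_attach: int, p_triad: float,
                rng: np.random.Generator) -> nx.Graph:
    """Holme-Kim scale-free network with tunable clustering: after each
    preferential edge, with probability ``p_triad`` the next edge closes a
    triangle through a neighbor of the last target.  ``p_triad = 0`` reduces
    exactly to :func:`generate_ba`."""
    if m_attach < 1 or n <= m_attach:
        raise ValueError(
            f"need n > m_attach >= 1, got n={n}, m_attach={m_attach}")
    if not 0.0 <= p_triad <= 1.0:
        raise ValueError(f"p_triad must be in [0, 1], got {p_triad}")
    return _grow_preferential(n, m_attach, p_triad, rng)


# ---------------------------------------------------------------------------
# measures

def graph_to_arrays(g: nx.Graph):
    """CSR adjacency (indptr, indices, degrees) with sorted neighbor lists;
    the in-memory form consumed by the simulation kernels."""
    n = g.number_of_nodes()
    degrees = np.zeros(n, dtype=np.int64)
    for v, d in g.degree():
        degrees[v] = d
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(degrees, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    for v in range(n):
        nbrs = sorted(g.neighbors(v))
        indices[indptr[v]:indptr[v + 1]] = nbrs
    return indptr, indices, degrees


def clustering_coefficient(g: nx.Graph) -> float:
    """Mean local clustering coefficient
    ``Cluster = (1/N) sum_i |E(Gamma_i)| / (d_i (d_i-1)/2)``, where
    ``Gamma_i`` is the subgraph induced by the neighbors of ``i``.  Nodes of
    degree < 2 contribute 0."""
    n = g.number_of_nodes()
    if n == 0:
        return 0.0
    indptr, indices, _ = graph_to_arrays(g)
    return local_clustering_sum(indptr, indices) / n


def is_connected(g: nx.Graph) -> bool:
    """True iff a single component spans all nodes."""
    return nx.is_connected(g)


def degree_sequence(g: nx.Graph) -> tuple[int, ...]:
    """Per-node degree vector (node id order), the quantity every rewiring
    operator must conserve."""
    return tuple(d for _, d in sorted(g.degree()))


def validate_graph(g: nx.Graph, require_connected: bool = False) -> None:
    """Raise ValueError unless g is simple with nodes 0..N-1 (and connected
    when requested)."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("graph needs at least 2 nodes")
    if set(g.nodes()) != set(range(n)):
        raise ValueError("node identifiers must be 0..N-1")
    if any(g.has_edge(v, v) for v in g.nodes()):
        raise ValueError("self-loops are not allowed")
    if require_connected and not nx.is_connected(g):
        raise ValueError("graph is not connected")


# ---------------------------------------------------------------------------
# degree-preserving rewiring

def simple_edge_swap(g: nx.Graph, rng: np.random.Generator,
                     max_tries: int = 100,
                     forced_pair=None) -> tuple[nx.Graph, bool]:
    """Double-edge swap: replace edges (a,b), (c,d) with (a,c), (b,d).

    The four endpoints must be distinct and neither new edge may pre-exist,
    so the degree sequence is conserved.  Returns ``(new_graph, True)`` on
    success, or ``(copy_of_input, False)`` if no valid swap was found within
    ``max_tries`` draws (e.g. on swap-saturated graphs such as complete
    graphs).  ``forced_pair=((a, b), (c, d))`` is a test hook that skips the
    random draw.
    """
    edges = list(g.edges())
    if len(edges) < 2:
        return g.copy(), False

    def try_pair(a, b, c, d):
        if len({a, b, c, d}) != 4:
            return None
        if g.has_edge(a, c) or g.has_edge(b, d):
            return None
        out = g.copy()
        out.remove_edge(a, b)
        out.remove_edge(c, d)
        out.add_edge(a, c)
        out.add_edge(b, d)
        return out

    if forced_pair is not None:
        (a, b), (c, d) = forced_pair
        out = try_pair(a, b, c, d)
        return (out, True) if out is not None else (g.copy(), False)

    for _ in range(max_tries):
        e1, e2 = rng.choice(len(edges), size=2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:  # both pairings of the two edges reachable
            c, d = d, c
        out = try_pair(a, b, c, d)
        if out is not None:
            return out, True
    return g.copy(), False


def simple_edge_swapping(g: nx.Graph, rng: np.random.Generator,
                         n_attempts: int,
                         require_connected: bool = True) -> nx.Graph:
    """Randomize a graph by repeated double-edge swaps (degree-preserving).

    Performs ``n_attempts`` swap attempts; a swap that would disconnect the
    graph is reverted when ``require_connected``.  Used for population
    initialization and offspring mutation.
    """
    cur = g.copy()
    for _ in range(n_attempts):
        nxt, ok = simple_edge_swap(cur, rng)
        if not ok:
            continue
        if require_connected and not nx.is_connected(nxt):
            continue
        cur = nxt
    return cur


def node_select(g: nx.Graph, rng: np.random.Generator,
                hub: int | None = None,
                max_attempts: int = 1000) -> RewireProposal | None:
    """Sample an edge-switching proposal around a hub node.

    Select ``u`` with degree >= 2 (uniform unless ``hub`` is given), two of
    its non-adjacent neighbors ``i`` and ``j`` with degree >= 2, then an edge
    ``(j, k)`` and an edge ``(i, m)`` such that all five nodes are distinct
    and neither ``(j, i)`` nor ``(k, m)`` exists.  Returns ``None`` when no
    valid tuple is found within ``max_attempts`` draws — a normal outcome,
    not an error.
    """
    if hub is None:
        hubs = [v for v in g.nodes() if g.degree(v) >= 2]
        if not hubs:
            return None
    elif g.degree(hub) < 2:
        return None
    for _ in range(max_attempts):
        u = (hub if hub is not None
             else hubs[int(rng.integers(len(hubs)))])
        nbrs = [w for w in g.neighbors(u) if g.degree(w) >= 2]
        if len(nbrs) < 2:
            if hub is not None:
                return None
            continue
        a, b = rng.choice(len(nbrs), size=2, replace=False)
        i, j = nbrs[a], nbrs[b]
        if g.has_edge(i, j):
            continue
        k_pool = [w for w in g.neighbors(j) if w != u and w != i]
        m_pool = [w for w in g.neighbors(i) if w != u and w != j]
        if not k_pool or not m_pool:
            continue
        k = k_pool[int(rng.integers(len(k_pool)))]
        m = m_pool[int(rng.integers(len(m_pool)))]
        if k == m or g.has_edge(k, m):
            continue
        return RewireProposal(u=u, i=i, j=j, k=k, m=m)
    return None


def edge_switch(g: nx.Graph, proposal: RewireProposal) -> nx.Graph:
    """Apply an edge switch: remove (j,k) and (i,m), add (j,i) and (k,m).

    Returns a new graph; the degree of every node is unchanged.  Raises
    ValueError if the proposal does not fit the graph.
    """
    if len(set(proposal.nodes())) != 5:
        raise ValueError("proposal nodes are not pairwise distinct")
    for (a, b) in proposal.removed:
        if not g.has_edge(a, b):
            raise ValueError(f"edge ({a}, {b}) to remove is absent")
    for (a, b) in proposal.added:
        if g.has_edge(a, b):
            raise ValueError(f"edge ({a}, {b}) to add already exists")
    out = g.copy()
    for (a, b) in proposal.removed:
        out.remove_edge(a, b)
    for (a, b) in proposal.added:
        out.add_edge(a, b)
    return out


# ---------------------------------------------------------------------------
# edge-list I/O

def write_edgelist(g: nx.Graph, path) -> None:
    """One ``u v`` pair per line, each pair and the list sorted, so output is
    bit-stable for a given edge set."""
    with open(path, "w") as fh:
        fh.write(f"# nodes: {g.number_of_nodes()}\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u} {v}\n")


def read_edgelist(path, require_connected: bool = False) -> nx.Graph:
    """Read a whitespace-separated 0-based integer edge list ('#' comments).

    An optional ``# nodes: N`` header preserves isolated trailing nodes;
    otherwise N is one past the largest id seen.  Validates simplicity, and
    connectivity on request.
    """
    edges = []
    declared_n = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if stripped.startswith("#"):
                if "nodes:" in stripped:
                    declared_n = int(stripped.split("nodes:")[1])
                continue
            if not stripped:
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'u v'")
            u, v = int(parts[0]), int(parts[1])
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u}")
            edges.append((u, v))
    if not edges:
        raise ValueError(f"{path}: no edges")
    n = declared_n if declared_n is not None else \
        max(max(u, v) for u, v in edges) + 1
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, v in edges:
        if g.has_edge(u, v):
            raise ValueError(f"{path}: duplicate edge ({u}, {v})")
        g.add_edge(u, v)
    validate_graph(g, require_connected=require_connected)
    return g
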