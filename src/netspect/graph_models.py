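"""Random graph generators and degree-preserving rewiring.

Five generative families — Erdős–Rényi (both the :math:`G(n,p)` and
:math:`G(n,m)` variants), random geometric on the unit square, random
k-regular, Watts–Strogatz, and clique-seeded preferential attachment —
plus a Maslov–Sneppen style double-edge-swap perturbation ("Markov
random switching") that randomizes a graph while conserving its size,
edge count, and degree sequence.

All generators return immutable :class:`Graph` objects and draw every
random number from a single ``numpy.random.Generator``, so identical
seeds give identical edge sets and no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Tuple

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "Graph",
    "PairingFailedError",
    "RewireInfeasibleError",
    "erdos_renyi_gnp",
    "erdos_renyi_gnm",
    "geometric_graph",
    "k_regular",
    "watts_strogatz",
    "preferential_attachment",
    "markov_rewire",
]


class RewireInfeasibleError(RuntimeError):
    """No legal double-edge swap could be proposed within the proposal cap.

    Attributes
    ----------
    swaps_completed : int
        Number of swaps successfully applied before giving up.
    """

    def __init__(self, message: str, swaps_completed: int):
        super().__init__(message)
        self.swaps_completed = swaps_completed


class PairingFailedError(RuntimeError):
    """The k-regular sampler failed to produce a simple graph."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph with 0-based integer vertex ids.

    Edges are stored once as canonical ``(i, j)`` tuples with ``i < j``.
    Self-loops, duplicate edges, and out-of-range ids are rejected at
    construction time, so every ``Graph`` in the library satisfies the
    simple-graph invariants by fiat.
    """

    n_vertices: int
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if int(self.n_vertices) < 1:
            raise ValueError("graph needs at least one vertex")
        object.__setattr__(self, "n_vertices", int(self.n_vertices))
        canon = set()
        for e in self.edges:
            i, j = int(e[0]), int(e[1])
            if i == j:
                raise ValueError(f"self-loop at vertex {i}")
            if not (0 <= i < self.n_vertices and 0 <= j < self.n_vertices):
                raise ValueError(f"edge ({i}, {j}) outside [0, {self.n_vertices})")
            canon.add((i, j) if i < j else (j, i))
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        a = np.zeros((self.n_vertices, self.n_vertices))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def edge_array(self) -> np.ndarray:
        """Edges as a sorted ``(m, 2)`` integer array (canonical order)."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    @classmethod
    def from_edges(cls, n_vertices: int, edges: Iterable[Tuple[int, int]]) -> "Graph":
        return cls(n_vertices, frozenset(tuple(e) for e in edges))

    @classmethod
    def from_adjacency(cls, a: np.ndarray, symmetrize: bool = True) -> "Graph":
        a = np.asarray(a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if symmetrize:
            a = np.maximum(a, a.T)
        ii, jj = np.nonzero(np.triu(a, 1))
        return cls.from_edges(a.shape[0], zip(ii.tolist(), jj.tolist()))

    def to_networkx(self) -> "nx.Graph":
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: "nx.Graph") -> "Graph":
        try:  # GraphML yields string ids; order them numerically when possible
            nodes = sorted(g.nodes(), key=int)
        except (TypeError, ValueError):
            nodes = sorted(g.nodes(), key=str)
        index = {v: i for i, v in enumerate(nodes)}
        return cls.from_edges(
            g.number_of_nodes(),
            ((index[u], index[v]) for u, v in g.edges() if u != v),
        )


def _pair_index(n: int):
    """Row/column indices of the C(n,2) vertex pairs in canonical order."""
    return np.triu_indices(n, k=1)


def erdos_renyi_gnp(n: int, p: float, seed=None) -> Graph:
    """Erdős–Rényi :math:`G(n, p)`: each vertex pair is an edge w.p. ``p``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    rng = _as_rng(seed)
    rows, cols = _pair_index(n)
    mask = rng.random(rows.size) < p
    return Graph.from_edges(n, zip(rows[mask].tolist(), cols[mask].tolist()))


def erdos_renyi_gnm(n: int, m: int, seed=None) -> Graph:
    """Erdős–Rényi :math:`G(n, m)`: exactly ``m`` uniformly sampled edges."""
    if n < 1:
        raise ValueError("n must be >= 1")
    total = n * (n - 1) // 2
    if not (0 <= m <= total):
        raise ValueError(f"m must lie in [0, {total}] for n={n}")
    rng = _as_rng(seed)
    rows, cols = _pair_index(n)
    idx = rng.choice(total, size=m, replace=False)
    return Graph.from_edges(n, zip(rows[idx].tolist(), cols[idx].tolist()))


def geometric_graph(n: int, r: float, seed=None) -> Graph:
    """Random geometric graph: uniform points in the unit square,
    edge iff Euclidean distance strictly below ``r`` (dimension fixed at 2)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if r < 0:
        raise ValueError("radius must be nonnegative")
    rng = _as_rng(seed)
    pts = rng.random((n, 2))
    if n == 1:
        return Graph.from_edges(1, [])
    rows, cols = _pair_index(n)
    mask = pdist(pts) < r
    return Graph.from_edges(n, zip(rows[mask].tolist(), cols[mask].tolist()))


def k_regular(n: int, k: int, seed=None) -> Graph:
    """Random k-regular graph (every vertex has degree exactly ``k``).

    Sampling delegates to :func:`networkx.random_regular_graph`, a
    configuration-model algorithm with suitable-pair search; unlike naive
    whole-pairing rejection it remains practical at large ``k`` (the
    simulations here need k=20).
    """
    if not (0 <= k < n):
        raise ValueError("k must satisfy 0 <= k < n")
    if (n * k) % 2 != 0:
        raise PairingFailedError(f"n*k = {n * k} is odd: no k-regular graph exists")
    if k == 0:
        return Graph.from_edges(n, [])
    rng = _as_rng(seed)
    try:
        g = nx.random_regular_graph(k, n, seed=rng)
    except nx.NetworkXError as exc:  # pragma: no cover - infeasible inputs
        raise PairingFailedError(str(exc)) from exc
    return Graph.from_networkx(g)


def watts_strogatz(n: int, k: int, p: float, seed=None) -> Graph:
    """Watts–Strogatz small-world graph.

    Starts from the ring lattice joining each vertex to its ``k`` nearest
    neighbors (``k/2`` per side).  Each lattice edge ``(i, j)``, scanned in
    canonical order (source vertex, then offset), is replaced with
    probability ``p`` by ``(i, l)`` with ``l`` uniform among vertices,
    rejecting self-loops and duplicates.  The edge count ``n*k/2`` is
    conserved for every ``p``.
    """
    if k % 2 != 0:
        raise ValueError("k must be even")
    if not (0 < k < n):
        raise ValueError("k must satisfy 0 < k < n")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    rng = _as_rng(seed)

    def canon(a, b):
        return (a, b) if a < b else (b, a)

    lattice = []
    for i in range(n):
        for d in range(1, k // 2 + 1):
            lattice.append((i, (i + d) % n))
    eset = {canon(i, j) for i, j in lattice}
    for i, j in lattice:
        if rng.random() >= p:
            continue
        # bounded retry: a vertex adjacent to everything keeps its edge
        for _ in range(8 * n):
            l = int(rng.integers(n))
            if l == i or l == j:
                continue
            if canon(i, l) in eset:
                continue
            eset.discard(canon(i, j))
            eset.add(canon(i, l))
            break
    return Graph.from_edges(n, eset)


def preferential_attachment(n: int, m: int, ps: float, seed=None) -> Graph:
    """Clique-seeded preferential attachment with attachment exponent ``ps``.

    Starts from an ``m``-clique; each new vertex attaches to ``m`` distinct
    existing vertices sampled with probability proportional to
    ``degree**ps``.  The clique start guarantees every existing vertex has
    positive degree whenever ``m >= 2``; in the degenerate ``m = 1`` case
    (single seed vertex of degree 0) the first target is drawn uniformly.
    """
    if not (1 <= m <= n):
        raise ValueError("m must satisfy 1 <= m <= n")
    rng = _as_rng(seed)
    edges = [(i, j) for i in range(m) for j in range(i + 1, m)]
    deg = np.zeros(n, dtype=np.float64)
    deg[:m] = m - 1
    for v in range(m, n):
        w = deg[:v] ** ps
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            probs = None  # uniform fallback (only reachable when m == 1)
        else:
            probs = w / total
        targets = rng.choice(v, size=m, replace=False, p=probs)
        for t in targets:
            edges.append((int(t), v))
            deg[t] += 1
            deg[v] += 1
    return Graph.from_edges(n, edges)


def markov_rewire(g: Graph, n_swaps: int, seed=None) -> Graph:
    """Degree-preserving randomization by double-edge swaps.

    Repeatedly picks two edges ``(i1, j1), (i2, j2)`` with four distinct
    endpoints and rewires them to ``(i1, j2), (i2, j1)``, rejecting any
    proposal that would create an existing edge.  Exactly ``n_swaps``
    successful swaps are applied; size, edge count, and the degree
    sequence are conserved exactly.

    Raises
    ------
    RewireInfeasibleError
        If ``100 * n_swaps`` proposals are exhausted before completing
        (e.g. complete graphs admit no legal swap).  The exception carries
        the number of swaps completed.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be nonnegative")
    if n_swaps == 0:
        return g
    rng = _as_rng(seed)
    edges = [tuple(e) for e in sorted(g.edges)]
    eset = set(edges)
    if len(edges) < 2:
        raise RewireInfeasibleError("fewer than two edges: no swap possible", 0)
    max_proposals = 100 * n_swaps
    done = 0
    proposals = 0
    while done < n_swaps:
        if proposals >= max_proposals:
            raise RewireInfeasibleError(
                f"exhausted {max_proposals} proposals after {done} of "
                f"{n_swaps} swaps",
                done,
            )
        proposals += 1
        a, b = rng.integers(0, len(edges), size=2)
        if a == b:
            continue
        i1, j1 = edges[a]
        i2, j2 = edges[b]
        if rng.random() < 0.5:
            i1, j1 = j1, i1
        if rng.random() < 0.5:
            i2, j2 = j2, i2
        if len({i1, j1, i2, j2}) < 4:
            continue
        e1 = (i1, j2) if i1 < j2 else (j2, i1)
        e2 = (i2, j1) if i2 < j1 else (j1, i2)
        if e1 in eset or e2 in eset:
            continue
        old1 = (i1, j1) if i1 < j1 else (j1, i1)
        old2 = (i2, j2) if i2 < j2 else (j2, i2)
        eset.discard(old1)
        eset.discard(old2)
        eset.add(e1)
        eset.add(e2)
        edges[a] = e1
        edges[b] = e2
        done += 1
    return Graph.from_edges(g.n_vertices, eset)
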