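"""Non-semantic word-trajectory graphs and their 14 connectivity measures.

Each window of running speech is turned into a directed multigraph whose
nodes are the unique words of the window and whose edges are the consecutive
word transitions, in order.  The connectivity statistics quantify short-range
recurrence (self-loops, 2- and 3-cycles, repeated and parallel edges) and
long-range recurrence (largest weakly/strongly connected components, paths),
which together proxy narrative planning.

Verbosity is controlled by computing the measures on fixed-size sliding
windows (default 30 words, step 15) and averaging across windows, and a
random-shuffle null (default 100 word permutations of the whole excerpt)
provides per-measure z-scores against structureless word order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GRAPH_MEASURES",
    "GraphConfig",
    "WordGraph",
    "GraphMeasures",
    "DegenerateWindowError",
    "build_graph",
    "graph_measures",
    "iter_windows",
    "windowed_measures",
    "shuffle_null",
    "ShuffleNull",
]

#: Canonical order of the 14 connectivity measures.
GRAPH_MEASURES = (
    "nodes",
    "edges",
    "repeated_edges",
    "parallel_edges",
    "l1",
    "l2",
    "l3",
    "lcc",
    "lsc",
    "average_total_degree",
    "density",
    "diameter",
    "average_shortest_path",
    "average_clustering_coefficient",
)


class DegenerateWindowError(ValueError):
    """A window of fewer than two tokens has no edge and no graph."""


@dataclass(frozen=True)
class GraphConfig:
    window_size: int = 30
    window_step: int = 15
    n_shuffles: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.window_step <= self.window_size:
            raise ValueError("require 0 < window_step <= window_size")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


@dataclass
class WordGraph:
    """Directed multigraph over one token window."""

    words: list[str]
    src: np.ndarray  # edge source node ids, length = window tokens - 1
    dst: np.ndarray  # edge target node ids

    @property
    def n_nodes(self) -> int:
        return len(self.words)

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def edge_list(self) -> list[tuple[str, str]]:
        return [(self.words[s], self.words[d]) for s, d in zip(self.src, self.dst)]


@dataclass
class GraphMeasures:
    nodes: float
    edges: float
    repeated_edges: float
    parallel_edges: float
    l1: float
    l2: float
    l3: float
    lcc: float
    lsc: float
    average_total_degree: float
    density: float
    diameter: float
    average_shortest_path: float
    average_clustering_coefficient: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GRAPH_MEASURES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in GRAPH_MEASURES])

    @classmethod
    def from_array(cls, values: np.ndarray) -> "GraphMeasures":
        return cls(**dict(zip(GRAPH_MEASURES, map(float, values))))


def build_graph(tokens: Sequence[str]) -> WordGraph:
    """One node per unique token, one directed multi-edge per adjacent pair."""
    if len(tokens) < 2:
        raise DegenerateWindowError(f"need >= 2 tokens, got {len(tokens)}")
    index: dict[str, int] = {}
    ids = np.empty(len(tokens), dtype=np.intp)
    for i, tok in enumerate(tokens):
        j = index.get(tok)
        if j is None:
            j = len(index)
            index[tok] = j
        ids[i] = j
    return WordGraph(words=list(index), src=ids[:-1], dst=ids[1:])


def _largest_weak_component(n: int, esrc: np.ndarray, edst: np.ndarray) -> int:
    """Size of the largest component of the undirected projection (union-find)."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s, d in zip(esrc.tolist(), edst.tolist()):
        rs, rd = find(s), find(d)
        if rs != rd:
            parent[rs] = rd
    sizes: dict[int, int] = {}
    for x in range(n):
        r = find(x)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values())


def _largest_strong_component(n: int, adj: list[list[int]]) -> int:
    """Size of the largest strongly connected component (iterative Tarjan)."""
    index = [-1] * n
    low = [0] * n
    on_stack = [False] * n
    stack: list[int] = []
    best = 1
    counter = 0
    for root in range(n):
        if index[root] != -1:
            continue
        work = [(root, 0)]
        while work:
            v, pi = work[-1]
            if pi == 0:
                index[v] = low[v] = counter
                counter += 1
                stack.append(v)
                on_stack[v] = True
            recurse = False
            for i in range(pi, len(adj[v])):
                w = adj[v][i]
                if index[w] == -1:
                    work[-1] = (v, i + 1)
                    work.append((w, 0))
                    recurse = True
                    break
                if on_stack[w] and index[w] < low[v]:
                    low[v] = index[w]
            if recurse:
                continue
            work.pop()
            if low[v] == index[v]:
                size = 0
                while True:
                    w = stack.pop()
                    on_stack[w] = False
                    size += 1
                    if w == v:
                        break
                if size > best:
                    best = size
            if work:
                u = work[-1][0]
                if low[v] < low[u]:
                    low[u] = low[v]
    return best


def _measures_array(g: WordGraph) -> np.ndarray:
    n = g.n_nodes
    e = g.n_edges

    # multigraph adjacency (edge multiplicities)
    multi = np.bincount(g.src * n + g.dst, minlength=n * n).reshape(n, n)
    binary = multi > 0

    distinct = int(binary.sum())
    repeated = e - distinct
    l1 = int(np.trace(multi))  # immediate word repeats = multigraph self-loops

    simple = binary.copy()
    np.fill_diagonal(simple, False)
    parallel = int(np.triu(simple & simple.T, k=1).sum())

    a = simple.astype(np.float64)
    a2 = a @ a
    l2 = np.trace(a2) / 2.0
    l3 = np.trace(a2 @ a) / 3.0

    if n == 1:
        lcc = lsc = 1
        density = diameter = asp = cc = 0.0
    else:
        esrc, edst = np.nonzero(simple)
        adj: list[list[int]] = [[] for _ in range(n)]
        for s, d in zip(esrc.tolist(), edst.tolist()):
            adj[s].append(d)
        lcc = _largest_weak_component(n, esrc, edst)
        lsc = _largest_strong_component(n, adj)

        # self-loop-free directed simple graph: E_simple / N(N-1)
        density = float(len(esrc)) / (n * (n - 1))

        # unweighted all-pairs shortest paths (Floyd-Warshall, vectorized)
        dist = np.where(simple, 1.0, np.inf)
        np.fill_diagonal(dist, 0.0)
        for k in range(n):
            np.minimum(dist, dist[:, k, None] + dist[None, k, :], out=dist)
        np.fill_diagonal(dist, np.inf)
        finite = dist[np.isfinite(dist)]
        if finite.size:
            diameter = float(finite.max())
            asp = float(finite.mean())
        else:
            diameter = asp = 0.0

        u = (simple | simple.T).astype(np.float64)
        deg = u.sum(axis=1)
        triangles = ((u @ u) * u).sum(axis=1) / 2.0
        possible = deg * (deg - 1) / 2.0
        local = np.divide(triangles, possible, out=np.zeros(n), where=possible > 0)
        cc = float(local.mean())

    atd = 2.0 * e / n
    return np.array(
        [n, e, repeated, parallel, l1, l2, l3, lcc, lsc, atd, density, diameter, asp, cc]
    )


def graph_measures(g: WordGraph) -> GraphMeasures:
    """All 14 connectivity measures of one window graph.

    LCC is computed on the undirected projection, LSC by strongly connected
    component decomposition; diameter and average shortest path run over the
    reachable ordered node pairs of the directed simple graph (unreachable
    pairs ignored); the clustering coefficient is the mean undirected local
    clustering; density excludes self-loops.
    """
    return GraphMeasures.from_array(_measures_array(g))


def iter_windows(tokens: Sequence[str], cfg: GraphConfig) -> list[Sequence[str]]:
    """Fixed-size windows starting at multiples of ``window_step``.

    A transcript shorter than one window is analyzed as a single window;
    trailing tokens beyond the last full window are dropped otherwise, so
    every analyzed window has exactly ``window_size`` tokens.
    """
    n = len(tokens)
    if n < cfg.window_size:
        return [tokens]
    starts = range(0, n - cfg.window_size + 1, cfg.window_step)
    return [tokens[s : s + cfg.window_size] for s in starts]


def _windowed_array(tokens: Sequence[str], cfg: GraphConfig) -> np.ndarray:
    if len(tokens) < 2:
        raise DegenerateWindowError("transcript has fewer than 2 tokens")
    rows = [_measures_array(build_graph(w)) for w in iter_windows(tokens, cfg)]
    return np.mean(rows, axis=0)


def windowed_measures(tokens: Sequence[str], cfg: GraphConfig | None = None) -> GraphMeasures:
    """Arithmetic mean of each measure across sliding windows."""
    cfg = cfg or GraphConfig()
    return GraphMeasures.from_array(_windowed_array(tokens, cfg))


@dataclass
class ShuffleNull:
    """Random-shuffle null distribution of the windowed measures.

    ``z`` is (observed − null mean) / null SD, NaN where the null SD is 0
    (the statistic is permutation-invariant there, e.g. node and edge counts
    of a whole-sequence window).
    """

    observed: GraphMeasures
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    z: dict[str, float]
    n_shuffles: int
    samples: np.ndarray = field(repr=False, default=None)


def shuffle_null(tokens: Sequence[str], cfg: GraphConfig | None = None) -> ShuffleNull:
    """Compare observed windowed measures with word-shuffled surrogates.

    The whole excerpt token sequence is permuted uniformly at random
    (seeded), then windowed exactly like the observed sequence.
    """
    cfg = cfg or GraphConfig()
    observed = _windowed_array(tokens, cfg)
    rng = np.random.default_rng(cfg.rng_seed)
    toks = np.asarray(tokens, dtype=object)
    samples = np.empty((cfg.n_shuffles, len(GRAPH_MEASURES)))
    for i in range(cfg.n_shuffles):
        samples[i] = _windowed_array(list(rng.permutation(toks)), cfg)
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1) if cfg.n_shuffles > 1 else np.zeros(len(GRAPH_MEASURES))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (observed - mean) / sd, np.nan)
    names = GRAPH_MEASURES
    return ShuffleNull(
        observed=GraphMeasures.from_array(observed),
        null_mean=dict(zip(names, map(float, mean))),
        null_sd=dict(zip(names, map(float, sd))),
        z=dict(zip(names, map(float, z))),
        n_shuffles=cfg.n_shuffles,
        samples=samples,
    )
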