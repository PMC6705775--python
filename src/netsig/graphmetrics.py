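"""Weighted graph-theoretic baseline metrics.

Five per-network scalars used as the comparison feature set:

* weighted clustering coefficient ``C^w`` (geometric-mean triangle form),
* weighted characteristic path length ``L^w`` (lengths = 1/weight),
* weighted global efficiency ``E^w``,
* small-world parameter ``σ = (C/C_rand)/(L/L_rand)`` against
  density-matched Erdős–Rényi surrogates,
* small-world propensity ``SWP = 1 - sqrt((ΔC² + ΔL²)/2)`` against
  matched lattice and degree-preserving random null models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .graph import GraphValidationError, WeightedGraph

__all__ = [
    "GraphMetricSet",
    "InfinitePathError",
    "UndefinedSWPError",
    "clustering_w",
    "path_length_w",
    "global_efficiency_w",
    "small_world",
    "swp",
    "metric_set",
]


class InfinitePathError(ValueError):
    """Characteristic path length is infinite on a disconnected graph."""


class UndefinedSWPError(ValueError):
    """Lattice and random nulls are indistinguishable; SWP is undefined."""


def _shortest_lengths(g: WeightedGraph) -> np.ndarray:
    """All-pairs shortest weighted path lengths with edge length 1/weight."""
    w = g.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def clustering_w(g: WeightedGraph) -> float:
    """Mean weighted clustering coefficient (geometric-mean triangles).

    Weights are rescaled by the maximum weight first; nodes of degree
    < 2 contribute zero.  Reduces to the binary clustering coefficient on
    0/1 graphs.
    """
    w = g.weights
    if w.max() > 0:
        w = w / w.max()
    cbrt = np.cbrt(w)
    t = np.diag(cbrt @ cbrt @ cbrt) / 2.0
    k = g.degrees()
    denom = k * (k - 1)
    per_node = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1), 0.0)
    return float(per_node.mean())


def path_length_w(g: WeightedGraph) -> float:
    """Characteristic path length: mean shortest weighted path over ordered pairs."""
    if g.n_nodes < 2:
        raise GraphValidationError("path length needs at least 2 nodes")
    d = _shortest_lengths(g)
    iu = ~np.eye(g.n_nodes, dtype=bool)
    if np.any(np.isinf(d[iu])):
        raise InfinitePathError(
            "graph is disconnected; characteristic path length is infinite "
            "(use global efficiency instead)"
        )
    return float(d[iu].mean())


def global_efficiency_w(g: WeightedGraph) -> float:
    """Mean inverse shortest weighted path length; disconnected pairs count 0."""
    if g.n_nodes < 2:
        return 0.0
    d = _shortest_lengths(g)
    iu = ~np.eye(g.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(d[iu] > 0, 1.0 / d[iu], 0.0)
    inv[np.isinf(d[iu])] = 0.0
    return float(inv.mean())


def _gnm_surrogate(g: WeightedGraph, rng: np.random.Generator) -> WeightedGraph:
    """ER surrogate with the same node count and edge count, carrying a
    shuffled copy of the original weight multiset; retried until connected."""
    n, m = g.n_nodes, g.n_edges
    weights = np.array([w for _, _, w in g.edge_list()])
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    for _ in range(100):
        pick = rng.choice(n_pairs, size=m, replace=False)
        w = np.zeros((n, n))
        w[iu[0][pick], iu[1][pick]] = rng.permutation(weights)
        cand = WeightedGraph(w + w.T, is_binary=g.is_binary)
        if cand.is_connected():
            return cand
    raise GraphValidationError("could not draw a connected ER surrogate")


def small_world(g: WeightedGraph, n_reference: int = 20, seed: int = 0) -> float:
    """Small-world parameter σ = (C/C_rand) / (L/L_rand).

    The reference values are means over ``n_reference`` Erdős–Rényi
    surrogates matched in node count and edge count, with the observed
    weight multiset shuffled onto the random topology.
    """
    if n_reference < 1:
        raise GraphValidationError("n_reference must be positive")
    g.require_connected("the small-world parameter")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    c_rand = np.empty(n_reference)
    l_rand = np.empty(n_reference)
    for i in range(n_reference):
        s = _gnm_surrogate(g, rng)
        c_rand[i] = clustering_w(s)
        l_rand[i] = path_length_w(s)
    return float(
        (clustering_w(g) / c_rand.mean()) / (path_length_w(g) / l_rand.mean())
    )


def _lattice_null(g: WeightedGraph) -> WeightedGraph:
    """Ring lattice matched in node and edge count; the strongest observed
    weights are placed on the shortest circular distances."""
    n, m = g.n_nodes, g.n_edges
    # enumerate pairs by circular distance, then by node index
    slots: list[tuple[int, int]] = []
    for dist in range(1, n // 2 + 1):
        seen = set()
        for i in range(n):
            j = (i + dist) % n
            e = (min(i, j), max(i, j))
            if e not in seen:
                seen.add(e)
                slots.append(e)
        if len(slots) >= m:
            break
    if len(slots) < m:
        raise GraphValidationError("too many edges for a simple lattice null")
    weights = np.sort([w for _, _, w in g.edge_list()])[::-1]
    w = np.zeros((n, n))
    for (i, j), wt in zip(slots[:m], weights):
        w[i, j] = w[j, i] = wt
    return WeightedGraph(w, is_binary=g.is_binary)


def _rewired_null(g: WeightedGraph, rng: np.random.Generator) -> WeightedGraph:
    """Degree-preserving randomized null, redrawn until connected."""
    for _ in range(100):
        cand = _rewire_once(g, rng)
        if cand.is_connected():
            return cand
    raise GraphValidationError("could not draw a connected degree-preserving null")


def _rewire_once(g: WeightedGraph, rng: np.random.Generator) -> WeightedGraph:
    """One degree-preserving double-edge-swap randomization (10·|E| attempted
    swaps) with the weight multiset shuffled onto the rewired topology."""
    edges = [(i, j) for i, j, _ in g.edge_list()]
    weights = np.array([w for _, _, w in g.edge_list()])
    m = len(edges)
    present = set(edges)
    for _ in range(10 * m):
        a, b = rng.integers(m), rng.integers(m)
        if a == b:
            continue
        (u, v), (x, y) = edges[a], edges[b]
        if rng.random() < 0.5:
            x, y = y, x
        e1 = (min(u, x), max(u, x))
        e2 = (min(v, y), max(v, y))
        if e1[0] == e1[1] or e2[0] == e2[1] or e1 in present or e2 in present:
            continue
        present.discard(edges[a])
        present.discard(edges[b])
        present.add(e1)
        present.add(e2)
        edges[a], edges[b] = e1, e2
    w = np.zeros((g.n_nodes, g.n_nodes))
    perm = rng.permutation(weights)
    for (i, j), wt in zip(edges, perm):
        w[i, j] = w[j, i] = wt
    return WeightedGraph(w, is_binary=g.is_binary)


def swp(g: WeightedGraph, n_reference: int = 20, seed: int = 0) -> float:
    """Small-world propensity ``1 - sqrt((ΔC² + ΔL²)/2)``.

    ``ΔC = (C_lat - C)/(C_lat - C_rand)`` and
    ``ΔL = (L - L_rand)/(L_lat - L_rand)``, each clamped to [0, 1];
    the lattice null is a matched ring lattice with the strongest
    weights on the shortest lattice distances, the random null a
    degree-preserving rewiring, both averaged over ``n_reference``
    random draws.
    """
    if n_reference < 1:
        raise GraphValidationError("n_reference must be positive")
    g.require_connected("small-world propensity")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    lat = _lattice_null(g)
    c_lat, l_lat = clustering_w(lat), path_length_w(lat)
    c_rand = np.empty(n_reference)
    l_rand = np.empty(n_reference)
    for i in range(n_reference):
        null = _rewired_null(g, rng)
        c_rand[i] = clustering_w(null)
        l_rand[i] = path_length_w(null)
    c_r, l_r = c_rand.mean(), l_rand.mean()
    if abs(c_lat - c_r) < 1e-12 or abs(l_lat - l_r) < 1e-12:
        raise UndefinedSWPError(
            "lattice and random nulls coincide; SWP is undefined for this graph"
        )
    dc = np.clip((c_lat - clustering_w(g)) / (c_lat - c_r), 0.0, 1.0)
    dl = np.clip((path_length_w(g) - l_r) / (l_lat - l_r), 0.0, 1.0)
    return float(1.0 - np.sqrt((dc**2 + dl**2) / 2.0))


@dataclass(frozen=True)
class GraphMetricSet:
    """The five graph-theoretic features of one network."""

    clustering: float
    path_length: float
    efficiency: float
    small_world: float
    swp: float

    def as_dict(self) -> dict[str, float]:
        return {
            "clustering": self.clustering,
            "path_length": self.path_length,
            "efficiency": self.efficiency,
            "small_world": self.small_world,
            "swp": self.swp,
        }


def metric_set(g: WeightedGraph, n_reference: int = 20, seed: int = 0) -> GraphMetricSet:
    """All five metrics of one network (one feature row)."""
    return GraphMetricSet(
        clustering=clustering_w(g),
        path_length=path_length_w(g),
        efficiency=global_efficiency_w(g),
        small_world=small_world(g, n_reference, seed),
        swp=swp(g, n_reference, seed),
    )
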