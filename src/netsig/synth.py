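"""Synthetic network generators.

Implements the random-network families used in the simulation study
(ring lattices, Erdős–Rényi graphs, Watts–Strogatz small-world graphs,
weighted stochastic block models) and a two-class ensemble of weighted
networks that stands in for error-trial vs correct-trial connectivity
networks.

Weight convention: when a generator is asked for a weighted graph it
draws i.i.d. uniform(0, 1] weights on the existing edges — the one weight
law stated for the weighted stochastic block model — so PLV-like weights
stay in (0, 1].  Reproducibility: every generator is deterministic in its
``seed``; topology and weight streams are derived from independent
children of the seed so that ``make_small_world(p_rewire=0)`` is
bit-identical to ``make_k_regular`` at the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import GraphValidationError, WeightedGraph

__all__ = [
    "BlockSpec",
    "make_k_regular",
    "make_erdos_renyi",
    "make_small_world",
    "make_weighted_sbm",
    "make_two_class_ensemble",
]

_TOPOLOGY_STREAM = 0
_WEIGHT_STREAM = 1
_RETRY_SALT = 7919  # distinct stream for connectivity retries


@dataclass(frozen=True)
class BlockSpec:
    """Specification of a stochastic block model.

    ``membership[i]`` is the block label of node *i* (labels 0..K-1, every
    block non-empty); ``connect_probs`` is the symmetric K×K matrix of
    attachment probabilities.
    """

    membership: np.ndarray
    connect_probs: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.membership, dtype=int)
        p = np.asarray(self.connect_probs, dtype=float)
        if z.ndim != 1 or z.size == 0:
            raise GraphValidationError("membership must be a non-empty 1-d vector")
        k = p.shape[0]
        if p.ndim != 2 or p.shape != (k, k):
            raise GraphValidationError("connect_probs must be square")
        if not np.allclose(p, p.T):
            raise GraphValidationError("connect_probs must be symmetric")
        if np.any(p < 0) or np.any(p > 1):
            raise GraphValidationError("connect_probs entries must lie in [0, 1]")
        if z.min() < 0 or z.max() >= k:
            raise GraphValidationError(
                "membership labels must index rows of connect_probs"
            )
        if len(np.unique(z)) != k:
            raise GraphValidationError("every block must be non-empty")
        object.__setattr__(self, "membership", z)
        object.__setattr__(self, "connect_probs", p)

    @property
    def n_nodes(self) -> int:
        return self.membership.size

    @property
    def n_blocks(self) -> int:
        return self.connect_probs.shape[0]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _weighted(adj: np.ndarray, seed: int) -> np.ndarray:
    """Assign uniform(0, 1] weights to the edges of a binary adjacency.

    Weights are drawn in lexicographic edge order (i < j) so two graphs
    with identical topology and seed receive identical weights.
    """
    rng = _rng(seed, _WEIGHT_STREAM)
    w = adj.astype(float)
    ii, jj = np.nonzero(np.triu(adj, k=1))
    draws = 1.0 - rng.random(ii.size)  # (0, 1]
    w[ii, jj] = draws
    w[jj, ii] = draws
    return w


def _finish(adj: np.ndarray, weighted: bool, seed: int) -> WeightedGraph:
    if weighted:
        return WeightedGraph(_weighted(adj, seed), is_binary=False)
    return WeightedGraph(adj.astype(float), is_binary=True)


def _retry_connected(build, seed: int, require_connected: bool, max_tries: int = 100):
    g = build(seed)
    if not require_connected:
        return g
    if g.is_connected():
        return g
    for attempt in range(1, max_tries):
        derived = int(
            np.random.SeedSequence([int(seed), _RETRY_SALT, attempt]).generate_state(1)[0]
            % (2**31)
        )
        g = build(derived)
        if g.is_connected():
            return g
    raise GraphValidationError(
        f"could not generate a connected graph in {max_tries} attempts"
    )


def _ring_adjacency(n: int, k: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for offset in range(1, k // 2 + 1):
        adj[idx, (idx + offset) % n] = True
        adj[idx, (idx - offset) % n] = True
    return adj


def _check_ring_params(n: int, k: int) -> None:
    if k <= 0 or k >= n or k % 2 != 0:
        raise GraphValidationError(
            f"ring lattice needs an even degree k with 0 < k < n; got n={n}, k={k}"
        )


def make_k_regular(
    n: int, k: int, weighted: bool = False, seed: int = 0
) -> WeightedGraph:
    """Ring lattice: node i connects to its k/2 nearest neighbours each way."""
    _check_ring_params(n, k)
    return _finish(_ring_adjacency(n, k), weighted, seed)


def make_erdos_renyi(
    n: int,
    p: float,
    weighted: bool = False,
    seed: int = 0,
    require_connected: bool = False,
) -> WeightedGraph:
    """Erdős–Rényi G(n, p): each pair connected independently with probability p."""
    if not 0.0 <= p <= 1.0:
        raise GraphValidationError(f"attachment probability must be in [0, 1], got {p}")

    def build(s: int) -> WeightedGraph:
        rng = _rng(s, _TOPOLOGY_STREAM)
        upper = np.triu(rng.random((n, n)) < p, k=1)
        return _finish(upper | upper.T, weighted, s)

    return _retry_connected(build, seed, require_connected)


def make_small_world(
    n: int,
    k: int,
    p_rewire: float,
    weighted: bool = False,
    seed: int = 0,
    require_connected: bool = False,
) -> WeightedGraph:
    """Watts–Strogatz small-world graph.

    Starts from the k-regular ring lattice and rewires the far endpoint of
    each lattice edge independently with probability ``p_rewire`` to a
    uniformly random node, rejecting self-loops and duplicate edges.  The
    edge count is conserved.  With ``p_rewire == 0`` the result equals
    :func:`make_k_regular` exactly.
    """
    _check_ring_params(n, k)
    if not 0.0 <= p_rewire <= 1.0:
        raise GraphValidationError("p_rewire must be in [0, 1]")

    def build(s: int) -> WeightedGraph:
        rng = _rng(s, _TOPOLOGY_STREAM)
        adj = _ring_adjacency(n, k)
        # classic Watts–Strogatz order: offsets first, nodes within offset
        for offset in range(1, k // 2 + 1):
            for i in range(n):
                j = (i + offset) % n
                if rng.random() >= p_rewire:
                    continue
                new = int(rng.integers(n))
                tries = 0
                while (new == i or adj[i, new]) and tries < 8 * n:
                    new = int(rng.integers(n))
                    tries += 1
                if new == i or adj[i, new]:
                    continue  # node saturated; keep the lattice edge
                adj[i, j] = adj[j, i] = False
                adj[i, new] = adj[new, i] = True
        return _finish(adj, weighted, s)

    return _retry_connected(build, seed, require_connected)


def make_weighted_sbm(spec: BlockSpec, seed: int = 0) -> WeightedGraph:
    """Weighted stochastic block model.

    Edge (i, j) is present with probability ``connect_probs[z_i, z_j]``;
    present edges carry uniform(0, 1] weights.
    """
    z = spec.membership
    n = spec.n_nodes
    rng = _rng(seed, _TOPOLOGY_STREAM)
    pair_p = spec.connect_probs[np.ix_(z, z)]
    upper = np.triu(rng.random((n, n)) < pair_p, k=1)
    return _finish(upper | upper.T, True, seed)


def make_two_class_ensemble(
    n_per_class: int,
    n_nodes: int = 58,
    seed: int = 0,
    k: int = 6,
    p_rewire: float = 0.1,
) -> list[tuple[WeightedGraph, str]]:
    """Two-class ensemble of weighted networks for the classification harness.

    Class ``"structured"``: weighted small-world graphs (ring degree ``k``,
    rewiring probability ``p_rewire``).  Class ``"random"``: weighted
    Erdős–Rényi graphs matched in expected density (p = k/(n-1)).  Each
    instance gets its own seed-derived topology and weight draw, so
    instances within a class differ.  All graphs are connected.
    """
    if n_per_class < 2:
        raise GraphValidationError("need at least 2 networks per class")
    p_match = k / (n_nodes - 1)
    out: list[tuple[WeightedGraph, str]] = []
    for i in range(n_per_class):
        s = int(
            np.random.SeedSequence([int(seed), 11, i]).generate_state(1)[0] % (2**31)
        )
        out.append(
            (
                make_small_world(
                    n_nodes, k, p_rewire, weighted=True, seed=s, require_connected=True
                ),
                "structured",
            )
        )
    for i in range(n_per_class):
        s = int(
            np.random.SeedSequence([int(seed), 13, i]).generate_state(1)[0] % (2**31)
        )
        out.append(
            (
                make_erdos_renyi(
                    n_nodes, p_match, weighted=True, seed=s, require_connected=True
                ),
                "random",
            )
        )
    return out
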