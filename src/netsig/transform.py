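"""Graph-to-signal transformation via resistance-distance CMDS.

The transform maps a connected weighted graph into a set of node-indexed
signals whose pairwise squared Euclidean distances reproduce the
resistance distances of the graph.  Pipeline:

1. ``L = Δ - W`` — combinatorial (weighted) Laplacian.
2. ``R_ij = L†_ii + L†_jj - 2 L†_ij`` — resistance distance, the
   effective resistance between nodes when each edge is a resistor of
   resistance ``1/W_ij``.  ``R`` is a valid squared Euclidean distance
   matrix (non-negative, symmetric, triangle inequality).
3. ``B = -1/2 J R J`` with ``J = I - (1/N) 11ᵀ`` — double centering,
   the classical-multidimensional-scaling Gram matrix.  For resistance
   input this equals the Laplacian pseudoinverse ``L†``.
4. ``B = P Λ Pᵀ`` — spectral factorization; the *graph signals* are the
   columns of ``X = P Λ^{1/2}``, so ``X Xᵀ = B`` and every column is a
   zero-mean signal of length N.

Because a connected graph's centered Gram matrix has rank ``N - 1``, the
transform is lossless: the original distances, and then the graph
itself, can be recovered exactly from the full set of signals
(:func:`signals_to_distance`, :func:`distance_to_graph`).

For binary graphs an alternative, adjacency-derived distance is provided
in which ``D`` is the unweighted shortest-path (hop-count) distance; it
is squared entrywise before double centering, matching classical MDS of
a plain metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.linalg import eigh, pinvh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graph import GraphValidationError, WeightedGraph

__all__ = [
    "DistanceMatrix",
    "GramMatrix",
    "GraphSignals",
    "DistanceReport",
    "NotPSDError",
    "InvalidResistanceError",
    "laplacian",
    "resistance_distance",
    "adjacency_distance",
    "double_center",
    "graph_to_signals",
    "graph_signals",
    "signals_to_distance",
    "distance_to_graph",
    "stress",
    "stress_raw",
    "validate_distance",
]

Flavor = Literal["resistance", "adjacency"]


class NotPSDError(ValueError):
    """Gram matrix has a materially negative eigenvalue."""


class InvalidResistanceError(ValueError):
    """A distance matrix is not consistent with any connected graph."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative node-to-node distance matrix.

    ``flavor`` records provenance: ``"resistance"`` entries are already
    squared Euclidean distances and enter double centering directly;
    ``"adjacency"`` entries are hop-count distances of a binary graph and
    are squared entrywise first.
    """

    values: np.ndarray
    flavor: Flavor = "resistance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise GraphValidationError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise GraphValidationError("distance matrix must be symmetric")
        v = 0.5 * (v + v.T)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GramMatrix:
    """Double-centered Gram matrix B (symmetric, PSD, zero row sums)."""

    values: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GraphSignals:
    """Node-indexed signals from the spectral factorization of B.

    ``signals`` is N×C with column c equal to ``sqrt(λ_c) p_c``;
    eigenvalues are positive and descending.  Each column has zero mean
    and squared norm λ_c.
    """

    signals: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.signals.shape[0]

    @property
    def n_signals(self) -> int:
        return self.signals.shape[1]


def laplacian(g: WeightedGraph) -> np.ndarray:
    """Combinatorial Laplacian ``L = Δ - W`` (degree matrix minus weights)."""
    w = g.weights
    return np.diag(w.sum(axis=1)) - w


def resistance_distance(g: WeightedGraph) -> DistanceMatrix:
    """Effective-resistance distance from the Laplacian pseudoinverse.

    ``R_ij = L†_ii + L†_jj - 2 L†_ij``.  Requires a connected graph;
    across components the effective resistance is infinite and the
    pseudoinverse formula silently produces meaningless finite values.
    """
    g.require_connected("resistance distance")
    lp = pinvh(laplacian(g))
    d = np.diag(lp)
    r = d[:, None] + d[None, :] - 2.0 * lp
    np.fill_diagonal(r, 0.0)
    r = np.clip(r, 0.0, None)  # clear roundoff negatives ~1e-16
    return DistanceMatrix(r, flavor="resistance")


def adjacency_distance(g: WeightedGraph) -> DistanceMatrix:
    """Hop-count distance of a binary graph (adjacency-derived D).

    Adjacent pairs get distance 1; non-adjacent pairs get their unweighted
    shortest-path distance, keeping D a finite metric on connected graphs.
    """
    if not g.is_binary:
        raise GraphValidationError("adjacency distance is defined for binary graphs")
    g.require_connected("adjacency distance")
    d = shortest_path(csr_matrix(g.weights), method="D", unweighted=True)
    return DistanceMatrix(d, flavor="adjacency")


def double_center(d: DistanceMatrix) -> GramMatrix:
    """CMDS double centering ``B = -1/2 J D² J``.

    Resistance distances are themselves squared Euclidean distances and
    are centered directly (for a connected graph the result equals the
    Laplacian pseudoinverse); adjacency-derived distances are squared
    entrywise first.
    """
    m = d.values if d.flavor == "resistance" else d.values**2
    n = d.n_nodes
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * (j @ m @ j)
    b = 0.5 * (b + b.T)
    return GramMatrix(b)


def _canonical_signs(p: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so each column's largest-|.| entry is positive.

    Ties resolve to the lowest node index (argmax returns the first max).
    """
    idx = np.argmax(np.abs(p), axis=0)
    signs = np.sign(p[idx, np.arange(p.shape[1])])
    signs[signs == 0] = 1.0
    return p * signs


def graph_to_signals(b: GramMatrix, rank_tol: float = 1e-9) -> GraphSignals:
    """Spectral factorization of B into graph signals ``X = P Λ^{1/2}``.

    Eigenvalues above ``rank_tol * λ_max`` are retained in descending
    order.  Within a degenerate eigenvalue group (equal within the same
    tolerance) eigenvectors are ordered by the index of their
    largest-magnitude entry; downstream spectral features are invariant
    to rotations inside such a group.  Raises :class:`NotPSDError` if B
    has an eigenvalue below ``-1e-6 * λ_max``.
    """
    vals, vecs = eigh(b.values)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    lam_max = max(vals[0], 0.0)
    if lam_max == 0.0:
        raise NotPSDError("Gram matrix has no positive eigenvalue")
    if vals[-1] < -1e-6 * lam_max:
        raise NotPSDError(
            f"Gram matrix is not PSD: min eigenvalue {vals[-1]:.3e} "
            f"vs max {lam_max:.3e}"
        )
    keep = vals > rank_tol * lam_max
    vals, vecs = vals[keep], vecs[:, keep]
    vecs = _canonical_signs(vecs)

    # stable ordering inside degenerate eigenvalue groups
    order = np.arange(vals.size)
    group_tol = rank_tol * lam_max
    start = 0
    while start < vals.size:
        stop = start
        while stop + 1 < vals.size and vals[start] - vals[stop + 1] <= group_tol:
            stop += 1
        if stop > start:
            block = order[start : stop + 1]
            peaks = np.argmax(np.abs(vecs[:, block]), axis=0)
            order[start : stop + 1] = block[np.argsort(peaks, kind="stable")]
        start = stop + 1
    vals, vecs = vals[order], vecs[:, order]

    x = vecs * np.sqrt(vals)[None, :]
    return GraphSignals(signals=x, eigenvalues=vals)


def graph_signals(
    g: WeightedGraph,
    distance: Flavor = "resistance",
    rank_tol: float = 1e-9,
) -> GraphSignals:
    """Convenience composition: graph → distance → Gram → signals."""
    d = resistance_distance(g) if distance == "resistance" else adjacency_distance(g)
    return graph_to_signals(double_center(d), rank_tol=rank_tol)


def signals_to_distance(x: GraphSignals) -> DistanceMatrix:
    """Reconstruct ``R̂_ij = Σ_c (x_c(i) - x_c(j))²`` from the signals."""
    s = x.signals
    sq = np.sum(s**2, axis=1)
    r = sq[:, None] + sq[None, :] - 2.0 * (s @ s.T)
    np.fill_diagonal(r, 0.0)
    return DistanceMatrix(np.clip(r, 0.0, None), flavor="resistance")


def distance_to_graph(r_hat: DistanceMatrix, tol: float = 1e-6) -> WeightedGraph:
    """Recover the weighted graph from a resistance-distance matrix.

    Double centering gives ``B = L†``; pseudoinverting back yields the
    Laplacian, whose negated off-diagonal is the weight matrix.  If the
    recovered off-diagonal Laplacian has entries significantly positive
    (i.e. negative weights beyond ``tol`` relative to the largest
    recovered weight) the input was not a valid resistance matrix.
    """
    b = double_center(DistanceMatrix(r_hat.values, flavor="resistance"))
    lap = pinvh(b.values)
    w = -lap
    np.fill_diagonal(w, 0.0)
    w = 0.5 * (w + w.T)
    scale = max(w.max(), 1.0)
    if w.min() < -tol * scale:
        raise InvalidResistanceError(
            "recovered Laplacian has significantly positive off-diagonal "
            f"entries (min implied weight {w.min():.3e}); the input is not a "
            "valid resistance-distance matrix"
        )
    return WeightedGraph(np.clip(w, 0.0, None))


def stress(r: DistanceMatrix, r_hat: DistanceMatrix) -> float:
    """Kruskal stress-1 between original and reconstructed distances.

    ``sqrt( Σ_{i<j} (r̂ - r)² / Σ_{i<j} r² )``; zero for a perfect
    reconstruction, undefined for an all-zero reference.
    """
    if r.values.shape != r_hat.values.shape:
        raise GraphValidationError("stress requires matching shapes")
    iu = np.triu_indices(r.n_nodes, k=1)
    denom = np.sum(r.values[iu] ** 2)
    if denom == 0.0:
        raise GraphValidationError("stress is undefined for an all-zero reference")
    return float(np.sqrt(np.sum((r_hat.values[iu] - r.values[iu]) ** 2) / denom))


def stress_raw(r: DistanceMatrix, r_hat: DistanceMatrix) -> float:
    """Unnormalized residual sum of squares over unordered pairs."""
    if r.values.shape != r_hat.values.shape:
        raise GraphValidationError("stress requires matching shapes")
    iu = np.triu_indices(r.n_nodes, k=1)
    return float(np.sum((r_hat.values[iu] - r.values[iu]) ** 2))


def segment_plateaus(
    x: GraphSignals,
    n_segments: int,
    n_signals: int | None = None,
    pool: int | None = None,
) -> np.ndarray:
    """Recover a contiguous node partition from plateau structure.

    For a stochastic block model whose nodes are ordered by block, the
    leading signals are approximately piecewise constant with plateau
    supports equal to the block sizes.  This fits exactly
    ``n_segments`` contiguous constant segments to the rows of the
    selected signals by dynamic programming (minimizing within-segment
    sum of squares) and returns the segment label of each node.

    ``n_signals`` defaults to ``n_segments - 1`` (the number of
    block-separating signals).  Because impulse-like signals localized
    on single low-degree nodes can interleave with the plateau signals
    when eigenvalues are close, the ``n_signals`` signals are chosen as
    the most *spread* ones — highest energy-compactness
    ``‖x‖₁/(√N ‖x‖₂)`` — among the leading ``pool`` (default
    ``2 n_segments``) signals.
    """
    if n_segments < 1 or n_segments > x.n_nodes:
        raise GraphValidationError("n_segments must be between 1 and N")
    if n_signals is None:
        n_signals = max(n_segments - 1, 1)
    if pool is None:
        pool = min(2 * n_segments, x.n_signals)
    lead = x.signals[:, :pool]
    n = x.n_nodes
    spread = np.abs(lead).sum(axis=0) / (
        np.sqrt(n) * np.sqrt((lead**2).sum(axis=0))
    )
    picked = np.sort(np.argsort(spread)[::-1][:n_signals])
    sig = lead[:, picked]

    # DP over contiguous segmentations; cost = within-segment SSE
    s1 = np.vstack([np.zeros(sig.shape[1]), np.cumsum(sig, axis=0)])
    s2 = np.concatenate([[0.0], np.cumsum((sig**2).sum(axis=1))])

    def cost(a: int, b: int) -> float:  # segment [a, b)
        return s2[b] - s2[a] - float(((s1[b] - s1[a]) ** 2).sum()) / (b - a)

    best = np.full((n_segments + 1, n + 1), np.inf)
    back = np.zeros((n_segments + 1, n + 1), dtype=int)
    best[0, 0] = 0.0
    for k in range(1, n_segments + 1):
        for b in range(k, n + 1):
            for a in range(k - 1, b):
                v = best[k - 1, a] + cost(a, b)
                if v < best[k, b]:
                    best[k, b] = v
                    back[k, b] = a
    bounds = [n]
    for k in range(n_segments, 0, -1):
        bounds.append(back[k, bounds[-1]])
    bounds = bounds[::-1]
    labels = np.zeros(n, dtype=int)
    for k in range(n_segments):
        labels[bounds[k] : bounds[k + 1]] = k
    return labels


@dataclass
class DistanceReport:
    """Distance-axiom violations found by :func:`validate_distance`."""

    negative_entries: list[tuple[int, int]] = field(default_factory=list)
    nonzero_diagonal: list[int] = field(default_factory=list)
    asymmetric_pairs: list[tuple[int, int]] = field(default_factory=list)
    triangle_violations: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.negative_entries
            or self.nonzero_diagonal
            or self.asymmetric_pairs
            or self.triangle_violations
        )


def validate_distance(d: np.ndarray | DistanceMatrix, tol: float = 1e-8) -> DistanceReport:
    """Check the distance axioms: non-negativity, zero diagonal, symmetry,
    and the triangle inequality ``d_ij + d_jk ≥ d_ik`` (within ``tol``)."""
    v = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    report = DistanceReport()
    n = v.shape[0]
    for i, j in zip(*np.nonzero(v < -tol)):
        if i < j:
            report.negative_entries.append((int(i), int(j)))
    report.nonzero_diagonal = [int(i) for i in np.nonzero(np.abs(np.diag(v)) > tol)[0]]
    for i, j in zip(*np.nonzero(np.abs(v - v.T) > tol)):
        if i < j:
            report.asymmetric_pairs.append((int(i), int(j)))
    # d_ij + d_jk >= d_ik for all triples (vectorized over j)
    slack = v[:, :, None] + v[None, :, :] - v[:, None, :]
    bad = np.nonzero(slack < -tol)
    for i, j, k in zip(*bad):
        if i != j and j != k and i != k:
            report.triangle_violations.append((int(i), int(j), int(k)))
    return report
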