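"""Core weighted-graph container and validation.

A functional connectivity network (FCN) is an undirected graph whose
nodes are recording sites and whose edge weights quantify statistical
dependence (here, phase-locking values in [0, 1]).  The container below
is deliberately minimal: a dense symmetric non-negative weight matrix
with a zero diagonal, plus a flag marking binary (0/1) graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


class GraphValidationError(ValueError):
    """Raised when a matrix does not satisfy the weighted-graph invariants."""


class GraphConnectivityError(ValueError):
    """Raised when an operation requires a connected graph but the input is not."""


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected graph stored as a dense symmetric weight matrix.

    Parameters
    ----------
    weights
        ``(N, N)`` symmetric matrix of non-negative edge weights with a
        zero diagonal.  ``weights[i, j] == 0`` means "no edge".
    is_binary
        If True every entry must be exactly 0 or 1 and the graph is
        treated as unweighted by downstream operations.
    """

    weights: np.ndarray
    is_binary: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise GraphValidationError(f"weight matrix must be square, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise GraphValidationError("weight matrix contains non-finite entries")
        if not np.allclose(w, w.T, atol=1e-8):
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise GraphValidationError(
                f"weight matrix is asymmetric; worst violation at ({i}, {j}): "
                f"{w[i, j]} vs {w[j, i]}"
            )
        if np.any(np.diag(w) != 0):
            raise GraphValidationError("diagonal entries must be zero")
        if np.any(w < 0):
            raise GraphValidationError("weights must be non-negative")
        if self.is_binary and not np.all((w == 0) | (w == 1)):
            raise GraphValidationError("binary graph has entries outside {0, 1}")
        w = 0.5 * (w + w.T)  # exact symmetry for numerics downstream
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    # -- basic descriptors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of edges with strictly positive weight."""
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def degrees(self) -> np.ndarray:
        """Binary degree of each node (count of incident positive-weight edges)."""
        return (self.weights > 0).sum(axis=1)

    def strengths(self) -> np.ndarray:
        """Weighted degree (sum of incident edge weights) of each node."""
        return self.weights.sum(axis=1)

    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1) / 2)

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return False
        n_comp, _ = connected_components(
            csr_matrix(self.weights > 0), directed=False
        )
        return n_comp == 1

    def require_connected(self, context: str = "this operation") -> None:
        if not self.is_connected():
            raise GraphConnectivityError(
                f"{context} requires a connected graph; the input has more "
                "than one component"
            )

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Edges as ``(i, j, w)`` with ``i < j``, sorted lexicographically."""
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        return [(int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)]

    def binarized(self) -> "WeightedGraph":
        """Topology-only copy: every positive weight becomes 1."""
        return WeightedGraph((self.weights > 0).astype(float), is_binary=True)
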