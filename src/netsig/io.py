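"""File formats and run configuration.

Graphs travel as dense CSV matrices (no header, N rows × N columns),
3-column tab-separated edge lists (``i<TAB>j<TAB>w``, 0-based ids), or
GraphML.  Signals/eigenvalues and feature tables travel as CSV.  All
writers round-trip losslessly through their paired readers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .classify import FeatureTable
from .graph import GraphValidationError, WeightedGraph
from .transform import GraphSignals

__all__ = [
    "RunConfig",
    "read_graph",
    "write_graph",
    "read_signals",
    "write_signals",
    "read_feature_table",
    "write_feature_table",
]


@dataclass
class RunConfig:
    """Serializable settings of one pipeline run."""

    seed: int = 0
    distance: str = "resistance"
    rank_tol: float = 1e-9
    c_tilde: int | None = None
    n_bins: int | None = None
    sigma: float = 0.01
    n_reference: int = 20
    classifiers: tuple[str, ...] = ("linear-svm", "lda", "logistic", "knn")
    n_per_class: int = 18
    n_nodes: int = 58

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data["classifiers"] = tuple(data.get("classifiers", cls.classifiers))
        return cls(**data)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".graphml":
        return "graphml"
    if suffix in (".tsv", ".edges", ".edgelist"):
        return "edgelist-tsv"
    return "matrix-csv"


def read_graph(path: str | Path, fmt: str | None = None) -> WeightedGraph:
    """Load and validate a graph from matrix CSV / edge-list TSV / GraphML."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "matrix-csv":
        w = np.loadtxt(path, delimiter=",", ndmin=2)
        return WeightedGraph(w, is_binary=bool(np.all((w == 0) | (w == 1))))
    if fmt == "edgelist-tsv":
        edges: dict[tuple[int, int], float] = {}
        n_max = -1
        for line_no, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise GraphValidationError(
                    f"{path}:{line_no}: expected 'i<TAB>j<TAB>w', got {line!r}"
                )
            i, j, w = int(parts[0]), int(parts[1]), float(parts[2])
            if i == j:
                raise GraphValidationError(f"{path}:{line_no}: self-loop on node {i}")
            key = (min(i, j), max(i, j))
            if key in edges:
                raise GraphValidationError(
                    f"{path}:{line_no}: duplicate edge {key}"
                )
            edges[key] = w
            n_max = max(n_max, i, j)
        mat = np.zeros((n_max + 1, n_max + 1))
        for (i, j), w in edges.items():
            mat[i, j] = mat[j, i] = w
        return WeightedGraph(mat, is_binary=bool(np.all((mat == 0) | (mat == 1))))
    if fmt == "graphml":
        g = nx.read_graphml(path)
        nodes = sorted(g.nodes(), key=lambda s: int(s))
        mat = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        return WeightedGraph(mat, is_binary=bool(np.all((mat == 0) | (mat == 1))))
    raise ValueError(f"unknown graph format {fmt!r}")


def write_graph(g: WeightedGraph, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "matrix-csv":
        np.savetxt(path, g.weights, delimiter=",", fmt="%.17g")
    elif fmt == "edgelist-tsv":
        lines = [f"{i}\t{j}\t{w:.17g}" for i, j, w in g.edge_list()]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        gx = nx.from_numpy_array(g.weights)
        nx.write_graphml(gx, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def write_signals(signals: GraphSignals, path: str | Path, eigs_path: str | Path) -> None:
    np.savetxt(path, signals.signals, delimiter=",", fmt="%.17g")
    np.savetxt(eigs_path, signals.eigenvalues[None, :], delimiter=",", fmt="%.17g")


def read_signals(path: str | Path, eigs_path: str | Path) -> GraphSignals:
    x = np.loadtxt(path, delimiter=",", ndmin=2)
    lam = np.loadtxt(eigs_path, delimiter=",", ndmin=2).ravel()
    return GraphSignals(signals=x, eigenvalues=lam)


def write_feature_table(table: FeatureTable, path: str | Path, label_col: str = "class") -> None:
    df = table.features.copy()
    df[label_col] = table.labels
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path, label_col: str = "class") -> FeatureTable:
    df = pd.read_csv(path)
    if label_col not in df.columns:
        raise GraphValidationError(f"feature CSV has no label column {label_col!r}")
    labels = df[label_col].to_numpy()
    return FeatureTable(df.drop(columns=[label_col]), labels)
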