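"""Metric graphs induced by connectivity matrices.

A subject's coherence matrix defines a fully connected undirected graph on the
ROI nodes whose edge lengths are the multiplicative inverse of coherence
(strong coupling = short edge, in analogy with conductance and resistance).
Volume entropy is defined on this metric graph; the directed-edge indexing
needed by the edge-adjacency operator lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import ConnectivityMatrix

__all__ = [
    "MetricGraph",
    "DirectedEdgeSystem",
    "GraphValidationError",
    "ValidationReport",
    "build_metric_graph",
    "directed_edges",
    "validate_graph",
]

#: Asymmetry beyond this max-norm tolerance is an error, not noise.
SYMMETRY_TOL = 1e-9


class GraphValidationError(ValueError):
    """Raised for inputs that cannot define a valid metric graph."""


@dataclass
class MetricGraph:
    """Undirected graph with positive edge lengths.

    ``lengths`` is a symmetric ``n x n`` array; ``np.inf`` marks an absent
    edge (the diagonal is always absent).  Pipeline graphs are complete, but
    sparser graphs (cycles, paths) are representable so that the validation
    rules have something to reject.
    """

    node_labels: tuple[str, ...]
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.node_labels = tuple(self.node_labels)
        L = np.asarray(self.lengths, dtype=float)
        n = len(self.node_labels)
        if L.shape != (n, n):
            raise GraphValidationError(f"lengths shape {L.shape} != ({n}, {n})")
        if not np.array_equal(L, L.T):
            raise GraphValidationError("length matrix must be symmetric")
        L = L.copy()
        np.fill_diagonal(L, np.inf)
        finite = np.isfinite(L)
        if np.any(L[finite] <= 0):
            raise GraphValidationError("edge lengths must be positive")
        if np.any(np.isnan(L)):
            raise GraphValidationError("edge lengths must not be NaN")
        self.lengths = L

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def edge_mask(self) -> np.ndarray:
        """Boolean adjacency: ``True`` where an edge exists."""
        return np.isfinite(self.lengths)

    @property
    def n_edges(self) -> int:
        return int(self.edge_mask.sum()) // 2

    @property
    def is_complete(self) -> bool:
        n = self.n_nodes
        return self.n_edges == n * (n - 1) // 2

    def degrees(self) -> np.ndarray:
        return self.edge_mask.sum(axis=1)

    @classmethod
    def from_edges(
        cls, node_labels, edges: dict[tuple[int, int], float]
    ) -> "MetricGraph":
        """Build a (possibly sparse) graph from ``{(i, j): length}``."""
        n = len(node_labels)
        L = np.full((n, n), np.inf)
        for (i, j), length in edges.items():
            L[i, j] = L[j, i] = length
        return cls(tuple(node_labels), L)


@dataclass
class DirectedEdgeSystem:
    """Canonical indexing of the ``2|E|`` directed edges of a metric graph.

    Edges are ordered lexicographically by ``(initial node, terminal node)``
    so every eigenvector computed downstream is aligned identically across
    runs and platforms.  ``reverse`` is the involution pairing each directed
    edge with its reversal.
    """

    graph: MetricGraph
    initial: np.ndarray = field(init=False)
    terminal: np.ndarray = field(init=False)
    reverse: np.ndarray = field(init=False)
    lengths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ii, jj = np.nonzero(self.graph.edge_mask)
        order = np.lexsort((jj, ii))
        self.initial = ii[order]
        self.terminal = jj[order]
        self.lengths = self.graph.lengths[self.initial, self.terminal]
        index = {
            (int(u), int(v)): k
            for k, (u, v) in enumerate(zip(self.initial, self.terminal))
        }
        self._index = index
        self.reverse = np.array(
            [index[(int(v), int(u))] for u, v in zip(self.initial, self.terminal)]
        )

    @property
    def n_edges(self) -> int:
        """Number of *directed* edges."""
        return len(self.initial)

    def index(self, u: int, v: int) -> int:
        """Index of directed edge ``u -> v``."""
        return self._index[(u, v)]


@dataclass
class ValidationReport:
    """Structural checks a graph must pass before volume entropy is defined."""

    terminal_vertices: list[str]
    is_single_cycle: bool
    nonfinite_lengths: bool

    @property
    def ok(self) -> bool:
        return not (
            self.terminal_vertices or self.is_single_cycle or self.nonfinite_lengths
        )


def build_metric_graph(
    matrix: "ConnectivityMatrix | np.ndarray",
    min_coherence: float = 1e-6,
    labels=None,
) -> MetricGraph:
    """Convert a coherence matrix to its metric graph: ``l = 1 / coherence``.

    Coherence below ``min_coherence`` is clamped up so the graph stays fully
    connected with finite lengths.  Accepts a :class:`ConnectivityMatrix` or a
    raw square array (with optional ``labels``).  Matrices asymmetric beyond
    ``1e-9`` in max-norm are rejected; smaller asymmetry is averaged away.
    """
    if hasattr(matrix, "values") and hasattr(matrix, "labels"):
        values = np.asarray(matrix.values, dtype=float)
        labels = matrix.labels
    else:
        values = np.asarray(matrix, dtype=float)
    n = values.shape[0]
    if values.ndim != 2 or values.shape[1] != n:
        raise GraphValidationError(f"expected a square matrix, got {values.shape}")
    if labels is None:
        labels = tuple(f"node{i}" for i in range(n))
    if n < 4:
        raise GraphValidationError(
            "need at least 4 nodes: smaller complete graphs are a single cycle "
            "or have terminal vertices, where volume entropy is degenerate"
        )
    bad = np.argwhere(~np.isfinite(values) | (values < 0))
    if len(bad):
        i, j = bad[0]
        raise GraphValidationError(
            f"invalid coherence at ({i}, {j}): {values[i, j]!r} "
            "(entries must be finite and nonnegative)"
        )
    asym = np.abs(values - values.T).max()
    if asym > SYMMETRY_TOL:
        i, j = np.unravel_index(np.abs(values - values.T).argmax(), values.shape)
        raise GraphValidationError(
            f"matrix asymmetric at ({i}, {j}): |{values[i, j]} - {values[j, i]}| "
            f"= {asym:.3g} exceeds {SYMMETRY_TOL}"
        )
    values = 0.5 * (values + values.T)
    lengths = 1.0 / np.maximum(values, min_coherence)
    np.fill_diagonal(lengths, np.inf)
    return MetricGraph(tuple(labels), lengths)


def directed_edges(graph: MetricGraph) -> DirectedEdgeSystem:
    """Canonical directed-edge indexing of ``graph`` (lexicographic order)."""
    return DirectedEdgeSystem(graph)


def validate_graph(graph: MetricGraph) -> ValidationReport:
    """Check the structural assumptions under which volume entropy is positive.

    Flags terminal vertices (degree < 2), a graph that is one single cycle
    (every degree exactly 2 and connected — path counts then grow linearly,
    not exponentially, so the entropy is zero) and non-finite lengths on
    declared edges.
    """
    deg = graph.degrees()
    terminal = [graph.node_labels[i] for i in np.nonzero(deg < 2)[0]]
    single_cycle = bool(np.all(deg == 2)) and _is_connected(graph.edge_mask)
    mask = graph.edge_mask
    nonfinite = bool(np.any(~np.isfinite(graph.lengths[mask])))
    return ValidationReport(terminal, single_cycle, nonfinite)


def _is_connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        u = stack.pop()
        for v in np.nonzero(adj[u])[0]:
            if not seen[v]:
                seen[v] = True
                stack.append(v)
    return bool(seen.all())
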