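"""Edge capacities and afferent node capacities.

At the volume entropy h_vol the operator L(h_vol) has Perron root 1; its
(unique, strictly positive) eigenvector assigns each directed edge a
*capacity* x_e quantifying how much that edge contributes to the spread of
information through the network.  Summing capacities over the directed edges
terminating at a node gives the node's *afferent capacity*, a local measure of
inbound information flow; the analogous sum over initial nodes (the efferent
capacity) is computed for diagnostics only, since in richly connected graphs
it is close to uniform and carries little local signal.

Capacities are normalised to sum to one so they are comparable across
subjects whose graphs differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy import NumericalError, _dense_radius, _operator, _power_iteration, build_L
from .graph import DirectedEdgeSystem

__all__ = [
    "EdgeCapacityVector",
    "NodeCapacityVector",
    "compute_edge_capacities",
    "afferent_node_capacity",
    "edge_capacity_homogeneity",
]


@dataclass
class EdgeCapacityVector:
    """Perron eigenvector of L(h_vol), aligned to the directed-edge ordering,
    normalised to sum to one."""

    values: np.ndarray
    residual: float
    normalization: str = "sum-to-one"


@dataclass
class NodeCapacityVector:
    """Afferent (and diagnostic efferent) capacities per node."""

    node_labels: tuple[str, ...]
    afferent: np.ndarray
    efferent: np.ndarray


def compute_edge_capacities(
    des: DirectedEdgeSystem,
    h_vol: float,
    tol: float = 1e-12,
    residual_tol: float = 1e-8,
) -> EdgeCapacityVector:
    """Edge capacities: the positive eigenvector of L(h_vol) at eigenvalue 1.

    Power iteration (dense eigensolver fallback for small systems); the
    relative residual ||L x - x||_inf / ||x||_inf must not exceed
    ``residual_tol``, otherwise ``h_vol`` does not actually solve
    rho(L(h)) = 1 for this graph.
    """
    m = des.n_edges
    matvec = _operator(des, h_vol)
    rho, x, _, ok = _power_iteration(matvec, m, tol, 100_000)
    if not ok and m <= 2000:
        rho, x = _dense_radius(build_L(des, h_vol))
    x = np.abs(x)
    x /= x.sum()
    residual = float(np.max(np.abs(matvec(x) - x)) / np.max(np.abs(x)))
    if residual > residual_tol:
        raise NumericalError(
            f"eigen residual {residual:.3g} exceeds {residual_tol:.3g}: "
            f"h_vol={h_vol} is not a unit-eigenvalue point for this graph "
            f"(rho estimate {rho:.12g})"
        )
    if np.any(x <= 0):
        raise NumericalError("edge capacities not strictly positive")
    return EdgeCapacityVector(values=x, residual=residual)


def afferent_node_capacity(
    x: EdgeCapacityVector, des: DirectedEdgeSystem
) -> NodeCapacityVector:
    """Sum edge capacities by terminal node (afferent) and by initial node
    (efferent, diagnostic).  Both aggregations conserve the total of 1."""
    n = des.graph.n_nodes
    afferent = np.bincount(des.terminal, weights=x.values, minlength=n)
    efferent = np.bincount(des.initial, weights=x.values, minlength=n)
    return NodeCapacityVector(
        node_labels=des.graph.node_labels, afferent=afferent, efferent=efferent
    )


def edge_capacity_homogeneity(
    x: EdgeCapacityVector, des: DirectedEdgeSystem
) -> dict[str, float]:
    """Per-node coefficient of variation of incoming edge capacities.

    In richly connected graphs, edges sharing a terminal node have similar
    capacities; this diagnostic quantifies how far a given graph is from that
    regime.  Descriptive only — no threshold is enforced.
    """
    out: dict[str, float] = {}
    for v, label in enumerate(des.graph.node_labels):
        incoming = x.values[des.terminal == v]
        mu = incoming.mean()
        out[label] = float(incoming.std() / mu) if mu > 0 else float("nan")
    return out
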