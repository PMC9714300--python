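"""Volume entropy of a metric graph.

The volume entropy h_vol is the asymptotic exponential growth rate of the
number N_r of non-backtracking edge paths of total length below r:

    h_vol = lim_{r -> inf} log(N_r) / r .

It is computed spectrally.  Let L(h) be the matrix indexed by directed edges
with entry

    L(h)[e, f] = exp(-h * l(f))   if f continues e without backtracking
                                  (terminal(e) = initial(f), initial(e) != terminal(f)),
                 0                otherwise.

At h = 0 this is the unweighted non-backtracking (Hashimoto-type) edge
adjacency, whose spectral radius exceeds 1 for any graph that is neither a
single cycle nor has terminal vertices.  The spectral radius rho(L(h)) is
continuous and strictly decreasing in h, so there is a unique h >= 0 with
rho(L(h)) = 1; that h is the volume entropy.  The solver brackets this root
and bisects; a brute-force path-counting oracle on tiny graphs checks the
spectral answer against the limit definition directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from .graph import DirectedEdgeSystem, MetricGraph, directed_edges, validate_graph

__all__ = [
    "EntropyResult",
    "PathCountCurve",
    "NonpositiveEntropyError",
    "NumericalError",
    "build_L",
    "spectral_radius",
    "solve_volume_entropy",
    "count_paths_oracle",
]


class NonpositiveEntropyError(ValueError):
    """The graph's non-backtracking operator has spectral radius <= 1 at h=0,
    so path counts do not grow exponentially and the model does not apply."""


class NumericalError(RuntimeError):
    """An eigenvalue or root-finding computation failed to converge."""


@dataclass
class EntropyResult:
    """Solution of rho(L(h)) = 1.

    ``h_vol`` has units of 1/length; ``bracket`` is the final bisection
    interval and ``rho_at_solution`` the spectral radius at the returned h.
    """

    h_vol: float
    rho_at_solution: float
    bracket: tuple[float, float]
    iterations: int
    tol_h: float
    tol_rho: float


@dataclass
class PathCountCurve:
    """Non-backtracking path counts N_r on a grid of radii, with the fitted
    exponential growth rate of log N_r (the oracle estimate of h_vol)."""

    radii: np.ndarray
    counts: np.ndarray
    slope_estimate: float


def _nb_structure(des: DirectedEdgeSystem) -> sp.csr_matrix:
    """0/1 non-backtracking edge adjacency B[e, f] for ``des`` (cached)."""
    cached = getattr(des, "_nb_cache", None)
    if cached is not None:
        return cached
    m = des.n_edges
    out_edges: dict[int, np.ndarray] = {}
    for v in range(des.graph.n_nodes):
        out_edges[v] = np.nonzero(des.initial == v)[0]
    rows, cols = [], []
    for e in range(m):
        cont = out_edges[des.terminal[e]]
        cont = cont[cont != des.reverse[e]]
        rows.append(np.full(len(cont), e))
        cols.append(cont)
    B = sp.csr_matrix(
        (
            np.ones(sum(len(c) for c in cols)),
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(m, m),
    )
    des._nb_cache = B
    return B


def build_L(des: DirectedEdgeSystem, h: float) -> sp.csr_matrix:
    """The weighted non-backtracking operator L(h), stored sparse.

    Entry (e, f) equals exp(-h * l(f)) when f continues e without
    backtracking, else 0.  Column f of L(h) is column f of the 0/1 structure
    scaled by exp(-h * l(f)).
    """
    if h < 0:
        raise ValueError(f"h must be nonnegative, got {h}")
    B = _nb_structure(des)
    w = np.exp(-h * des.lengths)
    return B.multiply(w.reshape(1, -1)).tocsr()


def _complete_matvec(des: DirectedEdgeSystem, h: float) -> Callable[[np.ndarray], np.ndarray]:
    """O(n^2) matvec with L(h) for complete graphs.

    For edge e = (u, v), (L x)_e = sum_{w != u,v} W[v,w] x_(v,w)
    = rowsum_v(W o X) - W[v,u] x_(v,u), with W[v,w] = exp(-h l(v,w)).
    """
    g = des.graph
    n = g.n_nodes
    with np.errstate(over="ignore", invalid="ignore"):
        W = np.exp(-h * g.lengths)  # inf lengths (diagonal) -> 0 for h > 0; nan at h=0
    np.fill_diagonal(W, 0.0)
    init, term = des.initial, des.terminal

    def matvec(x: np.ndarray) -> np.ndarray:
        X = np.zeros((n, n))
        X[init, term] = x
        M = W * X
        s = M.sum(axis=1)
        return s[term] - M[term, init]

    return matvec


def _operator(des: DirectedEdgeSystem, h: float) -> Callable[[np.ndarray], np.ndarray]:
    if des.graph.is_complete:
        return _complete_matvec(des, h)
    L = build_L(des, h)
    return L.dot


def _power_iteration(
    matvec: Callable[[np.ndarray], np.ndarray],
    m: int,
    tol: float,
    maxiter: int,
    x0: np.ndarray | None = None,
) -> tuple[float, np.ndarray, int, bool]:
    """Power iteration with Collatz-Wielandt enclosure.

    For a nonnegative matrix with positive iterates, min and max of
    (Ax)_i / x_i bracket the Perron root; iteration stops when the enclosure
    width drops below ``tol * max(1, rho)``.  Returns (rho, vector, iters,
    converged); the vector is L1-normalised.
    """
    x = np.full(m, 1.0 / m) if x0 is None else np.abs(x0) / np.abs(x0).sum()
    rho = np.nan
    for it in range(1, maxiter + 1):
        y = matvec(x)
        pos = x > 0
        ypos = y[pos]
        if np.any(ypos <= 0):
            # zero continuation rows: enclosure degenerates; let caller fall back
            return float(np.abs(y).sum()), x, it, False
        ratios = ypos / x[pos]
        lo, hi = float(ratios.min()), float(ratios.max())
        rho = 0.5 * (lo + hi)
        x = y / y.sum()
        if hi - lo <= tol * max(1.0, rho):
            return rho, x, it, True
    return rho, x, maxiter, False


def _dense_radius(L: sp.spmatrix) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eig(L.toarray())
    k = int(np.argmax(np.abs(vals)))
    v = np.real(vecs[:, k])
    if v.sum() < 0:
        v = -v
    return float(np.abs(vals[k])), v / np.abs(v).sum()


def spectral_radius(
    L,
    tol_rho: float = 1e-10,
    maxiter: int = 100_000,
    x0: np.ndarray | None = None,
) -> float:
    """Largest absolute eigenvalue of a nonnegative matrix.

    Power iteration from a deterministic all-ones start, valid for the
    irreducible nonnegative operators arising from complete graphs; a dense
    eigensolver handles small matrices where the iteration fails to converge
    (periodic structure, zero rows).
    """
    L = sp.csr_matrix(L) if not sp.issparse(L) else L
    if np.any(L.data < 0):
        raise ValueError("matrix must be nonnegative")
    rho, _, _, ok = _power_iteration(L.dot, L.shape[0], tol_rho, maxiter, x0)
    if ok:
        return rho
    if L.shape[0] <= 2000:
        return _dense_radius(L)[0]
    raise NumericalError(
        f"power iteration did not converge in {maxiter} iterations; "
        f"last estimate {rho!r}"
    )


def solve_volume_entropy(
    graph: MetricGraph,
    tol_h: float = 1e-8,
    tol_rho: float = 1e-10,
    des: DirectedEdgeSystem | None = None,
    max_bisect: int = 200,
) -> EntropyResult:
    """Find the unique h >= 0 with rho(L(h)) = 1 by bisection.

    The initial upper bracket log(max row sum of L(0)) / l_min is a rigorous
    bound — every row sum of L(h) is at most its h=0 value times
    exp(-h * l_min) — and is doubled if necessary.  Bisection continues until
    the bracket is narrower than ``tol_h`` *and* rho at the midpoint is
    within ``tol_rho`` of 1, so the returned h also pins the eigenvalue.
    Successive evaluations must show rho strictly decreasing in h; a
    violation aborts with :class:`NumericalError`.
    """
    report = validate_graph(graph)
    if not report.ok:
        raise NonpositiveEntropyError(
            f"graph fails structural checks: terminal vertices "
            f"{report.terminal_vertices}, single cycle {report.is_single_cycle}, "
            f"non-finite lengths {report.nonfinite_lengths}"
        )
    if des is None:
        des = directed_edges(graph)
    m = des.n_edges

    evaluated: list[tuple[float, float]] = []
    warm: dict[str, np.ndarray | None] = {"x": None}

    def rho_at(h: float) -> float:
        matvec = _operator(des, h)
        rho, x, _, ok = _power_iteration(matvec, m, tol_rho, 100_000, warm["x"])
        if not ok:
            if m <= 2000:
                rho, x = _dense_radius(build_L(des, h))
            else:
                raise NumericalError(f"eigen iteration failed at h={h}")
        warm["x"] = x
        evaluated.append((h, rho))
        return rho

    rho0 = rho_at(0.0)
    if rho0 <= 1.0 + tol_rho:
        raise NonpositiveEntropyError(
            f"graph has nonpositive volume entropy: rho(L(0)) = {rho0:.6g} <= 1"
        )
    l_min = float(des.lengths.min())
    row_sum_max = float(np.max(_nb_structure(des).sum(axis=1)))
    h_lo, h_hi = 0.0, np.log(max(row_sum_max, 1.0 + 1e-9)) / l_min
    while rho_at(h_hi) >= 1.0:  # safety doubling; cannot trigger for complete graphs
        h_lo, h_hi = h_hi, 2.0 * h_hi

    iterations = 0
    rho_mid = np.nan
    h_mid = 0.5 * (h_lo + h_hi)
    for iterations in range(1, max_bisect + 1):
        h_mid = 0.5 * (h_lo + h_hi)
        rho_mid = rho_at(h_mid)
        if (h_hi - h_lo) <= tol_h and abs(rho_mid - 1.0) <= tol_rho:
            break
        if rho_mid > 1.0:
            h_lo = h_mid
        else:
            h_hi = h_mid
    else:
        raise NumericalError(
            f"bisection failed to meet tolerances in {max_bisect} iterations "
            f"(bracket width {h_hi - h_lo:.3g}, |rho-1| = {abs(rho_mid - 1):.3g})"
        )

    # monotonicity audit: rho must strictly decrease along increasing h
    pts = sorted(evaluated)
    for (h1, r1), (h2, r2) in zip(pts, pts[1:]):
        if h2 > h1 and r2 >= r1 + 10 * tol_rho:
            raise NumericalError(
                f"spectral radius not decreasing: rho({h1})={r1}, rho({h2})={r2}"
            )

    return EntropyResult(
        h_vol=h_mid,
        rho_at_solution=float(rho_mid),
        bracket=(h_lo, h_hi),
        iterations=iterations,
        tol_h=tol_h,
        tol_rho=tol_rho,
    )


def count_paths_oracle(
    graph: MetricGraph,
    r_max: float,
    r_grid: Sequence[float] | None = None,
    max_directed_edges: int = 30,
    override: bool = False,
) -> PathCountCurve:
    """Brute-force check of the limit definition of volume entropy.

    Exhaustively enumerates every non-backtracking edge path (a sequence of
    one or more directed edges, each continuing the last without reversing
    it) of total length below ``r_max``, by depth-first search.  N_r is then
    the number of enumerated paths of length < r for each r in the grid, and
    the growth rate is the least-squares slope of log N_r against r over the
    largest half of the grid (discarding the transient at small r).

    Exponential cost: refuses graphs with more than ``max_directed_edges``
    directed edges unless ``override`` is set.
    """
    des = directed_edges(graph)
    if des.n_edges > max_directed_edges and not override:
        raise ValueError(
            f"{des.n_edges} directed edges exceeds the oracle guard "
            f"({max_directed_edges}); pass override=True to force"
        )
    lengths = graph.lengths
    neighbors = [np.nonzero(graph.edge_mask[v])[0] for v in range(graph.n_nodes)]

    path_lengths: list[float] = []
    for u, v in zip(des.initial, des.terminal):
        first = lengths[u, v]
        if first >= r_max:
            continue
        stack = [(int(u), int(v), float(first))]
        while stack:
            pu, pv, acc = stack.pop()
            path_lengths.append(acc)
            for w in neighbors[pv]:
                if w != pu and acc + lengths[pv, w] < r_max:
                    stack.append((pv, int(w), acc + lengths[pv, w]))

    sorted_lengths = np.sort(np.asarray(path_lengths))
    if r_grid is None:
        r_grid = np.linspace(r_max / 8.0, r_max, 16)
    radii = np.asarray(r_grid, dtype=float)
    counts = np.searchsorted(sorted_lengths, radii, side="left")

    half = len(radii) // 2
    sel = (np.arange(len(radii)) >= half) & (counts > 0)
    if sel.sum() < 2:
        raise ValueError("r_max too small: not enough nonzero counts to fit a slope")
    slope = float(np.polyfit(radii[sel], np.log(counts[sel]), 1)[0])
    return PathCountCurve(radii=radii, counts=counts, slope_estimate=slope)
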