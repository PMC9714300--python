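"""Volume entropy: operator construction, spectral solve, path-count oracle."""

import numpy as np
import pytest

import volentropy as ve
from volentropy.entropy import NonpositiveEntropyError, build_L, spectral_radius

from conftest import random_coherence, unit_complete


def brute_force_L(des, h):
    """Independent dense construction of L(h) straight from the definition."""
    m = des.n_edges
    L = np.zeros((m, m))
    for e in range(m):
        for f in range(m):
            if des.terminal[e] == des.initial[f] and des.initial[e] != des.terminal[f]:
                L[e, f] = np.exp(-h * des.lengths[f])
    return L


def test_build_L_matches_definition_by_enumeration(k4_hetero):
    des = ve.directed_edges(k4_hetero)
    for h in (0.0, 0.7):
        np.testing.assert_allclose(
            build_L(des, h).toarray(), brute_force_L(des, h), rtol=0, atol=1e-15
        )


def test_L_at_zero_is_unweighted_nonbacktracking_adjacency(k4):
    des = ve.directed_edges(k4)
    L0 = build_L(des, 0.0).toarray()
    assert L0.shape == (12, 12)
    assert set(np.unique(L0)) == {0.0, 1.0}
    np.testing.assert_array_equal(L0.sum(axis=1), np.full(12, 2.0))  # n-2 = 2
    for e in range(12):
        assert L0[e, des.reverse[e]] == 0.0


def test_build_L_rejects_negative_h(k4):
    with pytest.raises(ValueError, match="nonnegative"):
        build_L(ve.directed_edges(k4), -0.1)


@pytest.mark.parametrize("n, expected", [(4, 2.0), (84, 82.0)])
def test_spectral_radius_of_unit_complete_graph_is_n_minus_2(n, expected):
    des = ve.directed_edges(unit_complete(n))
    assert spectral_radius(build_L(des, 0.0)) == pytest.approx(expected, abs=1e-9)


def test_spectral_radius_is_homogeneous(k4_hetero):
    L = build_L(ve.directed_edges(k4_hetero), 0.3)
    rho = spectral_radius(L)
    assert spectral_radius(L * 3.5) == pytest.approx(3.5 * rho, rel=1e-9)


def test_spectral_radius_agrees_with_dense_eigensolver(k4_hetero):
    L = build_L(ve.directed_edges(k4_hetero), 0.4)
    dense = np.max(np.abs(np.linalg.eigvals(L.toarray())))
    assert spectral_radius(L) == pytest.approx(dense, abs=1e-9)


@pytest.mark.parametrize("n", range(4, 11))
def test_unit_complete_graph_entropy_is_log_n_minus_2(n):
    res = ve.solve_volume_entropy(unit_complete(n))
    assert res.h_vol == pytest.approx(np.log(n - 2), abs=1e-6)
    assert abs(res.rho_at_solution - 1) <= res.tol_rho


def test_equal_length_solution_scales_with_the_common_length():
    # all lengths equal to c: h_vol = log(n-2)/c
    res = ve.solve_volume_entropy(unit_complete(5, length=2.5))
    assert res.h_vol == pytest.approx(np.log(3) / 2.5, abs=1e-6)


@pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
def test_scaling_all_lengths_by_c_divides_entropy_by_c(c):
    vals = random_coherence(7, seed=10)
    g = ve.build_metric_graph(vals)
    base = ve.solve_volume_entropy(g).h_vol
    scaled = ve.MetricGraph(g.node_labels, np.where(np.isfinite(g.lengths), g.lengths * c, np.inf))
    h_c = ve.solve_volume_entropy(scaled).h_vol
    assert h_c == pytest.approx(base / c, rel=1e-6)


def test_spectral_radius_strictly_decreases_in_h(k4_hetero):
    des = ve.directed_edges(k4_hetero)
    rhos = [spectral_radius(build_L(des, h)) for h in np.linspace(0, 2, 9)]
    assert np.all(np.diff(rhos) < 0)


def test_solution_is_unique_under_solver_perturbation():
    g = ve.build_metric_graph(random_coherence(6, seed=11))
    r1 = ve.solve_volume_entropy(g, tol_h=1e-8, tol_rho=1e-10)
    r2 = ve.solve_volume_entropy(g, tol_h=1e-9, tol_rho=1e-11)
    assert abs(r1.h_vol - r2.h_vol) <= 2 * r1.tol_h


def test_entropy_is_invariant_to_node_relabelling():
    vals = random_coherence(6, seed=12)
    perm = np.array([4, 0, 5, 2, 1, 3])
    h1 = ve.solve_volume_entropy(ve.build_metric_graph(vals)).h_vol
    h2 = ve.solve_volume_entropy(ve.build_metric_graph(vals[np.ix_(perm, perm)])).h_vol
    assert h2 == pytest.approx(h1, abs=1e-7)


def test_single_cycle_graph_is_rejected_as_nonpositive_entropy():
    square = ve.MetricGraph.from_edges(
        list("abcd"), {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0, (0, 3): 1.0}
    )
    with pytest.raises(NonpositiveEntropyError):
        ve.solve_volume_entropy(square)


# --- path-counting oracle -------------------------------------------------


def test_oracle_counts_k4_unit_paths_below_r3(k4):
    curve = ve.count_paths_oracle(k4, r_max=3.0, r_grid=[0.5, 1.5, 2.5, 3.0])
    # no path shorter than the shortest edge; 12 single edges; 12*2 two-edge
    np.testing.assert_array_equal(curve.counts, [0, 12, 36, 36])
    assert np.all(np.diff(curve.counts) >= 0)


def test_oracle_guard_refuses_large_graphs():
    with pytest.raises(ValueError, match="guard"):
        ve.count_paths_oracle(unit_complete(7), r_max=5.0)
    # explicit override works
    ve.count_paths_oracle(unit_complete(7), r_max=3.0, override=True)


def test_oracle_growth_rate_matches_spectral_entropy(k4, k4_hetero):
    h4 = ve.solve_volume_entropy(k4).h_vol
    slope = ve.count_paths_oracle(k4, r_max=14.0).slope_estimate
    assert slope == pytest.approx(h4, rel=0.10)

    hh = ve.solve_volume_entropy(k4_hetero).h_vol
    slope_h = ve.count_paths_oracle(k4_hetero, r_max=20.0).slope_estimate
    assert slope_h == pytest.approx(hh, rel=0.10)
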