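"""Volume entropy of small metric graphs: spectral solver vs. path counting.

Builds complete graphs with known entropy, solves rho(L(h)) = 1, and checks
the answer against brute-force enumeration of non-backtracking paths.
"""

import numpy as np

import volentropy as ve


def unit_complete(n):
    edges = {(i, j): 1.0 for i in range(n) for j in range(i + 1, n)}
    return ve.MetricGraph.from_edges([f"n{i}" for i in range(n)], edges)


# For a complete graph on n nodes with unit edge lengths every directed edge
# has exactly n-2 continuations, so the entropy is log(n-2) in closed form.
print("closed-form check on unit complete graphs:")
for n in (4, 6, 10):
    res = ve.solve_volume_entropy(unit_complete(n))
    print(
        f"  K{n}: h_vol = {res.h_vol:.8f}  (log(n-2) = {np.log(n - 2):.8f}, "
        f"{res.iterations} bisection steps)"
    )

# A heterogeneous K4: no closed form, so compare against the definition --
# the growth rate of the number N_r of non-backtracking paths of length < r.
hetero = ve.MetricGraph.from_edges(
    list("abcd"),
    {(0, 1): 1.0, (0, 2): 1.5, (0, 3): 2.0, (1, 2): 2.0, (1, 3): 1.5, (2, 3): 1.0},
)
spectral = ve.solve_volume_entropy(hetero).h_vol
curve = ve.count_paths_oracle(hetero, r_max=20.0)
print("\nheterogeneous K4 (edge lengths 1 / 1.5 / 2):")
print(f"  spectral h_vol            = {spectral:.6f}")
print(f"  path-count growth rate    = {curve.slope_estimate:.6f}")
print(f"  paths counted below r=20  = {curve.counts[-1]}")
print(
    "  The two estimates agree within a few percent; the residual gap is the\n"
    "  finite-r transient of the limit definition."
)
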