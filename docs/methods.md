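# Methods

## Model

A subject's band-specific connectivity is a symmetric matrix of lagged linear
coherence c_ij ∈ (0, 1) over labelled cortical regions (default: 84 Brodmann
areas, the 42 areas resolved by standard EEG source localisation in both
hemispheres).  The induced metric graph is complete, with edge length
l_ij = 1 / c_ij — the conductance/resistance analogy: strong coupling means a
short edge.  The diagonal is ignored; there are no self-loops.

Volume entropy h_vol is the exponential growth rate of the number N_r of
non-backtracking edge paths of total length < r.  It is found spectrally:
the operator L(h) on directed edges has entry exp(−h·l(f)) where f continues
e without reversing it.  For any graph that has no terminal vertices and is
not a single cycle, ρ(L(0)) > 1 and ρ(L(h)) is continuous and strictly
decreasing, so ρ(L(h)) = 1 has a unique root h_vol ≥ 0.  At that root the
Perron eigenvector gives strictly positive edge capacities (Perron–Frobenius:
the operator is irreducible and, for complete graphs on ≥ 4 nodes,
primitive); afferent node capacity sums capacities by terminal node.

Assumptions worth stating plainly: the graph must be complete (or at least
biconnected enough that the non-backtracking operator is irreducible) with
finite positive lengths; coherence is symmetric by definition, so asymmetric
input beyond numerical noise (1e-9 max-norm) is treated as data corruption,
not averaged silently.

## Parameters

| parameter | default | units / scale | why |
|---|---|---|---|
| `min_coherence` (ε) | 1e-6 | coherence | zero coherence would give an infinite edge; clamping keeps the model's complete-graph assumption instead of deleting edges. The reciprocal cap (1−ε) avoids zero-length edges. |
| `tol_h` | 1e-8 | 1/length | bisection bracket width on h. |
| `tol_rho` | 1e-10 | spectral radius | Collatz–Wielandt enclosure width for ρ, and the accepted |ρ−1| at the returned h. |
| `n_perm` | 10,000 | — | permutation count of the reference analysis. |
| `alpha` | 0.05 | — | per-test significance level; no multiplicity correction by default (an optional Benjamini–Hochberg flag exists). |
| bands | 8 | Hz | delta 2–3.5, theta 4–7.5, alpha1 8–10, alpha2 10–12, beta1 13–18, beta2 18.5–21, beta3 21.5–30, gamma 30.5–44. |

## Numerical choices

- **Eigenvalues.** Power iteration from the all-ones vector with a
  Collatz–Wielandt enclosure: min and max of (Lx)_i/x_i bracket the Perron
  root, giving a certified stopping rule rather than a heuristic one.  For
  complete graphs the matvec uses an O(n²) reformulation (row sums of the
  weighted coherence field minus the backtracking term) instead of the
  O(n³)-entry sparse operator, which makes the 6,972-edge problem take
  milliseconds.  A dense eigensolver is the fallback for small systems where
  the iteration cannot converge (periodic structure, zero rows).
- **Root finding.** Plain bisection on h.  The initial upper bracket
  log(max row sum of L(0)) / l_min is rigorous (row sums of L(h) decay at
  least like exp(−h·l_min)) and is doubled if ever insufficient.  Bisection
  continues until the bracket is below `tol_h` *and* |ρ(h)−1| ≤ `tol_rho`,
  so the eigenvector residual at the returned h is small enough for capacity
  computation.  Strict decrease of ρ across all evaluated h is asserted after
  the solve; a violation is reported as a numerical error.
- **Ties in permutation tests.** |T_perm| ≥ |T_obs| is evaluated with a
  1e-12 relative slack so exact mirror splits count as ties despite floating
  rounding.  The Monte-Carlo p uses the add-one estimator
  (1 + hits)/(1 + n_perm), which never returns 0; the exhaustive oracle
  returns the exact permutation p (#{|T| ≥ |T_obs|}/total, observed split
  included), which the Monte-Carlo estimator converges to.
- **Degenerate inputs.** Constant pooled values give p = 1 exactly.  Graphs
  with fewer than 4 nodes, terminal vertices, or single-cycle topology are
  rejected before the solve: their path counts do not grow exponentially, so
  h_vol ≤ 0 and the model does not apply.
- **Canonical ordering.** Directed edges are ordered lexicographically by
  (initial, terminal) node index, and subjects are sorted by id inside each
  permutation test, so eigenvectors and p-values are bit-reproducible across
  platforms and invariant to input row order.

## Synthetic cohort generator

The generator emulates the *design* of a two-group EEG connectivity study —
30 vs 15 subjects, 8 bands, 84 regions, coherence in (0,1) — not EEG itself.
The latent field z_ij = baseline_mean + u_s + e_ij (subject effect
u_s ~ N(0, subject_sd²); edge noise e_ij ~ N(0, edge_sd²) per subject, band
and unordered edge) maps through the logistic link to coherence, clamped to
[ε, 1−ε].  A planted effect (roi, band, group, δ) adds δ on the latent scale
to every edge incident to the region, for that group and band only — a
node-level effect, matching the node-level group differences the measure is
meant to detect.  Defaults: baseline_mean = −1.0 (typical coherence ≈ 0.27,
a realistic lagged-coherence level), subject_sd = 0.3, edge_sd = 0.5.  The
study this design mirrors reports no within-group variability, so these two
scales are conventions chosen to give plausible between-subject spread; they
are documented here and fixed.

Per-(subject, band) RNG substreams are derived by hashing, so enlarging the
cohort or reordering bands never changes existing subjects' data.

What the generator does **not** model: oscillatory time series, volume
conduction, source-localisation error, spatial correlation between
neighbouring regions, band-to-band dependence within a subject, or
heavy-tailed coherence distributions.  Passing tests therefore demonstrate
that the pipeline is correct and calibrated under a clean exchangeable null
and detects node-incident effects of moderate size — not that real EEG
effects of a given clinical magnitude would be detected.

## Statistical design

The test statistic is the difference of group means; the null is built by
reassigning pooled values to groups of the original sizes.  Tests are
two-sided, with direction read from the sign of the observed difference.
Each comparison row draws its permutations from a substream keyed by
(seed, target, band): row order, table composition and band subsets never
affect p-values.  Volume entropy is compared per band with the identical
machinery used for node capacities.

One consequence of sum-to-one normalisation deserves note: a large planted
gain at one region necessarily depresses the *relative* capacity of the
remaining regions in the affected group, so under a strong planted effect the
off-target rejection rate sits somewhat above the nominal α (about 9–10% at
α = 5% for a 3·edge_sd effect in validation runs) — these are real
compositional differences, not false positives of the test.  Under a pure
null the empirical type-I rate is nominal.

## Validation problem sizes

The heavy validation studies use sizes chosen to exercise the full pipeline
while staying desk-scale: the null-calibration study runs one full cohort
(45 subjects × 8 bands × 84 regions, 999 permutations per test, 672
region-band tests); the recovery study runs 20 replicate single-band cohorts
(45 subjects × 84 regions each).  The path-counting oracle is restricted to
graphs with ≤ 30 directed edges (enumeration is exponential in r_max).

## Known limitations

- Volume entropy is defined here only for undirected, connected, fully
  weighted graphs; thresholded/sparse or directed connectivity variants are
  out of scope.
- The efferent node capacity is reported but carries little local
  information in richly connected graphs (its near-uniformity is an
  empirical observation, logged via the homogeneity diagnostic, not a
  theorem for arbitrary lengths).
- The permutation test assumes exchangeability of subjects across groups
  under the null; confounders (age, duration of illness) are not modelled.
- With 680 uncorrected tests at α = 0.05, ≈ 34 false positives are expected
  under the global null; interpretation of single significant rows should
  weigh that, or enable the Benjamini–Hochberg option.
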