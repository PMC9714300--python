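# volentropy

Volume entropy and afferent node capacity of brain connectivity networks, with
permutation-based group comparison.

## The problem

Source-localised EEG yields, for each subject and frequency band, a symmetric
matrix of lagged linear coherence between cortical regions (here 84 Brodmann
areas, 42 per hemisphere).  Treating each coherence value as a conductance,
its reciprocal becomes an edge *length*, and the subject's brain network
becomes a fully connected **metric graph**: 84 nodes, 3,486 weighted
undirected edges.  Two questions follow:

- **Globally**, how fast does the number of distinct routes through the
  network grow — how much information can it spread?
- **Locally**, which regions receive a disproportionate share of that flow?

Both are answered by one spectral object.  The **volume entropy** of a metric
graph X is

```
h_vol = lim_{r→∞} log(N_r) / r
```

where N_r counts the non-backtracking edge paths of total length below r.
It is computed from the matrix L(h), indexed by the 2|E| = 6,972 directed
edges, with

```
L(h)[e, f] = exp(−h · l(f))   if t(e) = i(f) and i(e) ≠ t(f),   else 0
```

(i(·), t(·) are initial/terminal nodes; the condition says f continues e
without immediately reversing it).  The largest eigenvalue of L(0) exceeds 1
and decreases strictly as h grows, so there is a unique h with spectral
radius exactly 1 — that h is h_vol.  At the solution, the Perron eigenvector
x of L(h_vol) assigns every directed edge a positive **edge capacity** x_e;
summing capacities over edges *terminating* at a node gives its **afferent
node capacity**, a local measure of inbound information flow (the efferent
analogue is computed as a diagnostic only — it is nearly uniform in richly
connected graphs).  Capacities are normalised to sum to 1 per subject.

Group differences (e.g. between 30 patients with and 15 without a clinical
trait) are assessed per (region, band) for afferent capacity and per band
for volume entropy, with a two-sided label-permutation test on the
difference of group means (default 10,000 permutations, α = 0.05 per test,
no multiplicity correction).

Because patient EEG is not distributable, the package includes a
synthetic-cohort generator with *planted* group effects, so the whole
pipeline — and its statistical calibration — is testable end to end.

## Worked example

```python
import numpy as np
import volentropy as ve

edges = {(i, j): 1.0 for i in range(4) for j in range(i + 1, 4)}
k4 = ve.MetricGraph.from_edges(["a", "b", "c", "d"], edges)

res = ve.solve_volume_entropy(k4)
print(res.h_vol)                      # 0.6931471806  == log(4 - 2)

des = ve.directed_edges(k4)
x = ve.compute_edge_capacities(des, res.h_vol)
print(ve.afferent_node_capacity(x, des).afferent)   # [0.25 0.25 0.25 0.25]

curve = ve.count_paths_oracle(k4, r_max=14.0)
print(curve.slope_estimate)           # 0.6573745700  (path-count growth rate)
```

For the unit K4 every directed edge has exactly 2 continuations, so
h_vol = log 2 ≈ 0.6931 in closed form — the solver reproduces it to 1e-10,
full symmetry forces each node to receive exactly 1/4 of the flow, and
brute-force path counting up to length 14 estimates the same growth rate to
within 5% (the gap is the finite-r transient of the limit).

The `examples/` directory contains short narrative scripts for each stage:
entropy basics (`01`), synthetic cohorts and per-subject features (`02`), and
planted-effect group comparison (`03`).  The same pipeline is scriptable from
the shell:

```sh
volentropy simulate --config cfg.yaml --out cohort/
volentropy compute  --manifest cohort/manifest.tsv --config cfg.yaml --out features.tsv
volentropy compare  --features features.tsv --config cfg.yaml --out comparison.tsv
```

All interchange formats are plain text (CSV matrices with ROI labels, TSV
manifests and tables, flat YAML config).

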