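"""Planted-effect recovery: the full simulate -> compute -> compare pipeline.

Plants a coherence increase on every edge incident to one region, for one
group in one band, then checks that the permutation comparison points at
exactly that (region, band) with the right direction.
"""

import volentropy as ve
from volentropy.io import RunConfig
from volentropy.pipeline import compute_features, run_comparison, summarize_comparison

ROIS = ve.DEFAULT_ROI_LABELS[:12]
TARGET, BAND = ROIS[5], "beta2"

cohort_cfg = ve.CohortConfig(
    n_group_a=12,
    n_group_b=8,
    roi_labels=ROIS,
    bands=("alpha1", "beta2"),
    effects=[ve.Effect(TARGET, BAND, "A", 1.5)],  # 3 x edge_sd on the latent scale
    seed=5,
)
run_cfg = RunConfig(n_perm=4999, seed=17, bands=cohort_cfg.bands)

report = compute_features(ve.generate_cohort(cohort_cfg), run_cfg)
table = run_comparison(report.features, run_cfg)

print(f"planted: group A coherence bump on edges of {TARGET}, band {BAND}\n")
print(summarize_comparison(table, run_cfg.alpha))
row = table[(table.target == TARGET) & (table.band == BAND)].iloc[0]
print(
    f"\nplanted row: mean_A={row.mean_group_a:.4f} mean_B={row.mean_group_b:.4f} "
    f"p={row.p_value:.4f}"
)
print(
    "The planted region's afferent capacity is clearly higher in group A;\n"
    "other rows should mostly be non-significant (capacities sum to one, so a\n"
    "large planted gain slightly depresses the remaining regions of group A)."
)
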