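"""Permutation tests and the group-comparison table."""

import numpy as np
import pandas as pd
import pytest

import volentropy as ve
from volentropy.stats import ENTROPY_TARGET, features_frame


def test_exhaustive_p_for_separated_pairs():
    # pooled {1,2,3,4}, groups of 2: |T| over the six splits is 2,1,0,0,1,2,
    # so two of six assignments reach the observed |T| = 2
    assert ve.exhaustive_permutation_test([1, 2], [3, 4]) == pytest.approx(2 / 6)


def test_exhaustive_degenerate_cases():
    assert ve.exhaustive_permutation_test([0.0], [1.0]) == 1.0
    assert ve.exhaustive_permutation_test([1.0, 2.0], [2.0, 1.0]) == 1.0


def test_exhaustive_refuses_combinatorial_explosion():
    with pytest.raises(ValueError, match="exceed"):
        ve.exhaustive_permutation_test(np.arange(12), np.arange(12), max_combinations=1000)


def test_exhaustive_p_invariant_to_group_swap():
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=4), rng.normal(0.5, 1, size=6)
    assert ve.exhaustive_permutation_test(a, b) == pytest.approx(
        ve.exhaustive_permutation_test(b, a)
    )


def test_monte_carlo_matches_exhaustive_within_3_standard_errors():
    from volentropy._util import substream

    for n_a, n_b in [(2, 2), (3, 4), (5, 5)]:
        data = substream(1, "data", n_a, n_b)
        a, b = data.normal(size=n_a), data.normal(0.8, 1, size=n_b)
        exact = ve.exhaustive_permutation_test(a, b)
        mc = ve.permutation_test(
            a, b, n_perm=10_000, seed=substream(1, "mc", n_a, n_b)
        ).p_value
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(mc - exact) <= 3 * se + 2e-4


def test_monte_carlo_is_deterministic_and_never_zero():
    a, b = np.arange(5.0), np.arange(10.0, 15.0)
    r1 = ve.permutation_test(a, b, seed=9)
    r2 = ve.permutation_test(a, b, seed=9)
    assert r1 == r2
    assert 0 < r1.p_value <= 1


def test_constant_pooled_values_give_null_result():
    res = ve.permutation_test([2.0, 2.0], [2.0, 2.0, 2.0])
    assert res == ve.PermutationResult(0.0, 1.0)


def test_empty_group_and_zero_permutations_rejected():
    with pytest.raises(ValueError):
        ve.permutation_test([], [1.0])
    with pytest.raises(ValueError):
        ve.permutation_test([1.0], [2.0], n_perm=0)


# --- comparison table -----------------------------------------------------

ROIS = ("r1", "r2", "r3", "r4")
BANDS = ("delta", "beta2")


def synthetic_features(n_a=8, n_b=6, shift_roi=None, shift=0.0, seed=0):
    """Features frame with Dirichlet-style afferent rows; optional planted
    group-A shift on one ROI in band beta2."""
    rng = np.random.default_rng(seed)
    records = []
    for group, count in (("A", n_a), ("B", n_b)):
        for k in range(count):
            for band in BANDS:
                raw = rng.gamma(20.0, size=len(ROIS))
                if shift_roi is not None and group == "A" and band == "beta2":
                    raw[ROIS.index(shift_roi)] *= 1 + shift
                records.append(
                    ve.SubjectFeatures(
                        subject_id=f"{group}{k}",
                        group=group,
                        band=band,
                        h_vol=rng.normal(4.0, 0.1),
                        afferent=raw / raw.sum(),
                        roi_labels=ROIS,
                    )
                )
    return features_frame(records)


def test_compare_groups_row_count_and_schema():
    table = ve.compare_groups(synthetic_features(), n_perm=200, seed=3)
    assert len(table) == (len(ROIS) + 1) * len(BANDS)
    assert list(table.columns) == [
        "target", "band", "mean_group_a", "mean_group_b",
        "observed_diff", "p_value", "significant",
    ]
    assert ((table.p_value > 0) & (table.p_value <= 1)).all()
    assert (table.significant == (table.p_value < 0.05)).all()
    assert (table.target == ENTROPY_TARGET).sum() == len(BANDS)


def test_compare_groups_p_values_do_not_depend_on_row_or_table_composition():
    feats = synthetic_features()
    t1 = ve.compare_groups(feats, n_perm=300, seed=4)
    shuffled = feats.sample(frac=1.0, random_state=1).reset_index(drop=True)
    t2 = ve.compare_groups(shuffled, n_perm=300, seed=4)
    pd.testing.assert_frame_equal(t1, t2)
    # dropping a band leaves the other band's rows untouched
    only_delta = feats[feats.band == "delta"]
    t3 = ve.compare_groups(only_delta, n_perm=300, seed=4)
    merged = t1[t1.band == "delta"].reset_index(drop=True)
    pd.testing.assert_frame_equal(merged, t3)


def test_planted_shift_is_detected_with_correct_direction():
    table = ve.compare_groups(
        synthetic_features(shift_roi="r2", shift=0.8, seed=5), n_perm=999, seed=6
    )
    row = table[(table.target == "r2") & (table.band == "beta2")].iloc[0]
    assert row.significant and row.observed_diff > 0
    clean = table[(table.target == "r2") & (table.band == "delta")].iloc[0]
    assert clean.p_value > 0.05


def test_compare_groups_input_validation():
    feats = synthetic_features()
    with pytest.raises(ValueError, match="two groups"):
        ve.compare_groups(feats[feats.group == "A"])
    gappy = feats.drop(feats[(feats.subject_id == "A0") & (feats.band == "beta2")].index)
    with pytest.raises(ValueError, match="A0"):
        ve.compare_groups(gappy)


def test_benjamini_hochberg_flag_is_more_conservative():
    feats = synthetic_features(shift_roi="r2", shift=0.5, seed=8)
    plain = ve.compare_groups(feats, n_perm=499, seed=9)
    bh = ve.compare_groups(feats, n_perm=499, seed=9, correction="bh")
    assert bh.significant.sum() <= plain.significant.sum()
    assert (bh.p_adjusted >= bh.p_value - 1e-15).all()
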