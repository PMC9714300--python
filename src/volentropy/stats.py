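"""Permutation-based comparison of two subject groups.

For every (ROI, band) the groups' mean afferent node capacities are compared,
and for every band their mean volume entropies, with a label-permutation test:
the observed statistic is the difference in group means, the null is built by
reassigning the pooled values to groups of the original sizes, and the
two-sided Monte-Carlo p-value uses the add-one estimator

    p = (1 + #{ |T_perm| >= |T_obs| }) / (1 + n_perm),

which never returns zero.  Defaults follow the reference analysis: 10,000
permutations, alpha = 0.05 per test, no multiplicity correction (an optional
Benjamini-Hochberg flag is provided but off by default).  An exhaustive
enumeration over all group assignments serves as the exact oracle on small
groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import substream

__all__ = [
    "SubjectFeatures",
    "PermutationResult",
    "permutation_test",
    "exhaustive_permutation_test",
    "compare_groups",
    "features_frame",
    "ENTROPY_TARGET",
]

#: Row label used for the per-band volume-entropy comparison.
ENTROPY_TARGET = "VOLUME_ENTROPY"

#: Relative slack when comparing |T_perm| against |T_obs|, so that splits
#: that are exact mirrors of the observed one count as ties despite rounding.
_TIE_REL = 1e-12


@dataclass
class SubjectFeatures:
    """Per-subject, per-band features entering the group comparison."""

    subject_id: str
    group: str
    band: str
    h_vol: float
    afferent: np.ndarray
    roi_labels: tuple[str, ...]


@dataclass
class PermutationResult:
    observed_diff: float
    p_value: float


def _tie_threshold(t_obs: float) -> float:
    return abs(t_obs) * (1.0 - _TIE_REL) - 1e-300


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Two-sided Monte-Carlo permutation test on the difference of means.

    Deterministic given ``seed`` (an int or a ready-made Generator).
    Constant pooled values are an exact null: returns p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t_obs = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return PermutationResult(0.0, 1.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, n_a = pooled.size, a.size
    # one permutation per row, via argsort of iid uniforms
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = pooled[order]
    t_perm = shuffled[:, :n_a].mean(axis=1) - shuffled[:, n_a:].mean(axis=1)
    hits = int(np.sum(np.abs(t_perm) >= _tie_threshold(t_obs)))
    p = (1 + hits) / (1 + n_perm)
    return PermutationResult(t_obs, p)


def exhaustive_permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    max_combinations: int = 200_000,
) -> float:
    """Exact two-sided permutation p-value by full enumeration.

    p = #{ assignments with |T| >= |T_obs| } / C(n_a + n_b, n_a); the observed
    assignment is always counted, so p > 0.  Refuses problems with more than
    ``max_combinations`` assignments.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, n_a = a.size + b.size, a.size
    total = math.comb(n, n_a)
    if total > max_combinations:
        raise ValueError(f"{total} assignments exceed the bound {max_combinations}")
    pooled = np.concatenate([a, b])
    t_obs = float(a.mean() - b.mean())
    thresh = _tie_threshold(t_obs)
    grand = pooled.sum()
    hits = 0
    for idx in combinations(range(n), n_a):
        sum_a = pooled[list(idx)].sum()
        t = sum_a / n_a - (grand - sum_a) / (n - n_a)
        if abs(t) >= thresh:
            hits += 1
    return hits / total


def features_frame(features: Sequence[SubjectFeatures]) -> pd.DataFrame:
    """Tabulate SubjectFeatures records: one row per (subject, band), columns
    subject_id, group, band, h_vol, then one afferent column per ROI."""
    if not features:
        raise ValueError("no features given")
    labels = features[0].roi_labels
    rows = []
    for f in features:
        if tuple(f.roi_labels) != tuple(labels):
            raise ValueError(
                f"inconsistent ROI labels for subject {f.subject_id!r}"
            )
        rows.append(
            {
                "subject_id": f.subject_id,
                "group": f.group,
                "band": f.band,
                "h_vol": f.h_vol,
                **dict(zip(labels, f.afferent)),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    features: pd.DataFrame | Sequence[SubjectFeatures],
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-(ROI, band) and per-band group comparison table.

    ``features`` is a frame as produced by :func:`features_frame` (or the
    pipeline): columns ``subject_id, group, band, h_vol`` plus one afferent
    column per ROI.  Each row of the result is one permutation test; the RNG
    substream of a row depends only on (seed, target, band), so row order and
    table composition never change p-values.  ``correction='bh'`` applies
    Benjamini-Hochberg to the p-values before flagging significance
    (off by default, matching an uncorrected per-test alpha).
    """
    if not isinstance(features, pd.DataFrame):
        features = features_frame(features)
    meta = ["subject_id", "group", "band", "h_vol"]
    missing = [c for c in meta if c not in features.columns]
    if missing:
        raise ValueError(f"features table lacks columns {missing}")
    roi_cols = [c for c in features.columns if c not in meta]
    if not roi_cols:
        raise ValueError("features table has no ROI columns")
    groups = sorted(features["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    bands = list(dict.fromkeys(features["band"]))
    gaps = []
    for sid, sub in features.groupby("subject_id", sort=False):
        absent = set(bands) - set(sub["band"])
        if absent:
            gaps.append(f"{sid}: missing {sorted(absent)}")
    if gaps:
        raise ValueError("incomplete band coverage — " + "; ".join(gaps))
    for g in groups:
        if (features["group"] == g).sum() < 2 * len(bands):
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    ga, gb = groups
    rows = []
    for band in bands:
        # canonical subject order: p-values must not depend on row order
        sub = features[features["band"] == band].sort_values("subject_id")
        in_a = (sub["group"] == ga).to_numpy()
        for target in [*roi_cols, ENTROPY_TARGET]:
            col = "h_vol" if target == ENTROPY_TARGET else target
            vals = sub[col].to_numpy(dtype=float)
            va, vb = vals[in_a], vals[~in_a]
            res = permutation_test(
                va, vb, n_perm=n_perm, seed=substream(seed, target, band)
            )
            rows.append(
                {
                    "target": target,
                    "band": band,
                    "mean_group_a": va.mean(),
                    "mean_group_b": vb.mean(),
                    "observed_diff": res.observed_diff,
                    "p_value": res.p_value,
                }
            )
    table = pd.DataFrame(rows).sort_values(["band", "target"], ignore_index=True)
    if correction == "bh":
        from scipy.stats import false_discovery_control

        table["p_adjusted"] = false_discovery_control(table["p_value"], method="bh")
        table["significant"] = table["p_adjusted"] < alpha
    elif correction is None:
        table["significant"] = table["p_value"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return table
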