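"""End-to-end orchestration: connectivity matrices -> features -> comparison.

One subject x band matrix flows through metric-graph construction, the
volume-entropy solve and capacity aggregation to yield a feature record
(h_vol plus the afferent capacity of every ROI); a cohort of records is then
compared between groups with permutation tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .capacity import afferent_node_capacity, compute_edge_capacities
from .cohort import ConnectivityMatrix
from .entropy import solve_volume_entropy
from .graph import build_metric_graph, directed_edges
from .io import RunConfig
from .stats import SubjectFeatures, compare_groups, features_frame

log = logging.getLogger("volentropy")

__all__ = ["subject_features", "compute_features", "summarize_comparison"]


def subject_features(
    matrix: ConnectivityMatrix, config: RunConfig | None = None
) -> SubjectFeatures:
    """Compute one subject x band feature record: volume entropy and the
    afferent node capacity of every ROI."""
    config = config or RunConfig()
    graph = build_metric_graph(matrix, min_coherence=config.min_coherence)
    des = directed_edges(graph)
    result = solve_volume_entropy(
        graph, tol_h=config.tol_h, tol_rho=config.tol_rho, des=des
    )
    x = compute_edge_capacities(des, result.h_vol)
    nodes = afferent_node_capacity(x, des)
    return SubjectFeatures(
        subject_id=matrix.subject_id,
        group=matrix.group,
        band=matrix.band,
        h_vol=result.h_vol,
        afferent=nodes.afferent,
        roi_labels=graph.node_labels,
    )


@dataclass
class ComputeReport:
    """Features for the subjects that succeeded, plus per-record failures."""

    features: pd.DataFrame
    failures: list[tuple[str, str, str]]  # (subject_id, band, message)


def compute_features(
    cohort: Sequence[ConnectivityMatrix], config: RunConfig | None = None
) -> ComputeReport:
    """Run the per-subject pipeline over a cohort.

    A failing record is logged and skipped rather than aborting the batch;
    callers inspect ``failures`` (the CLI maps a partial result to a distinct
    exit status).
    """
    config = config or RunConfig()
    records: list[SubjectFeatures] = []
    failures: list[tuple[str, str, str]] = []
    for k, mat in enumerate(cohort):
        try:
            records.append(subject_features(mat, config))
            log.info(
                "[%d/%d] %s %s: h_vol=%.6f",
                k + 1,
                len(cohort),
                mat.subject_id,
                mat.band,
                records[-1].h_vol,
            )
        except Exception as exc:  # noqa: BLE001 - batch mode reports, not raises
            failures.append((mat.subject_id, mat.band, str(exc)))
            log.error("[%d/%d] %s %s failed: %s", k + 1, len(cohort), mat.subject_id, mat.band, exc)
    features = features_frame(records) if records else pd.DataFrame()
    return ComputeReport(features=features, failures=failures)


def summarize_comparison(table: pd.DataFrame, alpha: float = 0.05) -> str:
    """Human-readable summary: significant (target, band, direction) triples
    plus the expected false-positive count at the per-test alpha."""
    sig = table[table["significant"]]
    lines = [
        f"{len(sig)} of {len(table)} comparisons significant at alpha={alpha:g} "
        f"(about {alpha * len(table):.1f} expected under the null):"
    ]
    for row in sig.itertuples(index=False):
        direction = "A > B" if row.observed_diff > 0 else "B > A"
        lines.append(
            f"  {row.target:>16s}  {row.band:<8s} {direction}  p={row.p_value:.4f}"
        )
    return "\n".join(lines)


def run_comparison(
    features: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Group comparison with the run configuration's test parameters."""
    config = config or RunConfig()
    return compare_groups(
        features,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=config.seed,
        correction=config.correction,
    )
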