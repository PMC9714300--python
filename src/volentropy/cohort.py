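"""Synthetic two-group cohorts of band-specific connectivity matrices.

Real lagged-coherence connectivity from source-localised EEG is not publicly
distributable, so every downstream stage of the pipeline is exercised against
synthetic cohorts with *known* planted group differences.  The generative model
is deliberately simple and fully documented:

    z_ij = baseline_mean + u_s + e_ij        (latent, symmetric in i,j)
    u_s  ~ N(0, subject_sd^2)                per subject
    e_ij ~ N(0, edge_sd^2)                   per unordered edge, subject, band

Each planted effect ``(roi, band, group, delta)`` adds ``delta`` to ``z_ij``
for every edge incident to ``roi``, for subjects of ``group`` in ``band``
only.  Coherence is ``logistic(z)`` clamped to ``[eps, 1 - eps]`` so the
induced metric graph is always fully connected with finite positive lengths.

Randomness is reproducible and *stable*: each subject x band draws from its
own stream derived by hashing ``(seed, subject_id, band)``, so enlarging the
cohort or reordering bands never reshuffles existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from ._util import substream as _substream
from .rois import DEFAULT_ROI_LABELS

__all__ = [
    "DEFAULT_BANDS",
    "GROUPS",
    "Effect",
    "CohortConfig",
    "ConnectivityMatrix",
    "ConfigError",
    "generate_cohort",
    "write_cohort",
]

#: The eight analysis frequency bands with their ranges in Hz.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 3.5),
    "theta": (4.0, 7.5),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 12.0),
    "beta1": (13.0, 18.0),
    "beta2": (18.5, 21.0),
    "beta3": (21.5, 30.0),
    "gamma": (30.5, 44.0),
}

#: The two group labels. Group A plays the role of the larger cohort.
GROUPS: tuple[str, str] = ("A", "B")


class ConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class Effect:
    """A planted group difference: ``delta`` added (on the latent scale) to
    every edge incident to ``roi``, for subjects of ``group``, in ``band``."""

    roi: str
    band: str
    group: str
    delta: float


@dataclass
class CohortConfig:
    """Study design for a synthetic cohort.

    Defaults mirror the reference study design: 30 vs 15 subjects, 84
    Brodmann-area nodes, eight frequency bands.  ``baseline_mean``,
    ``subject_sd`` and ``edge_sd`` live on the latent (logit) scale; the
    default baseline of -1.0 puts typical coherence near 0.27, a realistic
    level for lagged coherence between cortical sources.
    """

    n_group_a: int = 30
    n_group_b: int = 15
    roi_labels: Sequence[str] = DEFAULT_ROI_LABELS
    bands: Sequence[str] = tuple(DEFAULT_BANDS)
    baseline_mean: float = -1.0
    subject_sd: float = 0.3
    edge_sd: float = 0.5
    effects: Sequence[Effect] = field(default_factory=tuple)
    min_coherence: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        self.roi_labels = tuple(self.roi_labels)
        self.bands = tuple(self.bands)
        self.effects = tuple(
            e if isinstance(e, Effect) else Effect(*e) for e in self.effects
        )
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ConfigError("each group needs at least 2 subjects")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ConfigError("roi_labels must be unique")
        if len(self.roi_labels) < 4:
            raise ConfigError("at least 4 ROIs required for a valid metric graph")
        if not self.bands:
            raise ConfigError("at least one band required")
        if not (0.0 < self.min_coherence < 0.5):
            raise ConfigError("min_coherence must lie in (0, 0.5)")
        for eff in self.effects:
            if eff.roi not in self.roi_labels:
                raise ConfigError(f"effect references unknown ROI {eff.roi!r}")
            if eff.band not in self.bands:
                raise ConfigError(f"effect references unknown band {eff.band!r}")
            if eff.group not in GROUPS:
                raise ConfigError(f"effect references unknown group {eff.group!r}")
            if not np.isfinite(eff.delta):
                raise ConfigError(f"effect delta must be finite: {eff}")

    @property
    def subject_ids(self) -> list[tuple[str, str]]:
        """``(group, subject_id)`` pairs, group A first, stable order."""
        width = max(2, len(str(max(self.n_group_a, self.n_group_b))))
        out = [("A", f"A{k + 1:0{width}d}") for k in range(self.n_group_a)]
        out += [("B", f"B{k + 1:0{width}d}") for k in range(self.n_group_b)]
        return out


@dataclass
class ConnectivityMatrix:
    """One subject's coherence matrix for one frequency band.

    ``values`` is square, symmetric, zero on the diagonal, with off-diagonal
    entries in ``(0, 1)``.
    """

    subject_id: str
    group: str
    band: str
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )


def generate_cohort(config: CohortConfig) -> list[ConnectivityMatrix]:
    """Generate one connectivity matrix per subject per band.

    Deterministic given ``config.seed``; matrices appear grouped by subject
    (group A first) and, within a subject, in band order.
    """
    labels = config.roi_labels
    n = len(labels)
    roi_index = {lab: i for i, lab in enumerate(labels)}
    iu = np.triu_indices(n, k=1)
    eps = config.min_coherence

    effects_by_gb: dict[tuple[str, str], list[Effect]] = {}
    for eff in config.effects:
        effects_by_gb.setdefault((eff.group, eff.band), []).append(eff)

    cohort: list[ConnectivityMatrix] = []
    for group, sid in config.subject_ids:
        u_s = config.subject_sd * _substream(config.seed, sid, "subject").standard_normal()
        for band in config.bands:
            rng = _substream(config.seed, sid, band)
            z = np.zeros((n, n))
            z[iu] = config.baseline_mean + u_s + config.edge_sd * rng.standard_normal(
                len(iu[0])
            )
            for eff in effects_by_gb.get((group, band), ()):
                # data live in the upper triangle only; each incident edge
                # {r, j} appears there exactly once, as (r, j>r) or (i<r, r)
                r = roi_index[eff.roi]
                z[r, r + 1 :] += eff.delta
                z[:r, r] += eff.delta
            z = z + z.T
            values = np.clip(expit(z), eps, 1.0 - eps)
            np.fill_diagonal(values, 0.0)
            cohort.append(ConnectivityMatrix(sid, group, band, labels, values))
    return cohort


def write_cohort(cohort: Sequence[ConnectivityMatrix], directory: str | Path) -> Path:
    """Write a cohort to ``directory`` as CSV matrices plus a TSV manifest.

    Returns the manifest path.  One file per (subject, band); the manifest has
    columns ``subject_id  group  band  path`` with paths relative to the
    manifest's directory.  Refuses an empty cohort before touching the disk.
    """
    from .io import write_connectivity  # local import: io depends on this module

    if not cohort:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for mat in cohort:
        fname = f"{mat.subject_id}_{mat.band}.csv"
        write_connectivity(mat, directory / fname)
        rows.append((mat.subject_id, mat.group, mat.band, fname))
    manifest = directory / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("subject_id\tgroup\tband\tpath\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return manifest
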