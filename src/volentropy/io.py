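"""Plain-text interchange: connectivity matrices, manifests, configs, tables.

Everything the pipeline reads or writes is plain text: connectivity matrices
are CSV with ROI labels as header row and first column (full symmetric matrix
written), manifests and result tables are TSV, and run configuration is a flat
YAML mapping.  Values are written with 17 significant digits so write/read
round-trips reproduce doubles exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import DEFAULT_BANDS, ConnectivityMatrix
from .graph import SYMMETRY_TOL

__all__ = [
    "ParseError",
    "RunConfig",
    "read_connectivity",
    "write_connectivity",
    "read_manifest",
    "load_cohort",
    "load_config_mapping",
    "write_run_info",
    "read_features",
    "write_features",
]

FLOAT_FORMAT = "%.17g"


class ParseError(ValueError):
    """A file does not conform to the interchange format."""


def write_connectivity(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Write a labelled coherence matrix as CSV (lossless at double precision)."""
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path, float_format=FLOAT_FORMAT)


def read_connectivity(
    path: str | Path,
    subject_id: str = "",
    group: str = "",
    band: str = "",
    expected_labels: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Read a labelled CSV coherence matrix, validating shape and symmetry.

    Errors name the offending line (1-based, header included).  Row labels
    must repeat the header labels in order; asymmetry beyond 1e-9 in any cell
    is an error, smaller asymmetry is averaged away; the diagonal is forced
    to zero.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split(",")
    labels = tuple(h.strip() for h in header[1:])
    n = len(labels)
    if n == 0:
        raise ParseError(f"{path}, line 1: no column labels")
    if len(lines) - 1 != n:
        raise ParseError(
            f"{path}: expected {n} data rows for {n} labels, found {len(lines) - 1}"
        )
    values = np.empty((n, n))
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != n + 1:
            raise ParseError(
                f"{path}, line {i}: ragged row ({len(cells)} cells, expected {n + 1})"
            )
        if cells[0].strip() != labels[i - 2]:
            raise ParseError(
                f"{path}, line {i}: row label {cells[0].strip()!r} does not match "
                f"header label {labels[i - 2]!r}"
            )
        try:
            values[i - 2] = [float(c) for c in cells[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}, line {i}: non-numeric entry ({exc})") from None
    if expected_labels is not None and tuple(expected_labels) != labels:
        raise ParseError(
            f"{path}: ROI labels disagree with the manifest-wide label set"
        )
    asym = np.abs(values - values.T)
    if asym.max() > SYMMETRY_TOL:
        i, j = np.unravel_index(asym.argmax(), asym.shape)
        raise ParseError(
            f"{path}: asymmetric at ({labels[i]}, {labels[j]}): "
            f"{values[i, j]!r} vs {values[j, i]!r}"
        )
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(subject_id, group, band, labels, values)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest (TSV).

    Columns must be exactly ``subject_id, group, band, path``; (subject, band)
    pairs must be unique, the group column must take exactly two values, and
    every path must resolve relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["subject_id", "group", "band", "path"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: manifest columns {list(df.columns)} != {expected}")
    dup = df.duplicated(subset=["subject_id", "band"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate (subject, band) = ({first.subject_id}, {first.band})"
        )
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ParseError(f"{path}: expected exactly two groups, found {groups}")
    root = path.parent
    for rel in df["path"]:
        if not (root / rel).is_file():
            raise ParseError(f"{path}: listed file not found: {rel}")
    df.attrs["root"] = root
    return df


def load_cohort(manifest_path: str | Path) -> list[ConnectivityMatrix]:
    """Load every matrix listed in a manifest, enforcing one manifest-wide
    ROI label set."""
    manifest = read_manifest(manifest_path)
    root = manifest.attrs["root"]
    cohort: list[ConnectivityMatrix] = []
    labels: tuple[str, ...] | None = None
    for row in manifest.itertuples(index=False):
        mat = read_connectivity(
            root / row.path,
            subject_id=row.subject_id,
            group=row.group,
            band=row.band,
            expected_labels=labels,
        )
        labels = mat.labels
        cohort.append(mat)
    return cohort


@dataclass
class RunConfig:
    """Analysis parameters; the defaults reproduce the reference analysis
    (10,000 permutations, alpha = 0.05, the eight standard bands)."""

    min_coherence: float = 1e-6
    tol_h: float = 1e-8
    tol_rho: float = 1e-10
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    bands: tuple[str, ...] = tuple(DEFAULT_BANDS)
    correction: str | None = None

    def __post_init__(self) -> None:
        self.bands = tuple(self.bands)
        if self.n_perm < 1:
            raise ParseError("n_perm must be a positive integer")
        if not 0 < self.alpha < 1:
            raise ParseError("alpha must lie in (0, 1)")
        if self.min_coherence <= 0:
            raise ParseError("min_coherence must be positive")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        names = {f.name for f in dc_fields(cls)}
        return cls(**{k: v for k, v in mapping.items() if k in names})


#: Keys accepted in a config file (RunConfig keys plus generator keys).
CONFIG_KEYS = {f.name for f in dc_fields(RunConfig)} | {
    "n_group_a",
    "n_group_b",
    "baseline_mean",
    "subject_sd",
    "edge_sd",
    "effects",
    "roi_labels",
}


def load_config_mapping(path: str | Path) -> dict:
    """Load a flat YAML config file, rejecting unknown keys."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ParseError(f"{path}: config must be a flat key-value mapping")
    unknown = sorted(set(mapping) - CONFIG_KEYS)
    if unknown:
        raise ParseError(f"{path}: unknown config keys {unknown}")
    return mapping


def config_hash(mapping: dict) -> str:
    canonical = yaml.safe_dump(mapping, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_run_info(path: str | Path, mapping: dict, seed: int) -> None:
    """Record config hash, seed, tolerances and library versions for
    reproducibility."""
    import scipy

    info = {
        "config": mapping,
        "config_hash": config_hash(mapping),
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(info, fh, sort_keys=True)


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "group", "band", "h_vol"):
        if col not in df.columns:
            raise ParseError(f"{path}: features table lacks column {col!r}")
    return df
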