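"""Readers and writers for the on-disk formats, plus the run configuration.

Time-series matrices are delimited text (comma for .csv, tab for .tsv),
one row per time point, with an optional first header row of ROI labels
(autodetected).  A cohort manifest is a CSV with columns subject_id, path,
label, tr_seconds.  Networks and feature matrices are written as CSV,
reports and ground truth as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import HyperparameterGrid
from .connectivity import MiEstimatorConfig
from .errors import InvalidArgumentError
from .features import FeatureMatrix
from .network import DEFAULT_THRESHOLD_GRID, Fbn, PermutationConfig, RawFbn
from .timeseries import RoiTimeSeries
from .wavelet import WaveletConfig

__all__ = [
    "read_timeseries",
    "read_cohort",
    "write_fbn",
    "write_feature_matrix",
    "write_report",
    "RunConfig",
]

FLOAT_FMT = "%.10g"


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _is_numeric_row(cells: list[str]) -> bool:
    try:
        [float(c) for c in cells]
        return True
    except ValueError:
        return False


def read_timeseries(path: str | Path, tr: float, subject_id: str | None = None) -> RoiTimeSeries:
    """Read one subject's (time x ROI) matrix from delimited text.

    The first row is treated as a header of ROI labels when it does not
    parse as numbers.  Errors name the file, row and column involved.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidArgumentError(f"time-series file not found: {path}")
    delim = _delimiter_for(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise InvalidArgumentError(f"{path}: empty file")
    first = [c.strip() for c in lines[0].split(delim)]
    labels: list[str] = []
    start = 0
    if not _is_numeric_row(first):
        labels = first
        start = 1
    n_cols = len(first)
    rows = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        cells = [c.strip() for c in line.split(delim)]
        if len(cells) != n_cols:
            raise InvalidArgumentError(
                f"{path}: line {lineno} has {len(cells)} columns, expected {n_cols}"
            )
        row = []
        for col, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise InvalidArgumentError(
                    f"{path}: non-numeric value {cell!r} at line {lineno}, column {col}"
                ) from None
        rows.append(row)
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        data=np.asarray(rows),
        tr=tr,
        roi_labels=labels,
    )


def read_cohort(manifest_path: str | Path) -> tuple[list[RoiTimeSeries], np.ndarray]:
    """Read every subject named in a manifest CSV; returns (subjects, labels).

    Validates that all subjects share the ROI count and that labels are
    binary.  Relative paths are resolved against the manifest directory.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise InvalidArgumentError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "path", "label", "tr_seconds"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"{manifest_path}: missing manifest columns {sorted(missing)}")
    subjects = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        subjects.append(read_timeseries(p, tr=float(row["tr_seconds"]), subject_id=str(row["subject_id"])))
    n_rois = {ts.n_rois for ts in subjects}
    if len(n_rois) > 1:
        raise InvalidArgumentError(f"inconsistent ROI counts across subjects: {sorted(n_rois)}")
    labels = df["label"].to_numpy()
    if not set(np.unique(labels)) <= {0, 1}:
        raise InvalidArgumentError(f"labels must be binary 0/1, got {sorted(set(labels))}")
    return subjects, labels.astype(int)


def write_fbn(fbn: Fbn | RawFbn, path: str | Path) -> None:
    """n x n weight matrix as CSV with ROI labels as header row and index."""
    labels = fbn.roi_labels or [f"ROI_{i + 1}" for i in range(fbn.weights.shape[0])]
    pd.DataFrame(fbn.weights, index=labels, columns=labels).to_csv(
        path, float_format=FLOAT_FMT
    )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    pd.DataFrame(fm.values, index=fm.subject_ids, columns=fm.feature_names).assign(
        label=fm.labels
    ).to_csv(path, float_format=FLOAT_FMT, index_label="subject_id")


def write_report(report_dict: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=2) + "\n")


@dataclass
class RunConfig:
    """End-to-end pipeline settings, loadable from a YAML file."""

    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    mi: MiEstimatorConfig = field(default_factory=MiEstimatorConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    threshold_ccc: float = 0.0
    threshold_nmi: float = 0.1
    k_features: int = 25
    grid: HyperparameterGrid = field(default_factory=HyperparameterGrid)
    seed: int = 0
    include_same_band: bool = True

    def __post_init__(self) -> None:
        for t in (*self.thresholds, self.threshold_ccc, self.threshold_nmi):
            if not 0.0 <= t <= 1.0:
                raise InvalidArgumentError(f"threshold {t} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub_cls in (
            ("wavelet", WaveletConfig),
            ("mi", MiEstimatorConfig),
            ("permutation", PermutationConfig),
            ("grid", HyperparameterGrid),
        ):
            if key in raw:
                sub = raw.pop(key)
                for k, v in list(sub.items()):
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = sub_cls(**sub)
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        kwargs.update(raw)
        return cls(**kwargs)
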