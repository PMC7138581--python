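"""Delimited-text readers and writers for every pipeline artifact.

TSV is the default dialect; CSV is accepted and selected by file
extension.  Floats are written with 17 significant digits so every
write/read round trip reproduces values exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, ManifestError, ParseError
from .types import SubjectManifest, TimeSeriesPanel, default_region_labels

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
]

FLOAT_FMT = "%.17g"
GROUP_LABELS = ("patient", "control")
_CLINICAL_COLUMNS = (
    "age", "sex", "education", "duration", "acth", "ufc",
    "cortisol_0am", "cortisol_4pm", "cortisol_8am",
)


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_timeseries(path, tr_seconds: float = 2.0) -> TimeSeriesPanel:
    """Read a regions x time panel; rows are regions, columns time points.

    An optional header row (any non-numeric cell) carries region labels,
    one per data row.  Missing labels are synthesized as R001..RNNN.
    """
    path = Path(path)
    sep = _sep(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if not lines:
        raise DimensionError(f"{path}: empty time-series file")

    rows = [ln.split(sep) for ln in lines]
    labels = None
    start = 0
    if any(not _is_number(tok) for tok in rows[0]):
        labels = [tok.strip() for tok in rows[0]]
        start = 1

    data_rows = rows[start:]
    if not data_rows:
        raise DimensionError(f"{path}: no data rows")
    width = len(data_rows[0])
    values = np.empty((len(data_rows), width), dtype=float)
    for i, row in enumerate(data_rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: row {start + i + 1} has {len(row)} fields, expected {width}"
            )
        for j, tok in enumerate(row):
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {tok!r} at row {start + i + 1}, "
                    f"column {j + 1}"
                ) from None
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise DimensionError(
            f"{path}: need at least 2 regions and 2 time points, "
            f"got {values.shape[0]} x {values.shape[1]}"
        )
    if not np.all(np.isfinite(values)):
        raise ParseError(f"{path}: non-finite values in time series")
    if labels is None:
        labels = default_region_labels(values.shape[0])
    elif len(labels) != values.shape[0]:
        raise FormatError(
            f"{path}: header carries {len(labels)} labels for "
            f"{values.shape[0]} regions"
        )
    return TimeSeriesPanel(
        subject_id=path.stem, region_labels=labels, values=values,
        tr_seconds=tr_seconds,
    )


def write_timeseries(panel: TimeSeriesPanel, path) -> None:
    path = Path(path)
    sep = _sep(path)
    with path.open("w") as fh:
        fh.write(sep.join(panel.region_labels) + "\n")
        for row in panel.values:
            fh.write(sep.join(FLOAT_FMT % v for v in row) + "\n")


def read_manifest(path) -> list[SubjectManifest]:
    """Read the subject manifest; requires subject_id and group columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype={"subject_id": str, "sex": str},
                     float_precision="round_trip")
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ManifestError(f"{path}: manifest missing required column {col!r}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ManifestError(f"{path}: duplicate subject_id values: {sorted(set(dupes))}")

    records = []
    for _, row in df.iterrows():
        group = str(row["group"]).strip().lower()
        if group not in GROUP_LABELS:
            raise ManifestError(
                f"{path}: unknown group {row['group']!r} for subject "
                f"{row['subject_id']}; admissible labels: {list(GROUP_LABELS)}"
            )
        kwargs = {}
        for col in _CLINICAL_COLUMNS:
            if col in df.columns:
                val = row[col]
                if pd.isna(val):
                    kwargs[col] = None
                elif col == "sex":
                    kwargs[col] = str(val)
                else:
                    kwargs[col] = float(val)
        records.append(SubjectManifest(
            subject_id=str(row["subject_id"]), group=group, **kwargs,
        ))
    return records


def manifest_to_frame(records: list[SubjectManifest]) -> pd.DataFrame:
    cols = ["subject_id", "group", *_CLINICAL_COLUMNS]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def write_manifest(records, path) -> None:
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = manifest_to_frame(records)
    df.to_csv(path, sep=_sep(path), index=False, float_format=FLOAT_FMT)


def write_matrix(labels, matrix, path) -> None:
    """Write a square labelled matrix (header row + label column)."""
    path = Path(path)
    sep = _sep(path)
    matrix = np.asarray(matrix)
    with path.open("w") as fh:
        fh.write("region" + sep + sep.join(labels) + "\n")
        for label, row in zip(labels, matrix):
            fh.write(label + sep + sep.join(FLOAT_FMT % v for v in row) + "\n")


def read_matrix(path) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0, float_precision="round_trip")
    labels = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != labels:
        raise FormatError(f"{path}: matrix row labels do not match column labels")
    return labels, df.to_numpy(dtype=float)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep(path), index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
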