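"""Reading and writing expression matrices, label files and report tables.

File conventions
----------------
Matrix files are tab- or comma-delimited text: first column = feature id,
header row = sample ids.  Label files are two-column delimited text mapping
sample id -> class label (a header row ``sample<TAB>label`` is accepted and
skipped).  Report tables are TSV with one ``statistic<TAB>value`` row per
summary field.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .dataset import DatasetError, ExpressionDataset

if TYPE_CHECKING:  # pragma: no cover
    from .multiplicity_screen import ScreenReport
    from .triplet_screen import TripletScreenReport

log = logging.getLogger(__name__)


def _detect_sep(path: Path) -> str:
    """Tab-preferred delimiter sniffing on the header line."""
    header = Path(path).open().readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def read_dataset(
    matrix_path: str | Path,
    labels_path: str | Path,
    positive_class: str | None = None,
    sep: str | None = None,
    transpose: bool = False,
) -> ExpressionDataset:
    """Load a delimited matrix + label file into an :class:`ExpressionDataset`.

    When ``positive_class`` is omitted the minority class is chosen (ties
    broken by the lexicographically smaller label) and the choice is logged.
    ``transpose=True`` accepts samples x features source tables.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    if sep is None:
        sep = _detect_sep(matrix_path)
    df = pd.read_csv(matrix_path, sep=sep, index_col=0,
                     float_precision="round_trip")
    if transpose:
        df = df.T

    feature_ids = [str(f) for f in df.index]
    sample_ids = [str(s) for s in df.columns]

    dup = _first_dup(feature_ids)
    if dup is not None:
        raise DatasetError(f"duplicate feature id {dup!r} in {matrix_path}")
    dup = _first_dup(sample_ids)
    if dup is not None:
        raise DatasetError(f"duplicate sample id {dup!r} in {matrix_path}")

    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                row = df.index[bad.isna().to_numpy().argmax()]
                raise DatasetError(
                    f"non-numeric cell at feature {row!r}, sample {col!r}"
                )
        values = df.astype(float).to_numpy()
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise DatasetError(
            f"missing value at feature {feature_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )

    label_map = read_labels(labels_path)
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise DatasetError(f"samples missing from label file: {missing}")
    labels = [label_map[s] for s in sample_ids]

    classes = sorted(set(labels))
    if len(classes) > 2:
        raise DatasetError(f"more than two classes in label file: {classes}")
    if len(classes) < 2:
        raise DatasetError(f"only one class in label file: {classes}")

    if positive_class is None:
        counts = {c: labels.count(c) for c in classes}
        positive_class = min(classes, key=lambda c: (counts[c], c))
        log.info(
            "positive_class not given; chose minority class %r (counts %s)",
            positive_class,
            counts,
        )

    return ExpressionDataset(feature_ids, sample_ids, values, labels, positive_class)


def read_labels(labels_path: str | Path) -> dict[str, str]:
    """Parse a two-column sample -> label file (tab or comma delimited)."""
    labels_path = Path(labels_path)
    sep = _detect_sep(labels_path)
    mapping: dict[str, str] = {}
    with labels_path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise DatasetError(
                    f"{labels_path}:{lineno}: expected two columns, got {line!r}"
                )
            sid, lab = parts[0].strip(), parts[1].strip()
            if lineno == 1 and sid.lower() in {"sample", "sample_id", "id"}:
                continue
            if sid in mapping:
                raise DatasetError(f"duplicate sample id {sid!r} in label file")
            mapping[sid] = lab
    return mapping


def write_dataset(
    ds: ExpressionDataset, matrix_path: str | Path, labels_path: str | Path
) -> None:
    """Write matrix and labels as TSV, round-trippable through read_dataset."""
    df = pd.DataFrame(ds.values, index=ds.feature_ids, columns=ds.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.17g")
    with Path(labels_path).open("w") as fh:
        fh.write("sample\tlabel\n")
        for sid, lab in zip(ds.sample_ids, ds.labels):
            fh.write(f"{sid}\t{lab}\n")


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def write_report_table(report, path: str | Path) -> Path:
    """Serialize a screen report summary as a statistic/value TSV.

    Accepts any report exposing ``summary_rows() -> list[(name, value)]``.
    Empty census fields are written as empty strings.
    """
    path = Path(path)
    rows = report.summary_rows()
    with path.open("w") as fh:
        fh.write("statistic\tvalue\n")
        for name, value in rows:
            fh.write(f"{name}\t{_fmt(value)}\n")
    return path


def read_report_table(path: str | Path) -> dict[str, str]:
    """Read back a statistic/value TSV as a string-valued dict."""
    out: dict[str, str] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("statistic"):
            raise DatasetError(f"{path}: not a report table")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, _, value = line.partition("\t")
            out[name] = value
    return out


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.17g}"
    return str(value)


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _first_dup(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
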