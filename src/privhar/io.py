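"""CSV readers and writers.

Two per-sequence dialects are supported:

* ``plain`` — headerless rows of ``x,y,z`` acceleration in g;
* ``e4`` — the Empatica E4 ACC export: first row is the start timestamp
  (repeated across the three columns), second row the sample rate, and the
  remaining rows x,y,z in raw counts of 1/64 g.

Datasets are a directory of per-sequence CSVs plus a ``manifest.csv`` with
columns ``file, subject_id, gender, age_group, activity``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .types import LABEL_COLUMNS, RawSequence

E4_COUNTS_PER_G = 64.0
_E4_DEFAULT_T0 = 1600000000.0

MANIFEST_COLUMNS = ("file", "subject_id", "gender", "age_group", "activity")


def write_sequence_csv(
    sequence: RawSequence,
    path: str | Path,
    dialect: str = "e4",
    start_timestamp: float = _E4_DEFAULT_T0,
) -> None:
    path = Path(path)
    if dialect == "plain":
        np.savetxt(path, sequence.samples, delimiter=",", fmt="%.6f")
    elif dialect == "e4":
        counts = np.round(sequence.samples * E4_COUNTS_PER_G).astype(int)
        with open(path, "w") as fh:
            fh.write(f"{start_timestamp:.6f},{start_timestamp:.6f},{start_timestamp:.6f}\n")
            rate = sequence.sample_rate_hz
            fh.write(f"{rate:.6f},{rate:.6f},{rate:.6f}\n")
            np.savetxt(fh, counts, delimiter=",", fmt="%d")
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'plain' or 'e4')")


def _looks_like_e4(raw: np.ndarray) -> bool:
    if len(raw) < 3:
        return False
    row0, row1 = raw[0], raw[1]
    return (
        np.all(row0 == row0[0])
        and np.all(row1 == row1[0])
        and row0[0] > 1e6  # unix timestamp
        and 0 < row1[0] <= 1e4  # plausible sample rate
    )


def read_sequence_csv(
    path: str | Path,
    dialect: str = "auto",
    sample_rate_hz: float | None = None,
    subject_id: str = "",
    gender: str = "M",
    age_group: int = 0,
    activity: str = "",
    sequence_id: str = "",
) -> RawSequence:
    """Read one per-sequence CSV; the dialect is auto-detected by row shape
    unless forced via ``dialect``."""
    path = Path(path)
    raw = np.loadtxt(path, delimiter=",", ndmin=2)
    if raw.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns, got {raw.shape[1]}")
    if dialect == "auto":
        dialect = "e4" if _looks_like_e4(raw) else "plain"
    if dialect == "e4":
        rate = float(raw[1, 0])
        samples = raw[2:] / E4_COUNTS_PER_G
    elif dialect == "plain":
        if sample_rate_hz is None:
            raise ValueError("plain dialect requires an explicit sample_rate_hz")
        rate = float(sample_rate_hz)
        samples = raw
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return RawSequence(
        subject_id=subject_id,
        gender=gender,
        age_group=age_group,
        activity=activity,
        samples=samples,
        sample_rate_hz=rate,
        sequence_id=sequence_id or path.stem,
    )


def write_dataset(
    sequences: list[RawSequence], outdir: str | Path, dialect: str = "e4"
) -> Path:
    """Write one CSV per sequence plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for seq in sequences:
        fname = f"{seq.sequence_id}.csv"
        write_sequence_csv(seq, outdir / fname, dialect=dialect)
        rows.append(
            {
                "file": fname,
                "subject_id": seq.subject_id,
                "gender": seq.gender,
                "age_group": seq.age_group,
                "activity": seq.activity,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def read_dataset(
    manifest_path: str | Path,
    dialect: str = "auto",
    sample_rate_hz: float | None = None,
) -> list[RawSequence]:
    """Load a dataset directory back from its manifest."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    sequences = []
    for row in manifest.itertuples(index=False):
        sequences.append(
            read_sequence_csv(
                root / row.file,
                dialect=dialect,
                sample_rate_hz=sample_rate_hz,
                subject_id=str(row.subject_id),
                gender=str(row.gender),
                age_group=int(row.age_group),
                activity=str(row.activity),
                sequence_id=Path(str(row.file)).stem,
            )
        )
    return sequences


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix (62 canonical feature columns + labels) to CSV."""
    _check_feature_matrix(matrix)
    matrix.to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path)
    _check_feature_matrix(matrix)
    return matrix


def _check_feature_matrix(matrix: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_NAMES if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix missing feature columns: {missing[:5]}...")
    missing_labels = [c for c in LABEL_COLUMNS if c not in matrix.columns]
    if missing_labels:
        raise ValueError(f"feature matrix missing label columns: {missing_labels}")
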