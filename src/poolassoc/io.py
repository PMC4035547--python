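"""Readers and writers for the tab-separated dataset and result formats."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .association import AssociationResult
from .simulate import DATASET_COLUMNS

__all__ = ["read_dataset", "write_result", "DatasetFormatError"]

_OPTIONAL_COLUMNS = ["s1_B", "s2_B"]


class DatasetFormatError(ValueError):
    """Malformed dataset file (bad header or invalid row)."""


def read_dataset(path) -> pd.DataFrame:
    """Read the per-family TSV dataset written by ``write_dataset``.

    One row per family with columns family_id, s1, s2, depth, phenotype
    (plus s1_B/s2_B in two-locus files).  Zero-depth rows are retained —
    the association step drops them and reports the count.  Malformed
    headers and invalid rows raise :class:`DatasetFormatError` naming the
    offending line (1-based, counting the header as line 1).
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t", dtype={"family_id": str}, float_precision="round_trip"
    )
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(
            f"{path}: header is missing required columns {missing}"
        )
    count_cols = ["s1", "s2", "depth"] + [
        c for c in _OPTIONAL_COLUMNS if c in frame.columns
    ]
    for col in count_cols:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() | (values < 0) | (values != values.round())
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise DatasetFormatError(
                f"{path}: line {line}: column {col!r} must be a "
                f"nonnegative integer, got {frame[col].iloc[bad.idxmax()]!r}"
            )
        frame[col] = values.astype(int)
    mismatch = frame["s1"] + frame["s2"] != frame["depth"]
    if mismatch.any():
        line = int(mismatch.idxmax()) + 2
        raise DatasetFormatError(
            f"{path}: line {line}: depth must equal s1 + s2"
        )
    return frame


def write_result(result: AssociationResult, path) -> None:
    """Write an association result as a one-row TSV plus a JSON sidecar.

    The TSV carries 6 significant digits for human reading; the ``.json``
    file next to it keeps full precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    record = result.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(record) + "\n")
        fh.write(
            "\t".join(
                _format_cell(v) for v in record.values()
            )
            + "\n"
        )
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2)
        fh.write("\n")


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)
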