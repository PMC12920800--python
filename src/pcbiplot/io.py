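"""Readers, writers and the machine-readable report document.

Matrices travel as CSV/TSV with a header row of feature names and a first
column of observation labels; numbers are written with 17 significant digits
so a write-then-read round-trip is bit-identical.  Reports are JSON with
status strings as the single source of truth (the display symbols of the
verdict vocabulary are never serialised as glyphs) and are validated against
a small structural schema before writing.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InputError, LabeledMatrix

__all__ = ["ReportDocument", "read_matrix", "write_matrix", "write_report"]

TOOL_VERSION = "0.1.0"


def read_matrix(path, delimiter: str | None = None) -> LabeledMatrix:
    """Read a labeled matrix from CSV/TSV.

    The delimiter is auto-detected (comma, tab or semicolon) unless forced.
    Non-numeric cells and duplicate labels raise :class:`InputError` with
    row/column context.
    """
    path = Path(path)
    if delimiter is None:
        with open(path, "r", encoding="utf-8") as fh:
            head = fh.readline()
        for cand in ("\t", ";", ","):
            if cand in head:
                delimiter = cand
                break
        else:
            delimiter = ","
    try:
        df = pd.read_csv(
            path, sep=delimiter, index_col=0, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate row labels: {dupes}")
    if df.columns.has_duplicates:
        raise InputError("duplicate column labels")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].isna()
        bad |= df[col].isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise InputError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    return LabeledMatrix(
        values=values,
        row_labels=tuple(str(i) for i in df.index),
        col_labels=tuple(str(c) for c in df.columns),
    )


def write_matrix(X: LabeledMatrix, path, delimiter: str = ",") -> None:
    """Write a labeled matrix with 17 significant digits (lossless round-trip)."""
    df = pd.DataFrame(
        X.values, index=list(X.row_labels), columns=list(X.col_labels)
    )
    df.to_csv(path, sep=delimiter, float_format="%.17g")


@dataclass(frozen=True)
class ReportDocument:
    """Envelope for any serialisable payload (grid report, audit, PCA summary)."""

    kind: str                  # "grid" | "audit" | "pca"
    fingerprint: dict
    settings: dict
    payload: object
    tool_version: str = TOOL_VERSION
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )

    def to_dict(self) -> dict:
        return {
            "tool_version": self.tool_version,
            "kind": self.kind,
            "timestamp": self.timestamp,
            "fingerprint": self.fingerprint,
            "settings": self.settings,
            "payload": self.payload,
        }


_REQUIRED_KEYS = {
    "tool_version": str,
    "kind": str,
    "timestamp": str,
    "fingerprint": dict,
    "settings": dict,
}


def validate_report(doc: dict) -> None:
    """Structural schema check: required keys, types, verdict vocabulary."""
    for key, typ in _REQUIRED_KEYS.items():
        if key not in doc:
            raise InputError(f"report missing key {key!r}")
        if not isinstance(doc[key], typ):
            raise InputError(f"report key {key!r} must be {typ.__name__}")
    if "payload" not in doc:
        raise InputError("report missing payload")
    payload = doc["payload"]
    if isinstance(payload, dict) and "outcomes" in payload:
        for item in payload["outcomes"]:
            if item.get("status") not in ("exact", "sign_flip", "fail", "skipped"):
                raise InputError(f"invalid outcome status: {item.get('status')!r}")
    if isinstance(payload, list):
        for item in payload:
            if isinstance(item, dict) and "symbol" in item:
                if item["symbol"] not in ("match", "abs_match", "mismatch"):
                    raise InputError(f"invalid audit symbol: {item['symbol']!r}")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_report(doc: ReportDocument, path) -> None:
    """Validate and write a report document as JSON."""
    data = doc.to_dict()
    validate_report(data)
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=2, cls=_NumpyEncoder)
            fh.write("\n")
    except OSError as exc:
        raise InputError(f"cannot write report to {path}: {exc}") from exc
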