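"""Selection data model, Raven-style selection-table I/O and label binarization.

The tab-delimited selection table is the interchange format between the
detector, manual annotation and the classifier. Tables are written with a
fixed dialect (decimal point, UTF-8, trailing newline, times to 4 decimals,
frequencies to 1) so that write -> read round-trips are lossless at those
precisions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import LabelError, SchemaError, TableParseError

__all__ = [
    "Selection",
    "AnnotatedSelection",
    "read_selection_table",
    "write_selection_table",
    "binarize_labels",
    "PRESENCE",
    "ABSENCE",
]

PRESENCE = "presence"
ABSENCE = "absence"

VALID_CLASSES = frozenset({0, 1, 2, 3})

_REQUIRED_COLUMNS = (
    "Selection",
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
)

_HEADER = (
    "Selection\tView\tChannel\tBegin Time (s)\tEnd Time (s)"
    "\tLow Freq (Hz)\tHigh Freq (Hz)"
)


@dataclass(frozen=True)
class Selection:
    """A rectangular time x frequency box marking one candidate song."""

    selection_id: int
    source_id: str
    begin_time: float
    end_time: float
    low_freq: float
    high_freq: float
    channel: int = 1

    def __post_init__(self) -> None:
        if self.selection_id <= 0:
            raise ValueError(f"selection_id must be positive, got {self.selection_id}")
        if not self.begin_time < self.end_time:
            raise ValueError(
                f"begin_time ({self.begin_time}) must precede end_time ({self.end_time})"
            )
        if not self.low_freq < self.high_freq:
            raise ValueError(
                f"low_freq ({self.low_freq}) must be below high_freq ({self.high_freq})"
            )

    @property
    def duration(self) -> float:
        return self.end_time - self.begin_time

    def overlap_seconds(self, other: "Selection") -> float:
        """Temporal intersection with another selection, in seconds."""
        return max(
            0.0,
            min(self.end_time, other.end_time) - max(self.begin_time, other.begin_time),
        )


@dataclass(frozen=True)
class AnnotatedSelection:
    """A selection carrying a manual (or inherited) class label 0-3.

    Class 0 means "not the target species"; classes 1-3 are target songs of
    increasing selection quality. The derived binary label is absence for
    class 0 and presence otherwise.
    """

    selection: Selection
    class_label: int

    def __post_init__(self) -> None:
        if self.class_label not in VALID_CLASSES:
            raise LabelError(
                f"class label must be in {sorted(VALID_CLASSES)}, got {self.class_label}"
            )

    @property
    def binary_label(self) -> str:
        return ABSENCE if self.class_label == 0 else PRESENCE


def _coerce_numeric(frame: pd.DataFrame, column: str, path: str) -> pd.Series:
    values = pd.to_numeric(frame[column], errors="coerce")
    bad = values.isna() & frame[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
        raise TableParseError(
            f"{path}: non-numeric value {frame[column][bad].iloc[0]!r} "
            f"in column {column!r} at line {row}"
        )
    if values.isna().any():
        row = int(np.flatnonzero(values.isna().to_numpy())[0]) + 2
        raise TableParseError(f"{path}: empty cell in column {column!r} at line {row}")
    return values


def read_selection_table(
    path: str | os.PathLike, source_id: str | None = None
) -> list[Selection] | list[AnnotatedSelection]:
    """Parse a tab-delimited selection table.

    Returns :class:`AnnotatedSelection` records when a "Class" column is
    present, plain :class:`Selection` records otherwise. ``source_id``
    defaults to the file's basename without extension.
    """
    path = os.fspath(path)
    if source_id is None:
        source_id = os.path.splitext(os.path.basename(path))[0]
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    cols = {c: _coerce_numeric(frame, c, path) for c in _REQUIRED_COLUMNS}
    if "Channel" in frame.columns:
        channel = _coerce_numeric(frame, "Channel", path).astype(int)
    else:
        channel = pd.Series(1, index=frame.index)
    annotated = "Class" in frame.columns
    if annotated:
        classes = _coerce_numeric(frame, "Class", path).astype(int)
    records: list = []
    for i in frame.index:
        sel = Selection(
            selection_id=int(cols["Selection"][i]),
            source_id=source_id,
            begin_time=float(cols["Begin Time (s)"][i]),
            end_time=float(cols["End Time (s)"][i]),
            low_freq=float(cols["Low Freq (Hz)"][i]),
            high_freq=float(cols["High Freq (Hz)"][i]),
            channel=int(channel[i]),
        )
        records.append(
            AnnotatedSelection(selection=sel, class_label=int(classes[i]))
            if annotated
            else sel
        )
    return records


def write_selection_table(
    records: list[Selection] | list[AnnotatedSelection], path: str | os.PathLike
) -> None:
    """Write records as a Raven-compatible tab-delimited selection table.

    All records must be of the same kind; annotated records add a "Class"
    column. An empty list yields a header-only (unannotated) file.
    """
    annotated_flags = {isinstance(r, AnnotatedSelection) for r in records}
    if len(annotated_flags) > 1:
        raise SchemaError("cannot mix annotated and plain selections in one table")
    annotated = annotated_flags == {True}
    header = _HEADER + ("\tClass" if annotated else "")
    lines = [header]
    for record in records:
        sel = record.selection if annotated else record
        row = (
            f"{sel.selection_id}\tSpectrogram 1\t{sel.channel}"
            f"\t{sel.begin_time:.4f}\t{sel.end_time:.4f}"
            f"\t{sel.low_freq:.1f}\t{sel.high_freq:.1f}"
        )
        if annotated:
            row += f"\t{record.class_label}"
        lines.append(row)
    with open(os.fspath(path), "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\n".join(lines) + "\n")


def binarize_labels(
    records: list[AnnotatedSelection],
) -> tuple[int, int, np.ndarray]:
    """Map 4-class annotations to binary presence/absence.

    Returns ``(n_presence, n_absence, binary)`` where ``binary`` is an int
    array with 1 for presence (classes 1-3) and 0 for absence (class 0).
    """
    labels = []
    for record in records:
        label = record.class_label if isinstance(record, AnnotatedSelection) else record
        if label not in VALID_CLASSES:
            raise LabelError(f"class label must be in {sorted(VALID_CLASSES)}, got {label}")
        labels.append(0 if label == 0 else 1)
    binary = np.asarray(labels, dtype=int)
    n_presence = int(binary.sum())
    return n_presence, len(binary) - n_presence, binary


def with_class(sel: Selection, class_label: int) -> AnnotatedSelection:
    """Attach a class label to a selection."""
    return AnnotatedSelection(selection=sel, class_label=class_label)


def renumber(records: list[Selection]) -> list[Selection]:
    """Reassign selection ids 1..n in list order."""
    return [replace(sel, selection_id=i + 1) for i, sel in enumerate(records)]
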