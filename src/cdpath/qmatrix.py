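"""Q-matrix and response-matrix containers, CSV I/O, validation, pruning.

A Q-matrix is the J x K binary incidence matrix linking test items (rows)
to the latent cognitive attributes they require (columns).  It is the
bridge between observable item responses and the unobservable mastery
profile of an examinee, so every downstream step validates against it.

File format: comma-separated, one header row of attribute labels, one row
per item.  An optional first column may carry item labels; when absent,
labels ``Item1..ItemJ`` are generated.  Response matrices use the same
layout with item labels in the header and one row per examinee.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("cdpath")

__all__ = [
    "QMatrix",
    "ResponseMatrix",
    "QMatrixError",
    "read_qmatrix",
    "write_qmatrix",
    "read_responses",
    "write_responses",
    "attribute_item_counts",
    "prune_attributes",
]


class QMatrixError(ValueError):
    """Raised when a Q-matrix or response matrix violates its contract."""


def _check_binary(arr: np.ndarray, what: str, row_labels, col_labels) -> np.ndarray:
    arr = np.asarray(arr)
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise QMatrixError(
            f"{what} has non-binary entry {arr[i, j]!r} at "
            f"row {row_labels[i]!r}, column {col_labels[j]!r}"
        )
    return arr.astype(np.int8)


@dataclass(frozen=True)
class QMatrix:
    """Binary item-by-attribute incidence matrix.

    Invariants (enforced on construction): entries in {0,1}; no all-zero
    item row (an item must measure at least one attribute); unique labels.
    """

    entries: np.ndarray
    item_labels: tuple[str, ...]
    attribute_labels: tuple[str, ...]

    def __post_init__(self):
        entries = np.atleast_2d(np.asarray(self.entries))
        if entries.ndim != 2 or entries.size == 0:
            raise QMatrixError("Q-matrix must be a non-empty 2-D array")
        object.__setattr__(self, "item_labels", tuple(str(x) for x in self.item_labels))
        object.__setattr__(
            self, "attribute_labels", tuple(str(x) for x in self.attribute_labels)
        )
        if len(self.item_labels) != entries.shape[0]:
            raise QMatrixError("item label count does not match row count")
        if len(self.attribute_labels) != entries.shape[1]:
            raise QMatrixError("attribute label count does not match column count")
        if len(set(self.item_labels)) != len(self.item_labels):
            raise QMatrixError("item labels are not unique")
        if len(set(self.attribute_labels)) != len(self.attribute_labels):
            raise QMatrixError("attribute labels are not unique")
        entries = _check_binary(
            entries, "Q-matrix", self.item_labels, self.attribute_labels
        )
        zero_rows = np.flatnonzero(entries.sum(axis=1) == 0)
        if zero_rows.size:
            raise QMatrixError(
                f"item {self.item_labels[zero_rows[0]]!r} measures no attribute "
                "(all-zero Q-matrix row)"
            )
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    def required_attributes(self, item: int) -> np.ndarray:
        """0-based indices of the attributes item ``item`` loads on."""
        return np.flatnonzero(self.entries[item])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            index=pd.Index(self.item_labels, name="item"),
            columns=list(self.attribute_labels),
        )


@dataclass(frozen=True)
class ResponseMatrix:
    """N x J matrix of dichotomous item scores (1 correct, 0 incorrect)."""

    entries: np.ndarray
    examinee_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        entries = np.atleast_2d(np.asarray(self.entries))
        ids = self.examinee_ids or tuple(f"S{i + 1}" for i in range(entries.shape[0]))
        object.__setattr__(self, "examinee_ids", tuple(str(x) for x in ids))
        if len(self.examinee_ids) != entries.shape[0]:
            raise QMatrixError("examinee id count does not match row count")
        cols = [f"item{j + 1}" for j in range(entries.shape[1])]
        entries = _check_binary(entries, "response matrix", self.examinee_ids, cols)
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)

    @property
    def n_examinees(self) -> int:
        return self.entries.shape[0]

    @property
    def n_items(self) -> int:
        return self.entries.shape[1]

    def raw_scores(self) -> np.ndarray:
        return self.entries.sum(axis=1)


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise QMatrixError(f"{path}: empty table")
    first = df.iloc[:, 0]
    # first column is a label column when any value is not a 0/1 token
    if not first.isin(["0", "1"]).all():
        df = df.set_index(df.columns[0])
    else:
        df.index = pd.Index(
            [f"Item{i + 1}" for i in range(len(df))], name="item"
        )
    return df


def _coerce_binary_frame(df: pd.DataFrame, path) -> np.ndarray:
    values = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            tok = str(raw).strip()
            if tok not in ("0", "1"):
                raise QMatrixError(
                    f"{path}: non-binary cell {raw!r} at row {df.index[i]!r}, "
                    f"column {col!r}"
                )
            values[i, j] = int(tok)
    return values


def read_qmatrix(path) -> QMatrix:
    """Read a Q-matrix from CSV (header = attribute labels)."""
    df = _read_table(path)
    values = _coerce_binary_frame(df, path)
    return QMatrix(values, tuple(df.index), tuple(df.columns))


def write_qmatrix(q: QMatrix, path) -> None:
    q.to_frame().to_csv(Path(path))


def read_responses(path) -> ResponseMatrix:
    """Read a response matrix from CSV (header = item labels)."""
    df = _read_table(path)
    values = _coerce_binary_frame(df, path)
    return ResponseMatrix(values, tuple(df.index))


def write_responses(data: ResponseMatrix, path, item_labels=None) -> None:
    cols = list(item_labels) if item_labels is not None else [
        f"Item{j + 1}" for j in range(data.n_items)
    ]
    pd.DataFrame(
        data.entries, index=pd.Index(data.examinee_ids, name="examinee"), columns=cols
    ).to_csv(Path(path))


def attribute_item_counts(q: QMatrix) -> np.ndarray:
    """Number of items measuring each attribute (Q-matrix column sums)."""
    return q.entries.sum(axis=0).astype(int)


def prune_attributes(q: QMatrix, min_items: int = 3) -> tuple[QMatrix, tuple[str, ...]]:
    """Drop attributes measured by fewer than ``min_items`` items.

    Attributes measured too rarely cannot be diagnosed reliably; the
    conventional floor is three items per attribute.  Pruning never removes
    items: if dropping a column would leave an item with no attributes the
    call fails, because silently changing J would desynchronise any paired
    response file.
    """
    if min_items < 1:
        raise QMatrixError("min_items must be >= 1")
    counts = attribute_item_counts(q)
    keep = counts >= min_items
    removed = tuple(
        lab for lab, k in zip(q.attribute_labels, keep) if not k
    )
    if not keep.any():
        raise QMatrixError(
            f"pruning at min_items={min_items} removes every attribute"
        )
    if not removed:
        return q, ()
    sub = q.entries[:, keep]
    zero_rows = np.flatnonzero(sub.sum(axis=1) == 0)
    if zero_rows.size:
        raise QMatrixError(
            f"pruning at min_items={min_items} leaves item "
            f"{q.item_labels[zero_rows[0]]!r} with no attributes"
        )
    logger.info("pruned attributes %s (min_items=%d)", removed, min_items)
    kept_labels = tuple(
        lab for lab, k in zip(q.attribute_labels, keep) if k
    )
    return QMatrix(sub, q.item_labels, kept_labels), removed
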