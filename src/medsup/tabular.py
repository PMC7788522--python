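"""Tabular containers and I/O for labelled numeric datasets.

Layout convention: instances are rows, numeric attributes are columns, and
for a training file the class label of each instance sits in the last
column. Files are delimited text (CSV or TSV) with a header row.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TabularError",
    "LabeledTable",
    "UnlabeledTable",
    "read_labeled_table",
    "read_test_table",
    "write_labeled_table",
    "write_predictions",
]

#: significant digits used when writing float values; read(write(t)) == t
#: holds up to this precision.
FLOAT_FORMAT = "%.10g"


class TabularError(ValueError):
    """A table or file violates the tabular layout contract."""


def _as_label_array(labels) -> np.ndarray:
    return np.asarray([str(x) for x in np.asarray(labels).ravel()], dtype=object)


@dataclass
class LabeledTable:
    """Instances x numeric attributes with one class label per instance.

    Parameters
    ----------
    attribute_names
        Column identifiers, one per attribute; must be unique.
    values
        Real-valued matrix, shape ``(n_instances, n_attributes)``. No
        missing entries are permitted.
    labels
        Class label per row (coerced to str).
    class_levels
        Ordered distinct labels. If omitted, the distinct labels sorted
        lexicographically (mirroring R factor level ordering).
    label_name
        Name of the label column, used when writing and when detecting a
        trailing label column in test files.
    """

    attribute_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    class_levels: tuple[str, ...] = ()
    label_name: str = "class"

    def __post_init__(self) -> None:
        self.attribute_names = [str(a) for a in self.attribute_names]
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = _as_label_array(self.labels)
        if self.values.ndim != 2:
            raise TabularError("values must be a 2-D matrix")
        if len(self.attribute_names) != self.values.shape[1]:
            raise TabularError(
                f"{len(self.attribute_names)} attribute names for "
                f"{self.values.shape[1]} value columns"
            )
        if len(set(self.attribute_names)) != len(self.attribute_names):
            dupes = sorted(
                {a for a in self.attribute_names if self.attribute_names.count(a) > 1}
            )
            raise TabularError(f"duplicate attribute names: {dupes}")
        if self.labels.shape[0] != self.values.shape[0]:
            raise TabularError(
                f"{self.labels.shape[0]} labels for {self.values.shape[0]} rows"
            )
        if not np.isfinite(self.values).all():
            raise TabularError("values contain missing or non-finite entries")
        if not self.class_levels:
            self.class_levels = tuple(sorted(set(self.labels)))
        else:
            self.class_levels = tuple(str(c) for c in self.class_levels)
            unknown = set(self.labels) - set(self.class_levels)
            if unknown:
                raise TabularError(f"labels outside class_levels: {sorted(unknown)}")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[str, int]:
        """Instance count per class level, in level order."""
        return {c: int(np.sum(self.labels == c)) for c in self.class_levels}

    def require_binary(self) -> None:
        """Raise unless the table carries exactly two non-empty classes."""
        counts = self.class_counts()
        nonempty = [c for c, n in counts.items() if n > 0]
        if len(nonempty) != 2 or len(self.class_levels) != 2:
            raise TabularError(
                "binary classification requires exactly 2 non-empty classes, "
                f"got counts {counts}"
            )

    def unlabeled(self) -> "UnlabeledTable":
        """Drop the labels, keeping values and attribute names."""
        return UnlabeledTable(list(self.attribute_names), self.values.copy())


@dataclass
class UnlabeledTable:
    """Instances x numeric attributes without class labels (a test set)."""

    attribute_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.attribute_names = [str(a) for a in self.attribute_names]
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.attribute_names) != self.values.shape[1]:
            raise TabularError(
                f"{len(self.attribute_names)} attribute names for "
                f"{self.values.shape[1]} value columns"
            )
        if not np.isfinite(self.values).all():
            raise TabularError("values contain missing or non-finite entries")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]


def _detect_delimiter(path: str) -> str:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
    except FileNotFoundError:
        raise TabularError(f"no such file: {path}") from None
    return "\t" if "\t" in first else ","


def _read_frame(path: str, delimiter: str | None) -> pd.DataFrame:
    sep = delimiter if delimiter is not None else _detect_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    except FileNotFoundError:
        raise TabularError(f"no such file: {path}") from None
    except pd.errors.EmptyDataError:
        raise TabularError(f"empty file: {path}") from None
    if df.shape[0] < 1:
        raise TabularError(f"{path}: no data rows below the header")
    return df


def _numeric_block(df: pd.DataFrame, path: str) -> np.ndarray:
    cols = []
    for name in df.columns:
        col = pd.to_numeric(df[name], errors="coerce")
        bad = col.isna() & ~df[name].isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise TabularError(
                f"{path}: non-numeric value {df[name].iloc[row]!r} in "
                f"attribute column {name!r} (data row {row + 1})"
            )
        if col.isna().any():
            raise TabularError(f"{path}: missing value in column {name!r}")
        cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def read_labeled_table(path: str, delimiter: str | None = None) -> LabeledTable:
    """Read a training table whose last column holds the class labels.

    The delimiter is auto-detected between comma and tab unless given
    explicitly. All columns but the last must parse as real numbers.
    """
    df = _read_frame(path, delimiter)
    if df.shape[1] < 2:
        raise TabularError(
            f"{path}: a labelled table needs at least one attribute column "
            "plus the label column"
        )
    label_name = str(df.columns[-1])
    labels = df.iloc[:, -1]
    if labels.isna().any():
        raise TabularError(f"{path}: missing value in label column {label_name!r}")
    values = _numeric_block(df.iloc[:, :-1], path)
    return LabeledTable(
        attribute_names=[str(c) for c in df.columns[:-1]],
        values=values,
        labels=labels.to_numpy(),
        label_name=label_name,
    )


def read_test_table(
    path: str,
    reference: LabeledTable,
    delimiter: str | None = None,
) -> tuple[UnlabeledTable, np.ndarray | None]:
    """Read a test table, detaching a trailing label column if present.

    The header must match ``reference.attribute_names``, optionally followed
    by one label column. The trailing column is treated as labels when its
    name equals the reference label column name or when every entry is a
    known class level of the reference; detached truth labels are returned
    for optional scoring, else ``None``.
    """
    df = _read_frame(path, delimiter)
    cols = [str(c) for c in df.columns]
    ref = reference.attribute_names
    truth: np.ndarray | None = None

    if len(cols) == len(ref) + 1:
        trailing = df.iloc[:, -1].astype(str)
        is_label = cols[-1] == reference.label_name or set(trailing) <= set(
            reference.class_levels
        )
        if not is_label:
            raise TabularError(
                f"{path}: expected {len(ref)} attribute columns, got "
                f"{len(cols)}; trailing column {cols[-1]!r} is neither the "
                f"label column {reference.label_name!r} nor made of known "
                f"class levels"
            )
        truth = _as_label_array(trailing)
        df = df.iloc[:, :-1]
        cols = cols[:-1]
    elif len(cols) != len(ref):
        raise TabularError(
            f"{path}: expected {len(ref)} attribute columns "
            f"(optionally + label), got {len(cols)}"
        )

    mismatched = [(a, b) for a, b in zip(cols, ref) if a != b]
    if mismatched:
        a, b = mismatched[0]
        raise TabularError(
            f"{path}: attribute name mismatch: file has {a!r} where the "
            f"training table has {b!r}"
        )
    return UnlabeledTable(cols, _numeric_block(df, path)), truth


def write_labeled_table(
    table: LabeledTable, path: str, delimiter: str = ","
) -> None:
    """Write a labelled table with the label in the last column."""
    df = pd.DataFrame(table.values, columns=table.attribute_names)
    df[table.label_name] = table.labels
    df.to_csv(path, sep=delimiter, index=False, float_format=FLOAT_FORMAT)


def write_predictions(
    ids: list, labels: list, path: str, delimiter: str = ","
) -> None:
    """Write a two-column (instance id, predicted class) file with header."""
    if len(ids) != len(labels):
        raise TabularError(
            f"{len(ids)} ids for {len(labels)} predictions"
        )
    df = pd.DataFrame({"instance": list(ids), "prediction": list(labels)})
    df.to_csv(path, sep=delimiter, index=False)
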