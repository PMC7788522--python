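"""Median-supplement balancing of imbalanced two-class training sets.

The scheme corrects class imbalance by appending m synthetic minority-class
instances, where m is the difference between the two class counts. Each
synthetic instance is built attribute-wise as ``median_j * u`` with ``u``
drawn uniformly on [0, 1), so every synthetic value lies between 0 and the
attribute's median (sign-aware when the median is negative). The balanced
table is then handed to an ordinary classifier backend.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tabular import LabeledTable, TabularError

__all__ = [
    "MedianVector",
    "SupplementSet",
    "BalancedTable",
    "attribute_medians",
    "supplement_size",
    "generate_supplement",
    "balance",
]

MEDIAN_SCOPES = ("all", "minority")


@dataclass(frozen=True)
class MedianVector:
    """Per-attribute medians with a record of which rows they summarize.

    ``scope`` is ``"all"`` (medians over every training instance — the
    literal balancing recipe) or ``"minority"`` (medians over minority-class
    instances only).
    """

    values: np.ndarray
    scope: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())
        if self.scope not in MEDIAN_SCOPES:
            raise ValueError(f"scope must be one of {MEDIAN_SCOPES}, got {self.scope!r}")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SupplementSet:
    """An m x n block of synthetic instances plus its assigned class label."""

    values: np.ndarray
    assigned_label: str
    seed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("SupplementSet values must be an m x n matrix")
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class BalancedTable(LabeledTable):
    """A labelled table whose rows are flagged original vs synthetic.

    Original rows come first, in input order; removing the flagged rows
    recovers the input table exactly.
    """

    is_synthetic: np.ndarray | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.is_synthetic is None:
            self.is_synthetic = np.zeros(self.n_instances, dtype=bool)
        self.is_synthetic = np.asarray(self.is_synthetic, dtype=bool)
        if self.is_synthetic.shape[0] != self.n_instances:
            raise TabularError("is_synthetic flag length must match row count")

    def original(self) -> LabeledTable:
        """The input table: synthetic rows removed."""
        keep = ~self.is_synthetic
        return LabeledTable(
            list(self.attribute_names),
            self.values[keep],
            self.labels[keep],
            class_levels=self.class_levels,
            label_name=self.label_name,
        )


def _minority_majority(table: LabeledTable) -> tuple[str, str]:
    """(minority, majority) levels; a tie keeps level order (first = minority)."""
    table.require_binary()
    a, b = table.class_levels
    counts = table.class_counts()
    if counts[b] < counts[a]:
        return b, a
    return a, b


def attribute_medians(table: LabeledTable, scope: str = "all") -> MedianVector:
    """Column-wise medians over all instances or minority instances only.

    Even row counts use the arithmetic mean of the two middle order
    statistics (the usual convention, as in :func:`numpy.median`).
    """
    if scope not in MEDIAN_SCOPES:
        raise ValueError(f"scope must be one of {MEDIAN_SCOPES}, got {scope!r}")
    if table.n_instances == 0:
        raise TabularError("cannot take medians of an empty table")
    if scope == "minority":
        minority, _ = _minority_majority(table)
        rows = table.values[table.labels == minority]
        if rows.shape[0] == 0:
            raise TabularError("minority class is empty")
    else:
        rows = table.values
    return MedianVector(np.median(rows, axis=0), scope)


def supplement_size(class_counts: tuple[int, int]) -> int:
    """m = |n1 - n2|, the number of synthetic instances needed for balance."""
    n1, n2 = class_counts
    return abs(int(n1) - int(n2))


def generate_supplement(
    medians: MedianVector, m: int, label: str, seed: int
) -> SupplementSet:
    """Draw the m x n synthetic block S[i, j] = median_j * U[i, j].

    U is an m x n matrix of i.i.d. uniform draws on [0, 1), so each column
    lies between 0 and its median. Fully reproducible from ``seed``.
    """
    if m < 0:
        raise ValueError(f"supplement size m must be >= 0, got {m}")
    rng = np.random.default_rng(seed)
    u = rng.random((m, medians.n))
    return SupplementSet(u * medians.values[np.newaxis, :], str(label), int(seed))


def balance(
    table: LabeledTable, seed: int, median_scope: str = "all"
) -> BalancedTable:
    """Append a median-scaled synthetic block to equalize the class counts.

    The supplement has size m = |n1 - n2| and carries the minority-class
    label (the only labelling that yields a balanced set). Original rows
    are preserved unmodified, in order, before the synthetic rows. A table
    that is already balanced is returned unchanged apart from all-False
    synthetic flags (m = 0 fixed point).
    """
    minority, majority = _minority_majority(table)
    counts = table.class_counts()
    m = supplement_size((counts[minority], counts[majority]))
    if m == 0:
        return BalancedTable(
            list(table.attribute_names),
            table.values.copy(),
            table.labels.copy(),
            class_levels=table.class_levels,
            label_name=table.label_name,
        )
    medians = attribute_medians(table, scope=median_scope)
    supp = generate_supplement(medians, m, minority, seed)
    values = np.vstack([table.values, supp.values])
    labels = np.concatenate([table.labels, np.asarray([minority] * m, dtype=object)])
    flags = np.concatenate([np.zeros(table.n_instances, dtype=bool), np.ones(m, dtype=bool)])
    return BalancedTable(
        list(table.attribute_names),
        values,
        labels,
        class_levels=table.class_levels,
        label_name=table.label_name,
        is_synthetic=flags,
    )
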