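"""Binary symptom matrices: I/O, validation, prevalence and frequency screening.

A symptom matrix is a records x symptoms table of 0/1 indicators ("the patient
presents this manifestation"). The CSV dialect is deliberately rigid: UTF-8,
comma separated, mandatory header row of unique symptom names, every body cell
exactly ``0`` or ``1``. Incomplete records are rejected by default; an opt-in
lenient mode drops them with a logged count (missing-data EM is out of scope).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CodingError, EmptySelectionError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "SymptomMatrix",
    "read_symptom_matrix",
    "write_symptom_matrix",
    "prevalence_table",
    "screen_by_frequency",
]


@dataclass
class SymptomMatrix:
    """N x M matrix of binary clinical manifestations.

    Attributes
    ----------
    values : np.ndarray
        int8 array of shape (N, M), entries in {0, 1}.
    symptoms : list of str
        Column names, unique, order preserved from the source.
    record_ids : list
        Optional row identifiers (defaults to 0..N-1).
    """

    values: np.ndarray
    symptoms: list[str]
    record_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise SchemaError("symptom matrix must be two-dimensional")
        n, m = self.values.shape
        if n < 1:
            raise SchemaError("symptom matrix needs at least one record")
        if m != len(self.symptoms):
            raise SchemaError(
                f"{m} columns but {len(self.symptoms)} symptom names"
            )
        if len(set(self.symptoms)) != len(self.symptoms):
            dupes = sorted({s for s in self.symptoms if self.symptoms.count(s) > 1})
            raise SchemaError(f"duplicate symptom names: {dupes}")
        bad = (self.values != 0) & (self.values != 1)
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise CodingError(
                f"non-binary value {self.values[r, c]} at record {r}, "
                f"column {self.symptoms[c]!r}"
            )
        if not self.record_ids:
            self.record_ids = list(range(n))
        elif len(self.record_ids) != n:
            raise SchemaError("record_ids length does not match record count")

    # -- basic views ------------------------------------------------------

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_symptoms(self) -> int:
        return self.values.shape[1]

    def column(self, symptom: str) -> np.ndarray:
        return self.values[:, self.symptoms.index(symptom)]

    def counts(self) -> np.ndarray:
        """Per-column count of ones."""
        return self.values.sum(axis=0).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.symptoms, index=self.record_ids)

    def subset(self, symptoms: Sequence[str]) -> "SymptomMatrix":
        missing = [s for s in symptoms if s not in self.symptoms]
        if missing:
            raise SchemaError(f"unknown symptom columns: {missing}")
        idx = [self.symptoms.index(s) for s in symptoms]
        return SymptomMatrix(self.values[:, idx], list(symptoms), list(self.record_ids))

    def evidence(self, symptoms: Iterable[str] | None = None) -> dict[str, np.ndarray]:
        """Column dict view used by the inference engine."""
        names = list(symptoms) if symptoms is not None else self.symptoms
        return {s: self.column(s).astype(np.int64) for s in names}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SymptomMatrix):
            return NotImplemented
        return self.symptoms == other.symptoms and np.array_equal(
            self.values, other.values
        )


def read_symptom_matrix(path: str | Path | io.TextIOBase, strict: bool = True) -> SymptomMatrix:
    """Read a binary symptom matrix from CSV.

    Parameters
    ----------
    path : file path or open text handle
    strict : bool
        If True (default), any missing cell raises :class:`CodingError`.
        If False, records with missing cells are dropped with a logged count.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text("utf-8")
    if not text.strip():
        raise SchemaError("empty CSV")
    # check the raw header before pandas mangles duplicate names
    header = [c.strip() for c in text.splitlines()[0].split(",")]
    if len(set(header)) != len(header):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise SchemaError(f"duplicate column name(s) in header: {dupes}")
    df = pd.read_csv(io.StringIO(text), dtype=str, skipinitialspace=True)
    symptoms = [str(c) for c in df.columns]

    raw = df.to_numpy()
    missing = pd.isna(raw)
    if missing.any():
        if strict:
            r, c = map(int, np.argwhere(missing)[0])
            raise CodingError(
                f"missing value at record {r}, column {symptoms[c]!r} "
                "(strict mode; pass strict=False to drop incomplete records)"
            )
        keep = ~missing.any(axis=1)
        dropped = int((~keep).sum())
        logger.info("dropped %d incomplete record(s)", dropped)
        raw = raw[keep]
        if raw.shape[0] == 0:
            raise CodingError("all records were incomplete")

    values = np.empty(raw.shape, dtype=np.int8)
    for (r, c), cell in np.ndenumerate(raw):
        cell = str(cell).strip()
        if cell == "0":
            values[r, c] = 0
        elif cell == "1":
            values[r, c] = 1
        else:
            raise CodingError(
                f"non-binary value {cell!r} at record {r}, column {symptoms[c]!r}"
            )
    return SymptomMatrix(values, symptoms)


def write_symptom_matrix(m: SymptomMatrix, path: str | Path) -> None:
    """Write in the same rigid CSV dialect ``read_symptom_matrix`` expects."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(m.symptoms) + "\n")
        for row in m.values:
            fh.write(",".join(str(int(v)) for v in row) + "\n")


def prevalence_table(m: SymptomMatrix) -> pd.DataFrame:
    """Per-symptom frequency table, descending by count.

    Returns a DataFrame with columns (symptom, count, proportion); ties in
    count are broken by original column order.
    """
    counts = m.counts()
    order = sorted(range(m.n_symptoms), key=lambda j: (-counts[j], j))
    return pd.DataFrame(
        {
            "symptom": [m.symptoms[j] for j in order],
            "count": [int(counts[j]) for j in order],
            "proportion": [counts[j] / m.n_records for j in order],
        }
    )


def screen_by_frequency(m: SymptomMatrix, min_count: int) -> SymptomMatrix:
    """Retain columns whose count of ones is >= ``min_count`` (order preserved).

    The frequency cutoff used for a given study is an explicit analysis
    parameter: there is no default.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = m.counts()
    keep = [s for s, c in zip(m.symptoms, counts) if c >= min_count]
    if not keep:
        raise EmptySelectionError(
            f"min_count={min_count} removed every symptom column"
        )
    return m.subset(keep)
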