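"""Cohort container: a rectangular table of complete categorical records.

Internally every row is stored as integer state codes (one column per
schema variable, codes indexing the variable's ordered state list), which
makes CPT counting and prediction vectorizable.  The public surface speaks
labels: construction from a pandas DataFrame of state labels, CSV
round-trip with canonical lowercase tokens, booleans serialized as
"true"/"false".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, SchemaMismatchError
from .schema import DomainSchema

__all__ = ["Cohort", "read_cohort_csv", "write_cohort_csv"]


@dataclass(frozen=True)
class Cohort:
    """Complete categorical patient records over a :class:`DomainSchema`.

    ``codes`` has shape (n, n_variables); column order follows
    ``schema.variables``.  No missing cells are permitted — training data
    are complete by contract, and partial evidence is a query-time concept.
    """

    schema: DomainSchema
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.ndim != 2 or codes.shape[1] != len(self.schema.variables):
            raise SchemaMismatchError(
                f"codes shape {codes.shape} does not match "
                f"{len(self.schema.variables)} schema variables"
            )
        if codes.shape[0] < 1:
            raise InvalidParameterError("cohort must contain at least one row")
        cards = np.asarray(self.schema.cardinalities)
        if (codes < 0).any() or (codes >= cards).any():
            bad = np.argwhere((codes < 0) | (codes >= cards))[0]
            raise SchemaMismatchError(
                f"row {bad[0]}, variable {self.schema.names[bad[1]]!r}: "
                f"state code {codes[bad[0], bad[1]]} out of range"
            )
        object.__setattr__(self, "codes", codes)

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    def __len__(self) -> int:
        return self.n

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self.schema.index(name)]

    def subset(self, indices: Iterable[int]) -> "Cohort":
        """Row subset / multiset (indices may repeat, e.g. bootstrap)."""
        idx = np.asarray(list(indices), dtype=np.int64)
        return Cohort(self.schema, self.codes[idx])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: DomainSchema) -> "Cohort":
        missing = set(schema.names) - set(df.columns)
        if missing:
            raise SchemaMismatchError(f"cohort CSV missing columns: {sorted(missing)}")
        n = len(df)
        codes = np.empty((n, len(schema.variables)), dtype=np.int64)
        for j, spec in enumerate(schema.variables):
            col = df[spec.name].astype(str)
            mapping = {s: i for i, s in enumerate(spec.states)}
            mapped = col.map(mapping)
            if mapped.isna().any():
                row = int(mapped.isna().idxmax())
                raise SchemaMismatchError(
                    f"row {row}, column {spec.name!r}: state "
                    f"{col.iloc[row]!r} not in {list(spec.states)}"
                )
            codes[:, j] = mapped.to_numpy(dtype=np.int64)
        return cls(schema, codes)

    @classmethod
    def from_records(
        cls, records: Iterable[Mapping[str, str]], schema: DomainSchema
    ) -> "Cohort":
        df = pd.DataFrame(list(records))
        return cls.from_dataframe(df, schema)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            spec.name: np.asarray(spec.states, dtype=object)[self.codes[:, j]]
            for j, spec in enumerate(self.schema.variables)
        }
        return pd.DataFrame(data, columns=list(self.schema.names))


def read_cohort_csv(path: str | Path, schema: DomainSchema) -> Cohort:
    """Read a cohort CSV (header of canonical names, cells = state labels)."""
    df = pd.read_csv(path, dtype=str)
    return Cohort.from_dataframe(df, schema)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    cohort.to_dataframe().to_csv(path, index=False, lineterminator="\n")
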