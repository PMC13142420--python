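"""Relational table container shared by all pipeline nodes.

A :class:`Table` is a thin, schema-normalised wrapper around a pandas
DataFrame restricted to four logical dtypes — ``string``, ``integer``,
``float`` and ``boolean`` — each of which may hold missing cells
(``pd.NA``).  Missing is distinct from the empty string.  Tables are
materialised eagerly, so iterating twice trivially yields identical
content, and node outputs are plain values that can be fanned out to any
number of downstream consumers.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: logical dtype name -> pandas nullable dtype
PANDAS_DTYPES = {
    "string": "string",
    "integer": "Int64",
    "float": "Float64",
    "boolean": "boolean",
}

_LOGICAL_FROM_PANDAS = {v: k for k, v in PANDAS_DTYPES.items()}


class TableError(ValueError):
    """Schema violation: duplicate/empty column names, bad dtypes, ..."""


def _normalise_column(s: pd.Series) -> pd.Series:
    """Coerce an arbitrary pandas column to one of the four logical dtypes."""
    dt = s.dtype
    if str(dt) in _LOGICAL_FROM_PANDAS:
        return s
    if pd.api.types.is_bool_dtype(dt):
        return s.astype("boolean")
    if pd.api.types.is_integer_dtype(dt):
        return s.astype("Int64")
    if pd.api.types.is_float_dtype(dt):
        return s.astype("Float64")
    if isinstance(dt, pd.CategoricalDtype):
        return s.astype("string")
    if dt == object or pd.api.types.is_string_dtype(dt):
        # object columns may mix None with python scalars of one kind
        non_null = s.dropna()
        if len(non_null) and all(isinstance(v, bool) for v in non_null):
            return s.astype("boolean")
        if len(non_null) and all(
            isinstance(v, (int, np.integer)) and not isinstance(v, bool) for v in non_null
        ):
            return s.astype("Int64")
        if len(non_null) and all(
            isinstance(v, (int, float, np.integer, np.floating)) and not isinstance(v, bool)
            for v in non_null
        ):
            return s.astype("Float64")
        return s.astype("string")
    raise TableError(f"column {s.name!r} has unsupported dtype {dt}")


class Table:
    """Named-column relational table with nullable cells.

    Parameters
    ----------
    df : pandas.DataFrame
        Source data; dtypes are normalised on ingest (ints -> Int64,
        floats -> Float64, bools -> boolean, everything else -> string).
    """

    __slots__ = ("_df",)

    def __init__(self, df: pd.DataFrame):
        cols = list(df.columns)
        if len(cols) != len(set(cols)):
            raise TableError(f"duplicate column names: {cols}")
        for c in cols:
            if not isinstance(c, str) or c == "":
                raise TableError(f"column names must be non-empty strings, got {c!r}")
        out = df.reset_index(drop=True)
        for c in cols:
            out[c] = _normalise_column(out[c])
        self._df = out

    # -- construction ----------------------------------------------------
    @classmethod
    def from_rows(
        cls,
        columns: Sequence[str],
        rows: Iterable[Sequence[object]],
        dtypes: Sequence[str] | None = None,
    ) -> "Table":
        df = pd.DataFrame(list(rows), columns=list(columns))
        if dtypes is not None:
            if len(dtypes) != len(columns):
                raise TableError("dtypes must match columns")
            for c, d in zip(columns, dtypes):
                if d not in PANDAS_DTYPES:
                    raise TableError(f"unknown dtype {d!r}")
                df[c] = df[c].astype(PANDAS_DTYPES[d])
        return cls(df)

    @classmethod
    def empty(cls, columns: Sequence[str], dtypes: Sequence[str]) -> "Table":
        return cls.from_rows(columns, [], dtypes=dtypes)

    # -- inspection ------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def columns(self) -> list[str]:
        return list(self._df.columns)

    @property
    def schema(self) -> list[tuple[str, str]]:
        return [(c, _LOGICAL_FROM_PANDAS[str(self._df[c].dtype)]) for c in self._df.columns]

    @property
    def n_rows(self) -> int:
        return len(self._df)

    def __len__(self) -> int:
        return len(self._df)

    def head(self, n: int) -> "Table":
        if n < 0:
            raise ValueError("row limit must be >= 0")
        return Table(self._df.head(n))

    def rows(self) -> list[tuple]:
        """All rows as tuples, with missing cells as None."""
        df = self._df
        return [
            tuple(None if v is pd.NA or (isinstance(v, float) and np.isnan(v)) else v for v in row)
            for row in df.itertuples(index=False, name=None)
        ]

    def equals(self, other: "Table") -> bool:
        return self.schema == other.schema and self._df.equals(other._df)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        sch = ", ".join(f"{n}:{d}" for n, d in self.schema)
        return f"<Table [{sch}] x {self.n_rows} rows>"
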