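"""Table-level transforms: group-by aggregation, join, and long-to-wide pivot.

Row-order contracts: group/pivot outputs are sorted lexicographically by
their key columns; joins preserve left-table order.  Missing numeric
values are treated as 0 in sums; absent pivot cells take an explicit
``fill`` value (duplicated cells are summed, matching count semantics).
"""

from __future__ import annotations

import logging

import pandas as pd

from .table import Table

logger = logging.getLogger("dmsflow")

__all__ = ["group_by_sum", "join", "pivot", "load_barcode_map"]

_NUMERIC = {"Int64", "Float64"}


def _require_numeric(table: Table, cols: list[str], role: str) -> None:
    for c in cols:
        if c not in table.columns:
            raise ValueError(f"{role} column {c!r} not in table columns {table.columns}")
        if str(table.df[c].dtype) not in _NUMERIC:
            raise ValueError(f"{role} column {c!r} is not numeric (dtype {table.df[c].dtype})")


def group_by_sum(table: Table, keys: list[str], sums: list[str]) -> Table:
    """One row per distinct key tuple with each sum column totalled.

    Non-key, non-sum columns are dropped; missing numeric values count as
    0; output is sorted by the key tuple.
    """
    if set(keys) & set(sums):
        raise ValueError(f"keys and sums must be disjoint: {set(keys) & set(sums)}")
    for k in keys:
        if k not in table.columns:
            raise ValueError(f"key column {k!r} not in table columns {table.columns}")
    _require_numeric(table, sums, "sum")
    df = table.df[keys + sums].copy()
    for s in sums:
        df[s] = df[s].fillna(0)
    if not keys:
        out = df[sums].sum().to_frame().T
        return Table(out)
    grouped = df.groupby(keys, dropna=False, sort=True, as_index=False)[sums].sum()
    grouped = grouped.sort_values(keys, kind="mergesort", na_position="last").reset_index(drop=True)
    return Table(grouped)


def join(
    left: Table,
    right: Table,
    on: list[str] | None = None,
    how: str = "inner",
    left_on: list[str] | None = None,
    right_on: list[str] | None = None,
) -> Table:
    """Relational join; ``how`` is ``inner`` or ``left``.

    Unmatched left rows (left join) keep missing right-side cells.
    Right-side columns colliding with left names are suffixed ``_right``.
    Output preserves left-table row order; inner-join multiplicity is the
    product of matching group sizes.
    """
    if how not in ("inner", "left"):
        raise ValueError(f"how must be 'inner' or 'left', got {how!r}")
    if on is not None:
        left_on = right_on = list(on)
    if not left_on or not right_on or len(left_on) != len(right_on):
        raise ValueError("join requires matching 'on' (or left_on/right_on) columns")
    for c in left_on:
        if c not in left.columns:
            raise ValueError(f"join column {c!r} missing from left table")
    for c in right_on:
        if c not in right.columns:
            raise ValueError(f"join column {c!r} missing from right table")
    ldf = left.df.copy()
    ldf["__order"] = range(len(ldf))
    merged = ldf.merge(
        right.df,
        how=how,
        left_on=left_on,
        right_on=right_on,
        suffixes=("", "_right"),
        sort=False,
    )
    merged = merged.sort_values("__order", kind="mergesort").drop(columns="__order")
    if how == "inner":
        n_unmatched = len(left) - len(
            ldf.merge(
                right.df[right_on].drop_duplicates(),
                how="inner",
                left_on=left_on,
                right_on=right_on,
            )
        )
        if n_unmatched:
            logger.info("join: %d left rows had no match and were dropped", n_unmatched)
    return Table(merged.reset_index(drop=True))


def pivot(
    table: Table,
    index: list[str],
    pivot_col: str,
    value_col: str,
    prefix: str = "",
    fill: float | int = 0,
) -> Table:
    """Long-to-wide reshape: one output column per distinct pivot level.

    Duplicate (index, level) cells are summed; absent cells take ``fill``.
    Levels sort numerically when every level parses as a number, else
    lexicographically.  Output is sorted by the index tuple.
    """
    for c in index + [pivot_col, value_col]:
        if c not in table.columns:
            raise ValueError(f"column {c!r} not in table columns {table.columns}")
    _require_numeric(table, [value_col], "value")
    df = table.df
    levels = [v for v in df[pivot_col].dropna().unique()]
    level_strs = [str(v) for v in levels]

    def _numkey(s: str):
        try:
            return float(s)
        except ValueError:
            return None

    if level_strs and all(_numkey(s) is not None for s in level_strs):
        order = sorted(set(level_strs), key=lambda s: (_numkey(s), s))
    else:
        order = sorted(set(level_strs))
    wide = pd.pivot_table(
        df.assign(**{pivot_col: df[pivot_col].astype("string")}),
        index=index,
        columns=pivot_col,
        values=value_col,
        aggfunc="sum",
        fill_value=None,
        dropna=False,
    )
    out = pd.DataFrame(index=wide.index)
    for lev in order:
        col = wide[lev] if lev in wide.columns else pd.Series(pd.NA, index=wide.index)
        out[f"{prefix}{lev}"] = col.fillna(fill)
    out = out.reset_index()
    out = out.sort_values(index, kind="mergesort", na_position="last").reset_index(drop=True)
    return Table(out)


def load_barcode_map(table: Table, barcode_col: str = "barcode") -> Table:
    """Validate a barcode-to-sequence map: duplicate barcodes are an error."""
    if barcode_col not in table.columns:
        raise ValueError(f"barcode column {barcode_col!r} missing from map")
    dup = table.df[barcode_col][table.df[barcode_col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate barcodes in map: {sorted(set(dup.dropna()))[:5]}")
    return table
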