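"""Restricted row-wise expression language for derived columns.

Programs are sequences of ``name = expr`` statements evaluated per row.
The grammar is a purely functional subset: column identifiers, literals,
arithmetic (``+ - * / **``), comparisons, ``and/or/not``, conditional
``a if c else b`` and a fixed builtin set (log, log2, log10, exp, sqrt,
abs, min, max, len).  No loops, no attribute access, no user code.

Arithmetic domain errors (divide by zero, log of a non-positive number)
yield a missing cell for that row rather than aborting; any missing
operand propagates to a missing result (Kleene semantics for and/or).
"""

from __future__ import annotations

import ast
import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .table import Table

__all__ = ["ExpressionError", "ExpressionProgram", "evaluate_expression", "filter_rows"]


class ExpressionError(ValueError):
    """Syntax error, unknown identifier, or disallowed construct."""


#: sentinel for a missing cell during evaluation
MISSING = object()

_FUNCTIONS = {
    "log": math.log,
    "log2": math.log2,
    "log10": math.log10,
    "exp": math.exp,
    "sqrt": math.sqrt,
    "abs": abs,
    "min": min,
    "max": max,
    "len": len,
}

_ALLOWED_BINOPS = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: lambda a, b: a / b,
    ast.Pow: lambda a, b: a**b,
}

_ALLOWED_CMPOPS = {
    ast.Eq: lambda a, b: a == b,
    ast.NotEq: lambda a, b: a != b,
    ast.Lt: lambda a, b: a < b,
    ast.LtE: lambda a, b: a <= b,
    ast.Gt: lambda a, b: a > b,
    ast.GtE: lambda a, b: a >= b,
}


def _check_expr(node: ast.expr, known: set[str]) -> None:
    """Static validation: whitelist node types, resolve every free name."""
    if isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float, str, bool)) or node.value is None:
            raise ExpressionError(f"unsupported literal {node.value!r}")
        return
    if isinstance(node, ast.Name):
        if node.id not in known:
            raise ExpressionError(f"unknown identifier {node.id!r}")
        return
    if isinstance(node, ast.BinOp):
        if type(node.op) not in _ALLOWED_BINOPS:
            raise ExpressionError(f"operator {type(node.op).__name__} not allowed")
        _check_expr(node.left, known)
        _check_expr(node.right, known)
        return
    if isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, (ast.USub, ast.UAdd, ast.Not)):
            raise ExpressionError(f"operator {type(node.op).__name__} not allowed")
        _check_expr(node.operand, known)
        return
    if isinstance(node, ast.Compare):
        for op in node.ops:
            if type(op) not in _ALLOWED_CMPOPS:
                raise ExpressionError(f"comparison {type(op).__name__} not allowed")
        _check_expr(node.left, known)
        for c in node.comparators:
            _check_expr(c, known)
        return
    if isinstance(node, ast.BoolOp):
        for v in node.values:
            _check_expr(v, known)
        return
    if isinstance(node, ast.IfExp):
        _check_expr(node.test, known)
        _check_expr(node.body, known)
        _check_expr(node.orelse, known)
        return
    if isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCTIONS:
            raise ExpressionError("only the builtin functions "
                                  f"{sorted(_FUNCTIONS)} may be called")
        if node.keywords:
            raise ExpressionError("keyword arguments are not allowed")
        for a in node.args:
            _check_expr(a, known)
        return
    raise ExpressionError(f"construct {type(node).__name__} not allowed")


def _eval(node: ast.expr, env: dict):
    if isinstance(node, ast.Constant):
        return node.value
    if isinstance(node, ast.Name):
        return env[node.id]
    if isinstance(node, ast.BinOp):
        a = _eval(node.left, env)
        b = _eval(node.right, env)
        if a is MISSING or b is MISSING:
            return MISSING
        return _ALLOWED_BINOPS[type(node.op)](a, b)
    if isinstance(node, ast.UnaryOp):
        v = _eval(node.operand, env)
        if v is MISSING:
            return MISSING
        if isinstance(node.op, ast.USub):
            return -v
        if isinstance(node.op, ast.UAdd):
            return +v
        return not v
    if isinstance(node, ast.Compare):
        left = _eval(node.left, env)
        for op, comp in zip(node.ops, node.comparators):
            right = _eval(comp, env)
            if left is MISSING or right is MISSING:
                return MISSING
            if not _ALLOWED_CMPOPS[type(op)](left, right):
                return False
            left = right
        return True
    if isinstance(node, ast.BoolOp):
        # Kleene three-valued logic
        is_and = isinstance(node.op, ast.And)
        saw_missing = False
        for v in node.values:
            val = _eval(v, env)
            if val is MISSING:
                saw_missing = True
                continue
            if is_and and not val:
                return False
            if not is_and and val:
                return True
        return MISSING if saw_missing else is_and
    if isinstance(node, ast.IfExp):
        cond = _eval(node.test, env)
        if cond is MISSING:
            return MISSING
        return _eval(node.body, env) if cond else _eval(node.orelse, env)
    if isinstance(node, ast.Call):
        args = [_eval(a, env) for a in node.args]
        if any(a is MISSING for a in args):
            return MISSING
        return _FUNCTIONS[node.func.id](*args)
    raise AssertionError(f"unchecked node {node!r}")  # pragma: no cover


@dataclass(frozen=True)
class ExpressionProgram:
    """Parsed, statically-checked list of ``name = expr`` statements."""

    statements: tuple[tuple[str, ast.expr], ...]
    source: str

    @classmethod
    def parse(cls, text: str) -> "ExpressionProgram":
        try:
            tree = ast.parse(text, mode="exec")
        except SyntaxError as e:
            raise ExpressionError(f"syntax error: {e}") from e
        stmts: list[tuple[str, ast.expr]] = []
        for node in tree.body:
            if not isinstance(node, ast.Assign) or len(node.targets) != 1 or not isinstance(
                node.targets[0], ast.Name
            ):
                raise ExpressionError(
                    "each statement must be a single assignment 'name = expression'"
                )
            stmts.append((node.targets[0].id, node.value))
        return cls(tuple(stmts), text)

    @property
    def assigned_names(self) -> list[str]:
        return [n for n, _ in self.statements]

    def validate(self, columns: list[str]) -> None:
        """Check every free identifier resolves before any row is touched."""
        known = set(columns)
        for name, expr in self.statements:
            _check_expr(expr, known | set(_FUNCTIONS))
            known.add(name)

    def eval_row(self, env: dict) -> dict:
        """Evaluate all statements on one row environment (MISSING-aware)."""
        out: dict = {}
        scope = dict(env)
        for name, expr in self.statements:
            try:
                val = _eval(expr, scope)
            except (ZeroDivisionError, ValueError, OverflowError):
                val = MISSING
            scope[name] = val
            out[name] = val
        return out


def _cell_to_env(v):
    if v is None or v is pd.NA:
        return MISSING
    if hasattr(v, "item"):  # numpy scalar -> python scalar
        return v.item()
    return v


def _column_from_values(values: list):
    """Infer a logical dtype for freshly computed values."""
    present = [v for v in values if v is not MISSING]
    pyvals = [None if v is MISSING else v for v in values]
    if present and all(isinstance(v, bool) for v in present):
        return pd.array(pyvals, dtype="boolean")
    if present and all(isinstance(v, int) and not isinstance(v, bool) for v in present):
        return pd.array(pyvals, dtype="Int64")
    if present and all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in present):
        return pd.array([None if v is None else float(v) for v in pyvals], dtype="Float64")
    return pd.array([None if v is None else str(v) for v in pyvals], dtype="string")


def evaluate_expression(table: Table, program: ExpressionProgram | str) -> Table:
    """Append (or overwrite, with a warning) one column per statement."""
    if isinstance(program, str):
        program = ExpressionProgram.parse(program)
    program.validate(table.columns)
    results: dict[str, list] = {n: [] for n in program.assigned_names}
    for row in table.df.itertuples(index=False):
        env = {c: _cell_to_env(v) for c, v in zip(table.columns, row)}
        for name, val in program.eval_row(env).items():
            results[name].append(val)
    df = table.df.copy()
    for name in program.assigned_names:
        if name in df.columns:
            warnings.warn(f"expression overwrites existing column {name!r}", stacklevel=2)
        df[name] = _column_from_values(results[name])
    return Table(df)


def filter_rows(table: Table, predicate: str) -> Table:
    """Keep rows where the boolean predicate is true; missing drops the row."""
    try:
        tree = ast.parse(predicate, mode="eval")
    except SyntaxError as e:
        raise ExpressionError(f"syntax error in predicate: {e}") from e
    expr = tree.body
    _check_expr(expr, set(table.columns) | set(_FUNCTIONS))
    keep: list[bool] = []
    for row in table.df.itertuples(index=False):
        env = {c: _cell_to_env(v) for c, v in zip(table.columns, row)}
        try:
            val = _eval(expr, env)
        except (ZeroDivisionError, ValueError, OverflowError):
            val = MISSING
        if val is MISSING:
            keep.append(False)
        elif isinstance(val, bool):
            keep.append(val)
        else:
            raise ExpressionError(
                f"predicate must evaluate to a boolean, got {type(val).__name__}"
            )
    return Table(table.df[pd.Series(keep, index=table.df.index)])
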