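"""Readers and writers: FASTQ counting, delimited tables, filename metadata.

All file access is compression-transparent: gzip input is detected from
magic bytes, never from the extension.  FASTQ quality strings are assumed
Phred+33 (the only encoding produced by modern instruments); anything with
a character below ``!`` is rejected.
"""

from __future__ import annotations

import csv
import gzip
import io as _stdio
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .table import PANDAS_DTYPES, Table

GZIP_MAGIC = b"\x1f\x8b"

__all__ = [
    "SequenceRecord",
    "ReadFilterSpec",
    "FilterTally",
    "FilenamePattern",
    "FormatError",
    "open_maybe_gzip",
    "read_fastq",
    "count_fastq_file",
    "count_sequences",
    "read_table",
    "write_table",
    "concat_tables",
    "tokenize_filename",
]


class FormatError(ValueError):
    """Malformed input file (truncated FASTQ, ragged CSV, ...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequencing read: id, upper-cased sequence and Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )


@dataclass(frozen=True)
class ReadFilterSpec:
    """Read filters, applied in order: trim, exact_length, max_n_bases,
    min_avg_quality.  Unset fields are no-ops."""

    min_avg_quality: float | None = None
    max_n_bases: int | None = None
    exact_length: int | None = None
    trim_start: int | None = None
    trim_length: int | None = None

    def __post_init__(self):
        for name in ("min_avg_quality", "max_n_bases", "exact_length", "trim_start", "trim_length"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


#: filter names in application order (after trimming)
FILTER_ORDER = ("exact_length", "max_n_bases", "min_avg_quality")


@dataclass
class FilterTally:
    """Per-file accounting: reads seen, kept, and dropped per filter."""

    records_read: int = 0
    kept: int = 0
    dropped: dict[str, int] = field(default_factory=lambda: {k: 0 for k in FILTER_ORDER})

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped.values())


def open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    """Open ``path`` for reading, transparently un-gzipping on magic bytes."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == GZIP_MAGIC:
        fh: IO = gzip.open(raw, "rt" if "t" in mode else "rb")
    elif "t" in mode:
        fh = _stdio.TextIOWrapper(raw, encoding="utf-8", newline="")
    else:
        fh = raw
    return fh


def open_for_write(path: str | Path, compress: bool = False) -> IO:
    """Open a text handle for writing; gzip with mtime=0 for reproducible bytes."""
    if compress:
        raw = open(path, "wb")
        gz = gzip.GzipFile(fileobj=raw, mode="wb", mtime=0)
        return _stdio.TextIOWrapper(gz, encoding="utf-8", newline="")
    return open(path, "w", encoding="utf-8", newline="")


def _apply_filters(
    rec: SequenceRecord, filters: ReadFilterSpec, tally: FilterTally
) -> SequenceRecord | None:
    seq, quals = rec.sequence, rec.qualities
    if filters.trim_start is not None or filters.trim_length is not None:
        start = filters.trim_start or 0
        if start > len(seq):
            raise ValueError(
                f"trim_start {start} exceeds read length {len(seq)} (read {rec.read_id!r})"
            )
        end = len(seq) if filters.trim_length is None else start + filters.trim_length
        if end > len(seq):
            raise ValueError(
                f"trim window [{start}, {end}) exceeds read length {len(seq)} "
                f"(read {rec.read_id!r})"
            )
        seq, quals = seq[start:end], quals[start:end]
        rec = SequenceRecord(rec.read_id, seq, quals)
    if filters.exact_length is not None and len(seq) != filters.exact_length:
        tally.dropped["exact_length"] += 1
        return None
    if filters.max_n_bases is not None and seq.count("N") > filters.max_n_bases:
        tally.dropped["max_n_bases"] += 1
        return None
    if filters.min_avg_quality is not None:
        avg = sum(quals) / len(quals) if quals else 0.0
        if avg < filters.min_avg_quality:
            tally.dropped["min_avg_quality"] += 1
            return None
    return rec


def read_fastq(
    path: str | Path,
    filters: ReadFilterSpec | None = None,
    tally: FilterTally | None = None,
) -> Iterator[SequenceRecord]:
    """Stream reads from a (possibly gzipped) FASTQ file.

    Records are upper-cased, trimmed, then filtered in the documented
    order; dropped reads are tallied in ``tally`` (updated in place).
    Truncated records raise :class:`FormatError` with an approximate line
    number.
    """
    filters = filters or ReadFilterSpec()
    tally = tally if tally is not None else FilterTally()
    with open_maybe_gzip(path) as fh:
        it = FastqGeneralIterator(fh)
        n = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as e:
                raise FormatError(f"{path}: near line {4 * n + 1}: {e}") from e
            n += 1
            tally.records_read += 1
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}: near line {4 * n - 3}: sequence/quality length mismatch"
                )
            quals = tuple(ord(c) - 33 for c in qual)
            if quals and min(quals) < 0:
                raise FormatError(
                    f"{path}: near line {4 * n}: quality character below '!' "
                    "(only Phred+33 is supported)"
                )
            rec = SequenceRecord(title.split()[0] if title else "", seq.upper(), quals)
            rec = _apply_filters(rec, filters, tally)
            if rec is not None:
                tally.kept += 1
                yield rec


def count_sequences(records: Iterator[SequenceRecord] | Counter, source_label: str) -> Table:
    """Tally distinct sequences into a ``(sequence, count, file)`` table,
    sorted by sequence."""
    counter = records if isinstance(records, Counter) else Counter(r.sequence for r in records)
    seqs = sorted(counter)
    df = pd.DataFrame(
        {
            "sequence": pd.array(seqs, dtype="string"),
            "count": pd.array([counter[s] for s in seqs], dtype="Int64"),
            "file": pd.array([source_label] * len(seqs), dtype="string"),
        }
    )
    return Table(df)


def count_fastq_file(
    path: str | Path,
    filters: ReadFilterSpec | None = None,
    source_label: str | None = None,
) -> tuple[Table, FilterTally]:
    """Read, filter and count one FASTQ file in a single streaming pass."""
    tally = FilterTally()
    label = source_label if source_label is not None else Path(path).name
    counter: Counter = Counter()
    for rec in read_fastq(path, filters, tally):
        counter[rec.sequence] += 1
    return count_sequences(counter, label), tally


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

_INT_RE = re.compile(r"[+-]?\d+\Z")


def _infer_column(values: list[str | None]) -> tuple[str, list]:
    """Narrowest dtype over all values: integer < float < string."""
    non_null = [v for v in values if v is not None]
    if non_null and all(_INT_RE.match(v) for v in non_null):
        return "integer", [int(v) if v is not None else None for v in values]
    if non_null:
        try:
            floats = [float(v) if v is not None else None for v in values]
        except ValueError:
            return "string", values
        return "float", floats
    return "string", values


def read_table(
    path: str | Path,
    delimiter: str = ",",
    header: bool = True,
) -> Table:
    """Load a delimited text file (gzip-transparent) into a Table.

    Empty fields become missing; each column takes the narrowest dtype
    (integer < float < string) consistent with every value it holds.
    Ragged rows raise :class:`FormatError` naming the offending row.
    """
    with open_maybe_gzip(path) as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = list(reader)
    if not rows:
        return Table(pd.DataFrame())
    if header:
        names = rows[0]
        data = rows[1:]
    else:
        names = [f"col_{i}" for i in range(len(rows[0]))]
        data = rows
    width = len(names)
    for i, row in enumerate(data):
        if len(row) != width:
            # csv row numbers are 1-based including the header line
            raise FormatError(
                f"{path}: row {i + (2 if header else 1)}: expected {width} fields, got {len(row)}"
            )
    cols: dict[str, pd.arrays.StringArray] = {}
    df = pd.DataFrame()
    for j, name in enumerate(names):
        raw = [row[j] if row[j] != "" else None for row in data]
        dtype, vals = _infer_column(raw)
        df[name] = pd.array(vals, dtype=PANDAS_DTYPES[dtype])
    return Table(df)


def _format_cell(v) -> str:
    import numpy as np

    if v is None or v is pd.NA:
        return ""
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return str(v)


def write_table(
    table: Table,
    path: str | Path,
    delimiter: str = ",",
    header: bool = True,
    compress: bool = False,
) -> None:
    """Write a Table as RFC-4180-style delimited text.

    Missing cells become empty fields; floats use their shortest
    round-trip representation; booleans are written ``true``/``false``.
    """
    with open_for_write(path, compress=compress) as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        if header:
            writer.writerow(table.columns)
        for row in table.rows():
            writer.writerow([_format_cell(v) for v in row])


def concat_tables(tables: list[Table]) -> Table:
    """Concatenate same-schema tables (column order-insensitive), widening
    dtypes to a common type (integer+float -> float, otherwise string)."""
    if not tables:
        raise ValueError("concat_tables requires at least one table")
    first_cols = tables[0].columns
    ref = set(first_cols)
    for i, t in enumerate(tables[1:], start=1):
        cols = set(t.columns)
        if cols != ref:
            missing = sorted(ref - cols)
            extra = sorted(cols - ref)
            raise ValueError(
                f"table {i} schema mismatch: missing columns {missing}, extra columns {extra}"
            )
    frames = [t.df[first_cols] for t in tables]
    out = pd.concat(frames, ignore_index=True)
    # widen mixed-dtype columns
    for c in first_cols:
        dtypes = {str(f[c].dtype) for f in frames}
        if len(dtypes) > 1:
            if dtypes <= {"Int64", "Float64"}:
                out[c] = out[c].astype("Float64")
            elif dtypes <= {"Int64", "Float64", "boolean"}:
                out[c] = out[c].astype("Float64")
            else:
                out[c] = out[c].astype("string")
    return Table(out)


# ---------------------------------------------------------------------------
# Filename tokenisation
# ---------------------------------------------------------------------------

_PLACEHOLDER_RE = re.compile(r"\{([^{}]*)\}")


class FilenamePattern:
    """Template like ``"{sample}_rep{replicate}_t{timepoint}.fastq.gz"``.

    Placeholders capture the shortest non-empty span consistent with the
    literal separators; matching applies to the base name only.
    """

    def __init__(self, template: str):
        self.template = template
        names: list[str] = []
        regex_parts: list[str] = []
        pos = 0
        last_end_was_placeholder = False
        for m in _PLACEHOLDER_RE.finditer(template):
            literal = template[pos : m.start()]
            name = m.group(1)
            if not name.isidentifier():
                raise ValueError(f"invalid placeholder name {name!r} in {template!r}")
            if name in names:
                raise ValueError(f"duplicate placeholder {name!r} in {template!r}")
            if last_end_was_placeholder and literal == "":
                raise ValueError(
                    f"adjacent placeholders without a separator are ambiguous: {template!r}"
                )
            names.append(name)
            regex_parts.append(re.escape(literal))
            regex_parts.append(f"(?P<{name}>.+?)")
            pos = m.end()
            last_end_was_placeholder = True
        regex_parts.append(re.escape(template[pos:]))
        self.names = names
        self._regex = re.compile("".join(regex_parts) + r"\Z")

    def match(self, path: str | Path) -> dict[str, str] | None:
        m = self._regex.match(Path(path).name)
        if m is None:
            return None
        return {k: m.group(k) for k in self.names}


def tokenize_filename(path: str | Path, pattern: FilenamePattern | str) -> dict[str, str] | None:
    """Extract metadata fields from a file's base name, or None on no-match."""
    if isinstance(pattern, str):
        pattern = FilenamePattern(pattern)
    return pattern.match(path)
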