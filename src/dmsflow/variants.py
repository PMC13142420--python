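"""Substitution-only HGVS variant calling against a reference sequence.

Each observed sequence is compared position-by-position with an
equal-length reference; differences are reported in HGVS nomenclature
(``c.76A>T``, multi-substitution ``c.[4A>C;9G>T]``, identity ``c.=``) at
the DNA level and, when a reading frame is supplied, at the protein level
with three-letter residue codes (``p.Lys2Gln``, stop as ``Ter``).

Length mismatches, ambiguity codes (N) and calls exceeding an optional
substitution budget are *uncallable values*, not exceptions — pooled
libraries routinely contain reads the caller must pass over.  Indels and
other non-substitution variants are out of scope (alignment-based calling
belongs to external aligner plugins).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import seq3

from .table import Table

__all__ = [
    "ReferenceSpec",
    "VariantCall",
    "call_dna_variant",
    "call_protein_variant",
    "translate",
    "apply_variant",
    "call_variants_table",
    "load_reference_fasta",
]

_BASES = frozenset("ACGT")
_TABLE1 = unambiguous_dna_by_id[1]
_CODON_MAP = dict(_TABLE1.forward_table)
_CODON_MAP.update({c: "*" for c in _TABLE1.stop_codons})


@dataclass(frozen=True)
class ReferenceSpec:
    """Reference sequence plus HGVS coordinate context.

    ``offset`` shifts 1-based positions (tile-based sub-references);
    ``frame`` (0-based index into the sequence) enables protein calling.
    """

    sequence: str
    prefix: str = "c"
    offset: int = 0
    frame: int | None = None
    accession: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.sequence.upper()) - _BASES
        if bad:
            raise ValueError(f"reference contains non-ACGT characters: {sorted(bad)}")
        if self.prefix not in ("c", "n", "g"):
            raise ValueError(f"prefix must be one of c/n/g, got {self.prefix!r}")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.frame is not None:
            if not 0 <= self.frame < len(self.sequence):
                raise ValueError("frame must index into the reference")
            if len(self.sequence) - self.frame < 3:
                raise ValueError("reference too short for a codon in the given frame")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def _tag(self, body: str) -> str:
        head = f"{self.accession}:" if self.accession else ""
        return f"{head}{self.prefix}.{body}"


@dataclass(frozen=True)
class VariantCall:
    """Result of calling one observed sequence."""

    hgvs_dna: str | None
    hgvs_protein: str | None
    n_substitutions: int
    callable: bool
    reason: str | None = None


def call_dna_variant(
    observed: str,
    ref: ReferenceSpec,
    max_substitutions: int | None = None,
) -> VariantCall:
    """Positional comparison of ``observed`` against the reference.

    Returns an uncallable value (never raises) on length mismatch,
    non-ACGT bases, or when the substitution budget is exceeded.
    """
    obs = observed.upper()
    if len(obs) != len(ref.sequence):
        return VariantCall(None, None, 0, False, "length mismatch")
    if set(obs) - _BASES:
        return VariantCall(None, None, 0, False, "ambiguous or invalid base")
    diffs = [
        (i + 1 + ref.offset, r, o)
        for i, (r, o) in enumerate(zip(ref.sequence, obs))
        if r != o
    ]
    if max_substitutions is not None and len(diffs) > max_substitutions:
        return VariantCall(None, None, len(diffs), False, "too many substitutions")
    if not diffs:
        body = "="
    elif len(diffs) == 1:
        p, r, o = diffs[0]
        body = f"{p}{r}>{o}"
    else:
        body = "[" + ";".join(f"{p}{r}>{o}" for p, r, o in diffs) + "]"
    hgvs_protein = None
    if ref.frame is not None:
        hgvs_protein = call_protein_variant(obs, ref)
    return VariantCall(ref._tag(body), hgvs_protein, len(diffs), True)


def translate(nt: str, frame: int = 0) -> str:
    """Standard-genetic-code translation; stop codons are '*' and do not
    truncate, trailing partial codons are ignored."""
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = nt.upper()
    bad = set(seq) - _BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    aas = []
    for i in range(frame, len(seq) - 2, 3):
        aas.append(_CODON_MAP[seq[i : i + 3]])
    return "".join(aas)


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def call_protein_variant(observed_nt: str, ref: ReferenceSpec) -> str:
    """Residue-by-residue HGVS protein descriptor (``p.=`` for synonymous)."""
    if ref.frame is None:
        raise ValueError("protein calling requires ReferenceSpec.frame")
    if len(observed_nt) != len(ref.sequence):
        raise ValueError("observed and reference lengths differ")
    ref_aa = translate(ref.sequence[ref.frame :], 0)
    obs_aa = translate(observed_nt.upper()[ref.frame :], 0)
    diffs = [
        (i + 1, a, b) for i, (a, b) in enumerate(zip(ref_aa, obs_aa)) if a != b
    ]
    head = f"{ref.accession}:" if ref.accession else ""
    if not diffs:
        return f"{head}p.="
    if len(diffs) == 1:
        p, a, b = diffs[0]
        return f"{head}p.{_aa3(a)}{p}{_aa3(b)}"
    return head + "p.[" + ";".join(f"{_aa3(a)}{p}{_aa3(b)}" for p, a, b in diffs) + "]"


_SUB_RE = re.compile(r"(\d+)([ACGT])>([ACGT])\Z")


def apply_variant(hgvs_dna: str, ref: ReferenceSpec) -> str:
    """Reconstruct the observed sequence from a substitution descriptor.

    Inverse of :func:`call_dna_variant` for callable sequences; raises on
    out-of-range positions or reference-base mismatches (stale reference).
    """
    body = hgvs_dna
    if ref.accession and body.startswith(f"{ref.accession}:"):
        body = body[len(ref.accession) + 1 :]
    want = f"{ref.prefix}."
    if not body.startswith(want):
        raise ValueError(f"descriptor {hgvs_dna!r} does not match prefix {ref.prefix!r}")
    body = body[len(want) :]
    if body == "=":
        return ref.sequence
    if body.startswith("[") and body.endswith("]"):
        parts = body[1:-1].split(";")
    else:
        parts = [body]
    seq = list(ref.sequence)
    for part in parts:
        m = _SUB_RE.match(part)
        if not m:
            raise ValueError(f"unsupported descriptor component {part!r}")
        pos = int(m.group(1)) - ref.offset
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {m.group(1)} out of range for reference")
        if seq[pos - 1] != m.group(2):
            raise ValueError(
                f"reference mismatch at {m.group(1)}: descriptor says {m.group(2)}, "
                f"reference has {seq[pos - 1]}"
            )
        seq[pos - 1] = m.group(3)
    return "".join(seq)


def load_reference_fasta(path: str) -> str:
    """Read a single-record FASTA reference sequence."""
    from Bio import SeqIO

    from .io import open_maybe_gzip

    with open_maybe_gzip(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    return str(records[0].seq).upper()


def call_variants_table(
    table: Table,
    ref: ReferenceSpec,
    sequence_col: str = "sequence",
    max_substitutions: int | None = None,
    drop_uncallable: bool = False,
) -> Table:
    """Append hgvs_dna / hgvs_protein / n_substitutions / callable columns."""
    if sequence_col not in table.columns:
        raise ValueError(f"sequence column {sequence_col!r} not in table")
    cache: dict[str, VariantCall] = {}
    calls = []
    for s in table.df[sequence_col]:
        if s is pd.NA or s is None:
            calls.append(VariantCall(None, None, 0, False, "missing sequence"))
            continue
        c = cache.get(s)
        if c is None:
            c = cache[s] = call_dna_variant(s, ref, max_substitutions)
        calls.append(c)
    df = table.df.copy()
    df["hgvs_dna"] = pd.array([c.hgvs_dna for c in calls], dtype="string")
    df["hgvs_protein"] = pd.array([c.hgvs_protein for c in calls], dtype="string")
    df["n_substitutions"] = pd.array([c.n_substitutions for c in calls], dtype="Int64")
    df["callable"] = pd.array([c.callable for c in calls], dtype="boolean")
    out = Table(df)
    if drop_uncallable:
        out = Table(out.df[out.df["callable"].fillna(False).astype(bool)])
    return out
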