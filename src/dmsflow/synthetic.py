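"""Seed-deterministic synthetic datasets with known ground truth.

The generators emulate a barcoded deep-mutational-scanning experiment:

* a variant library built by substituting random positions of a
  reference sequence, each variant tagged by one or more unique barcodes;
* a growth/selection time series in which variant frequencies evolve as
  f_v(t) proportional to f_v(0) * exp(s_v * x_t) (x_t = normalised time)
  and sequencing draws a fixed-depth multinomial sample per replicate and
  time point — fixed totals make conservation checks exact;
* a FACS sort in which each variant's cells land in the bin indexed by
  its latent stability theta_v in [0, 1], with symmetric spillover
  epsilon to adjacent bins (boundary spillover folds back into the
  boundary bin), followed by per-bin multinomial sequencing.

Reads are clean by default (no sequencing errors), so count recovery
through the FASTQ path is exact; an optional uniform per-base error rate
exercises the unmapped-barcode drop path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import open_for_write
from .table import Table

__all__ = [
    "LibrarySpec",
    "SelectionSpec",
    "FacsSpec",
    "Library",
    "make_library",
    "simulate_selection",
    "simulate_facs",
    "write_fastq_fixture",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class LibrarySpec:
    """Barcoded variant library parameters."""

    n_variants: int
    barcode_length: int
    reference: str
    barcodes_per_variant: int = 1
    substitutions_per_variant: int = 1
    include_wt: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.barcode_length < 4:
            raise ValueError("barcode_length must be >= 4")
        if self.barcodes_per_variant < 1:
            raise ValueError("barcodes_per_variant must be >= 1")
        if self.substitutions_per_variant < 0:
            raise ValueError("substitutions_per_variant must be >= 0")
        if set(self.reference.upper()) - set(_BASES):
            raise ValueError("reference must be ACGT only")
        needed = self.n_variants * self.barcodes_per_variant
        if 4**self.barcode_length < needed:
            raise ValueError(
                f"4^{self.barcode_length} barcodes cannot cover {needed} assignments"
            )
        if self.substitutions_per_variant > len(self.reference):
            raise ValueError("more substitutions than reference positions")


@dataclass(frozen=True)
class VariantRecord:
    """One library member with its independently constructed HGVS truth."""

    sequence: str
    hgvs_dna: str
    barcodes: tuple[str, ...]


@dataclass(frozen=True)
class Library:
    """Generated library: barcode map plus per-variant truth."""

    spec: LibrarySpec
    variants: tuple[VariantRecord, ...]
    barcode_map: Table

    @property
    def reference(self) -> str:
        return self.spec.reference.upper()


def _hgvs_for_subs(subs: list[tuple[int, str, str]], prefix: str = "c") -> str:
    """HGVS substitution string built positionally (independent of the
    variant-calling module, so it can serve as that module's oracle)."""
    if not subs:
        return f"{prefix}.="
    parts = [f"{pos}{ref}>{alt}" for pos, ref, alt in sorted(subs)]
    if len(parts) == 1:
        return f"{prefix}.{parts[0]}"
    return f"{prefix}.[" + ";".join(parts) + "]"


def make_library(spec: LibrarySpec) -> Library:
    """Generate a deterministic barcoded variant library.

    Variant sequences are distinct (substitution sets are resampled on
    collision) and all barcodes are unique.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference.upper()
    n = spec.n_variants

    variants: list[tuple[str, str]] = []
    seen: set[str] = set()
    for v in range(n):
        if spec.include_wt and v == 0:
            seq, hgvs = ref, _hgvs_for_subs([])
            if seq in seen:
                raise ValueError("duplicate wild-type entry")  # pragma: no cover
            seen.add(seq)
            variants.append((seq, hgvs))
            continue
        for _attempt in range(1000):
            k = spec.substitutions_per_variant
            positions = sorted(rng.choice(len(ref), size=k, replace=False).tolist())
            subs = []
            chars = list(ref)
            for p in positions:
                # pick among the 3 non-reference bases
                alts = [b for b in _BASES if b != ref[p]]
                alt = alts[int(rng.integers(0, 3))]
                chars[p] = alt
                subs.append((p + 1, ref[p], alt))
            seq = "".join(chars)
            if seq not in seen:
                seen.add(seq)
                variants.append((seq, _hgvs_for_subs(subs)))
                break
        else:  # pragma: no cover - astronomically unlikely for sane specs
            raise ValueError("could not generate a distinct variant; spec too tight")

    # unique barcodes
    needed = n * spec.barcodes_per_variant
    barcodes: list[str] = []
    seen_bc: set[str] = set()
    while len(barcodes) < needed:
        draw = rng.integers(0, 4, size=(max(needed * 2, 64), spec.barcode_length))
        for row in draw:
            bc = "".join(_BASES[i] for i in row)
            if bc not in seen_bc:
                seen_bc.add(bc)
                barcodes.append(bc)
                if len(barcodes) == needed:
                    break

    records = []
    rows = []
    for v, (seq, hgvs) in enumerate(variants):
        bcs = tuple(barcodes[v * spec.barcodes_per_variant : (v + 1) * spec.barcodes_per_variant])
        records.append(VariantRecord(seq, hgvs, bcs))
        for bc in bcs:
            rows.append((bc, seq))
    bc_map = Table(
        pd.DataFrame(
            {
                "barcode": pd.array([r[0] for r in rows], dtype="string"),
                "sequence": pd.array([r[1] for r in rows], dtype="string"),
            }
        )
    )
    return Library(spec, tuple(records), bc_map)


@dataclass(frozen=True)
class SelectionSpec:
    """Growth-selection simulation parameters.

    ``true_scores`` are per-variant log-enrichments over the whole
    experiment (slope on x = normalised time); the wild type, when the
    library has one, should carry 0.
    """

    true_scores: tuple[float, ...]
    times: tuple[float, ...] = (0.0, 1.0, 2.0)
    depth: int = 50_000
    replicates: int = 2
    initial_frequencies: tuple[float, ...] | None = None
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.times) < 2 or not all(
            b > a for a, b in zip(self.times, self.times[1:])
        ):
            raise ValueError("times must be >= 2 strictly increasing values")
        if self.depth < 1 or self.replicates < 1:
            raise ValueError("depth and replicates must be >= 1")
        if self.initial_frequencies is not None:
            f = np.asarray(self.initial_frequencies)
            if len(f) != len(self.true_scores) or np.any(f <= 0):
                raise ValueError("initial_frequencies must be positive, one per variant")
            if not math.isclose(float(f.sum()), 1.0, rel_tol=1e-9):
                raise ValueError("initial_frequencies must sum to 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def expected_frequencies(sel: SelectionSpec) -> np.ndarray:
    """Closed-form variant frequencies, one row per time point."""
    s = np.asarray(sel.true_scores, dtype=float)
    t = np.asarray(sel.times, dtype=float)
    x = (t - t[0]) / (t[-1] - t[0])
    if sel.initial_frequencies is None:
        f0 = np.full(len(s), 1.0 / len(s))
    else:
        f0 = np.asarray(sel.initial_frequencies, dtype=float)
    raw = f0[None, :] * np.exp(np.outer(x, s))
    return raw / raw.sum(axis=1, keepdims=True)


def simulate_selection(lib: Library, sel: SelectionSpec) -> Table:
    """Multinomial read counts per (barcode, replicate, time).

    A variant's frequency is split uniformly among its barcodes; each
    (replicate, time) sample is a single multinomial draw of exactly
    ``depth`` reads, so per-file totals are exact.
    """
    if len(sel.true_scores) != len(lib.variants):
        raise ValueError("true_scores must have one entry per library variant")
    rng = np.random.default_rng(sel.seed)
    freqs = expected_frequencies(sel)  # (T+1, n_variants)
    bpv = lib.spec.barcodes_per_variant
    barcodes = [bc for v in lib.variants for bc in v.barcodes]
    rows = []
    for rep in range(1, sel.replicates + 1):
        for ti, t in enumerate(sel.times):
            p_variant = freqs[ti]
            p_barcode = np.repeat(p_variant / bpv, bpv)
            counts = rng.multinomial(sel.depth, p_barcode)
            for bc, c in zip(barcodes, counts):
                rows.append((bc, rep, t, int(c)))
    df = pd.DataFrame(rows, columns=["barcode", "replicate", "time", "count"])
    df["barcode"] = df["barcode"].astype("string")
    df["replicate"] = df["replicate"].astype("Int64")
    df["time"] = df["time"].astype("Float64")
    df["count"] = df["count"].astype("Int64")
    return Table(df)


@dataclass(frozen=True)
class FacsSpec:
    """FACS sort-seq simulation parameters."""

    true_stability: tuple[float, ...]
    n_bins: int = 4
    spillover: float = 0.1
    depth_per_bin: int = 20_000
    seed: int = 0

    def __post_init__(self):
        th = np.asarray(self.true_stability)
        if np.any(th < 0) or np.any(th > 1):
            raise ValueError("true_stability values must lie in [0, 1]")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if not 0 <= self.spillover < 0.5:
            raise ValueError("spillover must be in [0, 0.5)")
        if self.depth_per_bin < 1:
            raise ValueError("depth_per_bin must be >= 1")


def bin_assignment_probabilities(spec: FacsSpec) -> np.ndarray:
    """Per-variant bin probability matrix (n_variants x n_bins)."""
    th = np.asarray(spec.true_stability, dtype=float)
    B = spec.n_bins
    eps = spec.spillover
    primary = np.clip(np.ceil(th * B).astype(int), 1, B)  # 1-based
    probs = np.zeros((len(th), B))
    for i, pb in enumerate(primary):
        probs[i, pb - 1] += 1 - 2 * eps
        for adj in (pb - 1, pb + 1):
            if 1 <= adj <= B:
                probs[i, adj - 1] += eps
            else:
                probs[i, pb - 1] += eps  # fold boundary spillover inward
    return probs


def simulate_facs(lib: Library, spec: FacsSpec) -> Table:
    """Multinomial sequencing counts per (barcode, bin)."""
    if len(spec.true_stability) != len(lib.variants):
        raise ValueError("true_stability must have one entry per library variant")
    rng = np.random.default_rng(spec.seed)
    probs = bin_assignment_probabilities(spec)  # variants x bins
    bpv = lib.spec.barcodes_per_variant
    barcodes = [bc for v in lib.variants for bc in v.barcodes]
    rows = []
    for b in range(1, spec.n_bins + 1):
        occupancy = probs[:, b - 1]
        if occupancy.sum() == 0:
            continue
        p_barcode = np.repeat(occupancy / occupancy.sum() / bpv, bpv)
        counts = rng.multinomial(spec.depth_per_bin, p_barcode)
        for bc, c in zip(barcodes, counts):
            rows.append((bc, b, int(c)))
    df = pd.DataFrame(rows, columns=["barcode", "bin", "count"])
    df["barcode"] = df["barcode"].astype("string")
    df["bin"] = df["bin"].astype("Int64")
    df["count"] = df["count"].astype("Int64")
    return Table(df)


def _mutate_read(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < error_rate:
            chars[i] = _BASES[int(rng.integers(0, 4))]
    return "".join(chars)


def write_fastq_fixture(
    counts: Table,
    out_dir: str | Path,
    name_template: str = "sim_rep{replicate}_t{time}.fastq",
    group_cols: tuple[str, ...] = ("replicate", "time"),
    quality: int = 30,
    compress: bool = False,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[Path]:
    """Expand a count table into FASTQ files, one per metadata group.

    Each barcode appears ``count`` times with constant Phred quality;
    zero-count barcodes are absent.  File names instantiate
    ``name_template`` with the group values so the filename tokenizer can
    recover them downstream.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    qchar = chr(quality + 33)
    df = counts.df
    paths = []
    group_cols_l = [c for c in group_cols if c in df.columns]
    groups = (
        df.groupby(group_cols_l, sort=True) if group_cols_l else [((), df)]
    )
    for key, sub in groups:
        if not isinstance(key, tuple):
            key = (key,)
        fields = {c: _format_group_value(v) for c, v in zip(group_cols_l, key)}
        name = name_template.format(**fields) + (".gz" if compress else "")
        path = out_dir / name
        with open_for_write(path, compress=compress) as fh:
            i = 0
            for bc, c in zip(sub["barcode"], sub["count"]):
                for _ in range(int(c)):
                    seq = _mutate_read(str(bc), error_rate, rng)
                    fh.write(f"@r{i}\n{seq}\n+\n{qchar * len(seq)}\n")
                    i += 1
        paths.append(path)
    return paths


def _format_group_value(v) -> str:
    if isinstance(v, float) and float(v).is_integer():
        return str(int(v))
    return str(v)
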