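"""End-to-end barcoded time-series demo: data generation + INI pipeline.

This module wires the synthetic generators to the pipeline engine in the
canonical DMS analysis: FASTQ reads are counted per file, file-name
metadata (replicate, time) is tokenised, barcodes are translated to
variant sequences via a barcode map, variants are called against the
reference in HGVS form, counts are aggregated and pivoted to wide form,
per-replicate regression scores are fitted over the time points, and
replicates are combined with a random-effects model.  The pipeline fans
out after variant calling to produce both a DNA-level and a
protein-level score file from a single run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .io import write_table
from .pipeline import execute, parse_config
from .table import Table

__all__ = ["DemoDataset", "generate_selection_dataset", "selection_pipeline_ini", "run_selection_demo"]

#: default demo study conditions: 200 variants, 3 time points, 2 replicates,
#: 50,000 reads per (replicate, time) FASTQ file
N_VARIANTS = 200
TIMES = (0.0, 1.0, 2.0)
REPLICATES = 2
DEPTH = 50_000
REFERENCE_LENGTH_CODONS = 40
BARCODE_LENGTH = 12
BARCODES_PER_VARIANT = 3


@dataclass(frozen=True)
class DemoDataset:
    """Paths and ground truth for one generated demo dataset."""

    data_dir: Path
    fastq_files: tuple[Path, ...]
    barcode_map_csv: Path
    truth_csv: Path
    reference: str
    truth: pd.DataFrame  # columns: hgvs_dna, hgvs_protein(optional), true_score


def _random_reference(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons: a plausible ORF for protein calling."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)


def generate_selection_dataset(
    out_dir: str | Path,
    seed: int = 0,
    n_variants: int = N_VARIANTS,
    times: tuple[float, ...] = TIMES,
    replicates: int = REPLICATES,
    depth: int = DEPTH,
) -> DemoDataset:
    """Generate FASTQ files, barcode map and truth table for the demo.

    True scores are drawn uniform on [-2, 2] with the wild type fixed at
    0; initial frequencies are mildly lognormal-dispersed as in a real
    pooled library.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    reference = _random_reference(rng, REFERENCE_LENGTH_CODONS)
    lib = synthetic.make_library(
        synthetic.LibrarySpec(
            n_variants=n_variants,
            barcode_length=BARCODE_LENGTH,
            reference=reference,
            barcodes_per_variant=BARCODES_PER_VARIANT,
            substitutions_per_variant=1,
            include_wt=True,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    )
    scores = rng.uniform(-2.0, 2.0, size=n_variants)
    scores[0] = 0.0  # wild type
    f0 = rng.lognormal(mean=0.0, sigma=0.25, size=n_variants)
    f0 = f0 / f0.sum()
    sel = synthetic.SelectionSpec(
        true_scores=tuple(scores),
        times=tuple(times),
        depth=depth,
        replicates=replicates,
        initial_frequencies=tuple(f0),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    counts = synthetic.simulate_selection(lib, sel)
    fastqs = synthetic.write_fastq_fixture(counts, out_dir)

    bc_path = out_dir / "barcode_map.csv"
    write_table(lib.barcode_map, bc_path)

    from .variants import ReferenceSpec, call_protein_variant

    ref_spec = ReferenceSpec(reference, frame=0)
    truth = pd.DataFrame(
        {
            "hgvs_dna": [v.hgvs_dna for v in lib.variants],
            "hgvs_protein": [
                call_protein_variant(v.sequence, ref_spec) for v in lib.variants
            ],
            "true_score": scores,
        }
    )
    truth_path = out_dir / "truth.csv"
    write_table(Table(truth), truth_path)
    return DemoDataset(
        out_dir, tuple(fastqs), bc_path, truth_path, reference, truth
    )


def selection_pipeline_ini(
    dataset: DemoDataset,
    out_dna: str = "scores_dna.csv",
    out_protein: str = "scores_protein.csv",
    times: tuple[float, ...] = TIMES,
    pseudocount: float = 0.5,
) -> str:
    """Render the demo analysis as an INI pipeline configuration."""
    lines = ["[reads]", "plugin = fastq_reader"]
    for i, f in enumerate(sorted(dataset.fastq_files)):
        lines.append(f"files.{i} = {f.name}")
    lines.append("filename_pattern = sim_rep{replicate}_t{time}.fastq")
    time_levels = [synthetic._format_group_value(t) for t in times]
    count_cols = [f"count_{t}" for t in time_levels]
    lines += [
        "",
        "[barcode_map]",
        "plugin = csv_reader",
        f"files.0 = {dataset.barcode_map_csv.name}",
        "",
        "[translated]",
        "plugin = join",
        "input.0 = reads",
        "input.1 = barcode_map",
        "left_on.0 = sequence",
        "right_on.0 = barcode",
        "how = inner",
        "",
        "[called]",
        "plugin = variant_caller",
        "input.0 = translated",
        "sequence_col = sequence_right",
        f"reference = {dataset.reference}",
        "frame = 0",
        "drop_uncallable = true",
    ]
    for level, hgvs_col, wt, out in (
        ("dna", "hgvs_dna", "c.=", out_dna),
        ("protein", "hgvs_protein", "p.=", out_protein),
    ):
        lines += [
            "",
            f"[agg_{level}]",
            "plugin = group_by",
            "input.0 = called",
            f"keys.0 = {hgvs_col}",
            "keys.1 = replicate",
            "keys.2 = time",
            "sum.0 = count",
            "",
            f"[wide_{level}]",
            "plugin = pivot",
            f"input.0 = agg_{level}",
            f"index.0 = {hgvs_col}",
            "index.1 = replicate",
            "pivot_col = time",
            "value_col = count",
            "prefix = count_",
            "fill = 0.0",
            "",
            f"[scores_{level}]",
            "plugin = regression_score",
            f"input.0 = wide_{level}",
            f"variant_col = {hgvs_col}",
        ]
        lines += [f"counts.{i} = {c}" for i, c in enumerate(count_cols)]
        lines += [f"times.{i} = {float(t)!r}" for i, t in enumerate(times)]
        lines += [
            f"wt = {wt}",
            f"pseudocount = {pseudocount!r}",
            "group_cols.0 = replicate",
            "",
            f"[combined_{level}]",
            "plugin = combine_replicates",
            f"input.0 = scores_{level}",
            f"variant_col = {hgvs_col}",
            "",
            f"[write_{level}]",
            "plugin = csv_writer",
            f"input.0 = combined_{level}",
            f"path = {out}",
        ]
    return "\n".join(lines) + "\n"


def run_selection_demo(
    work_dir: str | Path,
    seed: int = 0,
    workers: int = 1,
    n_variants: int = N_VARIANTS,
    depth: int = DEPTH,
) -> dict:
    """Generate the demo dataset, run the full pipeline, load the outputs.

    Returns a dict with the dataset, the INI text, terminal row counts,
    and the DNA/protein score DataFrames merged with ground truth.
    """
    work_dir = Path(work_dir)
    dataset = generate_selection_dataset(
        work_dir / "data", seed=seed, n_variants=n_variants, depth=depth
    )
    ini = selection_pipeline_ini(dataset)
    graph = parse_config(ini)
    counts = execute(graph, workers=workers, seed=seed, base_dir=dataset.data_dir)
    from .io import read_table

    dna = read_table(dataset.data_dir / "scores_dna.csv").df
    protein = read_table(dataset.data_dir / "scores_protein.csv").df
    merged = dna.merge(
        dataset.truth[["hgvs_dna", "true_score"]], on="hgvs_dna", how="inner"
    )
    return {
        "dataset": dataset,
        "ini": ini,
        "row_counts": counts,
        "dna_scores": dna,
        "protein_scores": protein,
        "dna_vs_truth": merged,
    }
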