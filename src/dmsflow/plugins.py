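"""Built-in plugin implementations and the default registry.

Each plugin is a pure function ``(inputs, params, ctx) -> Table``; file
paths are resolved against the run's base directory.  Writers write to a
temporary file and rename on success, so a failed run never leaves a
partial output behind.
"""

from __future__ import annotations

import logging
import os

import pandas as pd

from . import io as dio
from . import scoring, transforms, variants
from .expressions import ExpressionProgram, evaluate_expression, filter_rows
from .pipeline import ParamSpec, PluginRegistry, PluginSpec, RunContext
from .table import Table

logger = logging.getLogger("dmsflow")

P = ParamSpec


def _filters_from_params(params: dict) -> dio.ReadFilterSpec:
    return dio.ReadFilterSpec(
        min_avg_quality=params.get("min_avg_quality"),
        max_n_bases=params.get("max_n_bases"),
        exact_length=params.get("exact_length"),
        trim_start=params.get("trim_start"),
        trim_length=params.get("trim_length"),
    )


def _apply_filename_pattern(table: Table, path, pattern: str | None) -> Table:
    if not pattern:
        return table
    pat = dio.FilenamePattern(pattern)
    fields = pat.match(path)
    if fields is None:
        logger.warning("filename %s does not match pattern %r", path, pattern)
        fields = {name: None for name in pat.names}
    df = table.df.copy()
    for name, value in fields.items():
        df[name] = pd.array([value] * len(df), dtype="string")
    return Table(df)


def fastq_reader(inputs, params, ctx: RunContext) -> Table:
    files = params["files"]
    if not files:
        raise ValueError("fastq_reader requires at least one file")
    filters = _filters_from_params(params)
    tables = []
    for f in files:
        path = ctx.resolve(f)
        counted, tally = dio.count_fastq_file(path, filters)
        logger.info(
            "fastq %s: %d reads, %d kept, %d dropped",
            path.name,
            tally.records_read,
            tally.kept,
            tally.total_dropped,
        )
        tables.append(_apply_filename_pattern(counted, path, params.get("filename_pattern")))
    return dio.concat_tables(tables)


def csv_reader(inputs, params, ctx: RunContext) -> Table:
    files = params["files"]
    if not files:
        raise ValueError("csv_reader requires at least one file")
    tables = []
    for f in files:
        path = ctx.resolve(f)
        t = dio.read_table(path, delimiter=params["delimiter"], header=params["header"])
        tables.append(_apply_filename_pattern(t, path, params.get("filename_pattern")))
    return dio.concat_tables(tables)


def group_by(inputs, params, ctx) -> Table:
    return transforms.group_by_sum(inputs[0], params["keys"], params["sum"])


def join_plugin(inputs, params, ctx) -> Table:
    return transforms.join(
        inputs[0],
        inputs[1],
        on=params.get("on"),
        how=params["how"],
        left_on=params.get("left_on"),
        right_on=params.get("right_on"),
    )


def pivot_plugin(inputs, params, ctx) -> Table:
    return transforms.pivot(
        inputs[0],
        index=params["index"],
        pivot_col=params["pivot_col"],
        value_col=params["value_col"],
        prefix=params["prefix"],
        fill=params["fill"],
    )


def expression_plugin(inputs, params, ctx) -> Table:
    program = ExpressionProgram.parse("\n".join(params["expr"]))
    return evaluate_expression(inputs[0], program)


def filter_plugin(inputs, params, ctx) -> Table:
    return filter_rows(inputs[0], params["where"])


def variant_caller(inputs, params, ctx: RunContext) -> Table:
    seq = params.get("reference")
    if params.get("reference_fasta"):
        if seq:
            raise ValueError("give either 'reference' or 'reference_fasta', not both")
        seq = variants.load_reference_fasta(str(ctx.resolve(params["reference_fasta"])))
    if not seq:
        raise ValueError("variant_caller requires a reference sequence")
    ref = variants.ReferenceSpec(
        sequence=seq,
        prefix=params["prefix"],
        offset=params["offset"],
        frame=params.get("frame"),
        accession=params.get("accession"),
    )
    return variants.call_variants_table(
        inputs[0],
        ref,
        sequence_col=params["sequence_col"],
        max_substitutions=params.get("max_substitutions"),
        drop_uncallable=params["drop_uncallable"],
    )


def ratio_score_plugin(inputs, params, ctx) -> Table:
    return scoring.ratio_score(
        inputs[0],
        variant_col=params["variant_col"],
        count_cols=params["counts"],
        wt=params["wt"],
        pseudocount=params["pseudocount"],
        normalize_wt=params["normalize_wt"],
        group_cols=params.get("group_cols"),
    )


def regression_score_plugin(inputs, params, ctx) -> Table:
    return scoring.regression_score(
        inputs[0],
        variant_col=params["variant_col"],
        count_cols=params["counts"],
        times=params.get("times"),
        wt=params["wt"],
        pseudocount=params["pseudocount"],
        normalize_wt=params["normalize_wt"],
        group_cols=params.get("group_cols"),
    )


def combine_replicates_plugin(inputs, params, ctx) -> Table:
    return scoring.combine_replicates_table(
        inputs[0],
        variant_col=params["variant_col"],
        score_col=params["score_col"],
        se_col=params["se_col"],
    )


def bin_score_plugin(inputs, params, ctx) -> Table:
    return scoring.bin_score(
        inputs[0],
        variant_col=params["variant_col"],
        count_cols=params["counts"],
        weights=params.get("weights"),
        min_total_count=params["min_total_count"],
        cell_fractions=params.get("cell_fractions"),
    )


def csv_writer(inputs, params, ctx: RunContext) -> Table:
    path = ctx.resolve(params["path"])
    tmp = path.with_name(path.name + ".tmp")
    dio.write_table(
        inputs[0],
        tmp,
        delimiter=params["delimiter"],
        header=params["header"],
        compress=params["gzip"],
    )
    os.replace(tmp, path)
    return inputs[0]


_FILTER_PARAMS = (
    P("min_avg_quality", "float"),
    P("max_n_bases", "int"),
    P("exact_length", "int"),
    P("trim_start", "int"),
    P("trim_length", "int"),
)


def build_registry() -> PluginRegistry:
    reg = PluginRegistry()
    reg.register(
        PluginSpec(
            "fastq_reader",
            0,
            0,
            (P("files", "list_str", required=True), P("filename_pattern", "str"))
            + _FILTER_PARAMS,
            fastq_reader,
        )
    )
    reg.register(
        PluginSpec(
            "csv_reader",
            0,
            0,
            (
                P("files", "list_str", required=True),
                P("delimiter", "str", default=","),
                P("header", "bool", default=True),
                P("filename_pattern", "str"),
            ),
            csv_reader,
        )
    )
    reg.register(
        PluginSpec(
            "group_by",
            1,
            1,
            (P("keys", "list_str", required=True), P("sum", "list_str", required=True)),
            group_by,
        )
    )
    reg.register(
        PluginSpec(
            "join",
            2,
            2,
            (
                P("on", "list_str"),
                P("left_on", "list_str"),
                P("right_on", "list_str"),
                P("how", "str", default="inner"),
            ),
            join_plugin,
        )
    )
    reg.register(
        PluginSpec(
            "pivot",
            1,
            1,
            (
                P("index", "list_str", required=True),
                P("pivot_col", "str", required=True),
                P("value_col", "str", required=True),
                P("prefix", "str", default=""),
                P("fill", "float", required=True),
            ),
            pivot_plugin,
        )
    )
    reg.register(
        PluginSpec("expression", 1, 1, (P("expr", "list_str", required=True),), expression_plugin)
    )
    reg.register(PluginSpec("filter", 1, 1, (P("where", "str", required=True),), filter_plugin))
    reg.register(
        PluginSpec(
            "variant_caller",
            1,
            1,
            (
                P("sequence_col", "str", default="sequence"),
                P("reference", "str"),
                P("reference_fasta", "str"),
                P("prefix", "str", default="c"),
                P("offset", "int", default=0),
                P("frame", "int"),
                P("accession", "str"),
                P("max_substitutions", "int"),
                P("drop_uncallable", "bool", default=False),
            ),
            variant_caller,
        )
    )
    score_common = (
        P("variant_col", "str", required=True),
        P("counts", "list_str", required=True),
        P("wt", "str", default="c.="),
        P("pseudocount", "float", default=scoring.DEFAULT_PSEUDOCOUNT),
        P("normalize_wt", "bool", default=True),
        P("group_cols", "list_str"),
    )
    reg.register(PluginSpec("ratio_score", 1, 1, score_common, ratio_score_plugin))
    reg.register(
        PluginSpec(
            "regression_score",
            1,
            1,
            score_common + (P("times", "list_float"),),
            regression_score_plugin,
        )
    )
    reg.register(
        PluginSpec(
            "combine_replicates",
            1,
            1,
            (
                P("variant_col", "str", required=True),
                P("score_col", "str", default="score"),
                P("se_col", "str", default="SE"),
            ),
            combine_replicates_plugin,
        )
    )
    reg.register(
        PluginSpec(
            "bin_score",
            1,
            1,
            (
                P("variant_col", "str", required=True),
                P("counts", "list_str", required=True),
                P("weights", "list_float"),
                P("min_total_count", "int", default=0),
                P("cell_fractions", "list_float"),
            ),
            bin_score_plugin,
        )
    )
    reg.register(
        PluginSpec(
            "csv_writer",
            1,
            1,
            (
                P("path", "str", required=True),
                P("delimiter", "str", default=","),
                P("header", "bool", default=True),
                P("gzip", "bool", default=False),
            ),
            csv_writer,
        )
    )
    return reg
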