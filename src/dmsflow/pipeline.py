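"""Pipeline graph model: INI configuration, validation, and execution.

A pipeline is a DAG of plugin nodes.  Each INI section declares one node:
the reserved key ``plugin`` names the registered plugin type, reserved
keys ``input.<k>`` name the upstream sections feeding input slot *k*, and
every other key is a plugin parameter (list parameters use dotted numeric
suffixes, ``files.0``, ``files.1``, ...).

Execution is purely functional per node, so running with one worker or
many yields byte-identical outputs; parallelism across independent
branches is an implementation detail.
"""

from __future__ import annotations

import configparser
import heapq
import io as _stdio
import logging
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field
from pathlib import Path

from .table import Table

logger = logging.getLogger("dmsflow")

__all__ = [
    "ParamSpec",
    "PluginSpec",
    "PluginRegistry",
    "PluginNode",
    "PipelineGraph",
    "Diagnostic",
    "ConfigError",
    "GraphError",
    "ExecutionError",
    "RunContext",
    "parse_config",
    "serialize_config",
    "validate_graph",
    "topological_order",
    "execute",
    "preview",
    "default_registry",
]


class ConfigError(ValueError):
    """Malformed INI or a section that cannot be mapped onto a plugin."""


class GraphError(ValueError):
    """Invalid graph structure (cycle, dangling reference, arity)."""


class ExecutionError(RuntimeError):
    """A node failed during execution; carries the node id and cause."""

    def __init__(self, node_id: str, cause: BaseException):
        super().__init__(f"node {node_id!r} failed: {cause}")
        self.node_id = node_id
        self.cause = cause


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_SCALAR_KINDS = ("str", "int", "float", "bool")
_LIST_KINDS = ("list_str", "list_int", "list_float")


@dataclass(frozen=True)
class ParamSpec:
    """Declared plugin parameter: name, kind and optional default."""

    name: str
    kind: str
    default: object = None
    required: bool = False

    def __post_init__(self):
        if self.kind not in _SCALAR_KINDS + _LIST_KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")

    @property
    def is_list(self) -> bool:
        return self.kind in _LIST_KINDS


@dataclass(frozen=True)
class PluginSpec:
    """A registered plugin type: arity, parameter schema and callable."""

    name: str
    min_inputs: int
    max_inputs: int
    params: tuple[ParamSpec, ...]
    func: object  # callable(inputs: list[Table], params: dict, ctx: RunContext) -> Table

    def param(self, name: str) -> ParamSpec | None:
        for p in self.params:
            if p.name == name:
                return p
        return None


class PluginRegistry:
    """Mapping of plugin type names to :class:`PluginSpec`."""

    def __init__(self):
        self._plugins: dict[str, PluginSpec] = {}

    def register(self, spec: PluginSpec) -> None:
        if spec.name in self._plugins:
            raise ValueError(f"plugin type {spec.name!r} already registered")
        self._plugins[spec.name] = spec

    def get(self, name: str) -> PluginSpec:
        try:
            return self._plugins[name]
        except KeyError:
            raise KeyError(f"unknown plugin type {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._plugins

    def names(self) -> list[str]:
        return sorted(self._plugins)


def default_registry() -> PluginRegistry:
    """Registry with every built-in plugin pre-registered."""
    from .plugins import build_registry

    return build_registry()


# ---------------------------------------------------------------------------
# Graph model
# ---------------------------------------------------------------------------


@dataclass
class PluginNode:
    """One configured pipeline step."""

    node_id: str
    plugin_type: str
    params: dict = field(default_factory=dict)
    input_ids: list[str] = field(default_factory=list)

    def __eq__(self, other):
        return (
            isinstance(other, PluginNode)
            and self.node_id == other.node_id
            and self.plugin_type == other.plugin_type
            and self.params == other.params
            and self.input_ids == other.input_ids
        )


@dataclass
class PipelineGraph:
    """DAG of plugin nodes; edges are implied by each node's input_ids."""

    nodes: dict[str, PluginNode] = field(default_factory=dict)

    def add(self, node: PluginNode) -> None:
        if node.node_id in self.nodes:
            raise GraphError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node

    def consumers(self, node_id: str) -> list[str]:
        return [n.node_id for n in self.nodes.values() if node_id in n.input_ids]

    def terminal_ids(self) -> list[str]:
        has_consumer = {i for n in self.nodes.values() for i in n.input_ids}
        return sorted(set(self.nodes) - has_consumer)

    def __eq__(self, other):
        return isinstance(other, PipelineGraph) and self.nodes == other.nodes


@dataclass(frozen=True)
class Diagnostic:
    """One validation problem, naming the offending node."""

    node_id: str
    message: str

    def __str__(self):
        return f"[{self.node_id}] {self.message}"


# ---------------------------------------------------------------------------
# INI parsing / serialization
# ---------------------------------------------------------------------------


def _coerce_scalar(value: str, kind: str, where: str):
    try:
        if kind == "int":
            return int(value)
        if kind == "float":
            return float(value)
        if kind == "bool":
            low = value.strip().lower()
            if low in ("true", "yes", "1"):
                return True
            if low in ("false", "no", "0"):
                return False
            raise ValueError(f"not a boolean: {value!r}")
        return value
    except ValueError as e:
        raise ConfigError(f"{where}: cannot parse {value!r} as {kind}: {e}") from e


def parse_config(ini_text: str, registry: PluginRegistry | None = None) -> PipelineGraph:
    """Build a PipelineGraph from INI text.

    One section per node; parameter values are coerced to each plugin's
    declared types; dangling input references raise a validation error.
    """
    registry = registry or default_registry()
    cp = configparser.ConfigParser(
        strict=True, interpolation=None, delimiters=("=",), comment_prefixes=("#", ";")
    )
    cp.optionxform = str  # preserve key case
    try:
        cp.read_string(ini_text)
    except configparser.Error as e:
        lineno = getattr(e, "lineno", None)
        at = f" at line {lineno}" if lineno else ""
        raise ConfigError(f"malformed INI{at}: {e}") from e

    graph = PipelineGraph()
    for section in cp.sections():
        items = dict(cp.items(section))
        plugin_type = items.pop("plugin", None)
        if plugin_type is None:
            raise ConfigError(f"section [{section}] has no 'plugin' key")
        if plugin_type not in registry:
            raise ConfigError(
                f"section [{section}]: unknown plugin type {plugin_type!r} "
                f"(known: {registry.names()})"
            )
        spec = registry.get(plugin_type)
        # inputs
        input_keys = sorted(
            (k for k in items if k.startswith("input.")),
            key=lambda k: int(k.split(".", 1)[1]),
        )
        for i, k in enumerate(input_keys):
            if k != f"input.{i}":
                raise ConfigError(f"section [{section}]: input slots must be input.0..input.k")
        input_ids = [items.pop(k) for k in input_keys]
        # parameters
        params: dict = {}
        list_parts: dict[str, dict[int, str]] = {}
        for key, value in items.items():
            if "." in key:
                base, _, idx = key.rpartition(".")
                if idx.isdigit():
                    p = spec.param(base)
                    if p is None or not p.is_list:
                        raise ConfigError(
                            f"section [{section}]: unknown list parameter {base!r} "
                            f"for plugin {plugin_type!r}"
                        )
                    list_parts.setdefault(base, {})[int(idx)] = value
                    continue
            p = spec.param(key)
            if p is None:
                raise ConfigError(
                    f"section [{section}]: unknown parameter {key!r} for plugin {plugin_type!r}"
                )
            if p.is_list:
                raise ConfigError(
                    f"section [{section}]: list parameter {key!r} needs dotted "
                    f"numeric suffixes ({key}.0, {key}.1, ...)"
                )
            params[key] = _coerce_scalar(value, p.kind, f"section [{section}], key {key}")
        for base, parts in list_parts.items():
            idxs = sorted(parts)
            if idxs != list(range(len(idxs))):
                raise ConfigError(
                    f"section [{section}]: list parameter {base!r} indices must be 0..n"
                )
            elem_kind = registry.get(plugin_type).param(base).kind.split("_", 1)[1]
            params[base] = [
                _coerce_scalar(parts[i], elem_kind, f"section [{section}], key {base}.{i}")
                for i in idxs
            ]
        graph.add(PluginNode(section, plugin_type, params, input_ids))

    for node in graph.nodes.values():
        for ref in node.input_ids:
            if ref not in graph.nodes:
                raise ConfigError(
                    f"section [{node.node_id}]: input reference {ref!r} names no section"
                )
    return graph


def _format_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def serialize_config(graph: PipelineGraph, registry: PluginRegistry | None = None) -> str:
    """Render a graph as INI text; parse_config round-trips it exactly.

    Sections appear in topological order; within a section keys are
    ``plugin``, ``input.k``, then parameters sorted by name.
    """
    order = topological_order(graph)
    out = _stdio.StringIO()
    first = True
    for nid in order:
        node = graph.nodes[nid]
        if not first:
            out.write("\n")
        first = False
        out.write(f"[{nid}]\n")
        out.write(f"plugin = {node.plugin_type}\n")
        for i, ref in enumerate(node.input_ids):
            out.write(f"input.{i} = {ref}\n")
        for key in sorted(node.params):
            val = node.params[key]
            if isinstance(val, list):
                for i, v in enumerate(val):
                    out.write(f"{key}.{i} = {_format_value(v)}\n")
            else:
                out.write(f"{key} = {_format_value(val)}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Validation / ordering
# ---------------------------------------------------------------------------


def _find_cycle(graph: PipelineGraph) -> list[str] | None:
    WHITE, GREY, BLACK = 0, 1, 2
    color = {nid: WHITE for nid in graph.nodes}
    stack_path: list[str] = []

    def visit(nid: str) -> list[str] | None:
        color[nid] = GREY
        stack_path.append(nid)
        for dep in graph.nodes[nid].input_ids:
            if dep not in graph.nodes:
                continue
            if color[dep] == GREY:
                i = stack_path.index(dep)
                return stack_path[i:]
            if color[dep] == WHITE:
                cyc = visit(dep)
                if cyc:
                    return cyc
        stack_path.pop()
        color[nid] = BLACK
        return None

    for nid in sorted(graph.nodes):
        if color[nid] == WHITE:
            cyc = visit(nid)
            if cyc:
                return cyc
    return None


def validate_graph(
    graph: PipelineGraph, registry: PluginRegistry | None = None
) -> list[Diagnostic]:
    """Return one diagnostic per invariant violation (empty list = valid)."""
    registry = registry or default_registry()
    diags: list[Diagnostic] = []
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        if node.plugin_type not in registry:
            diags.append(Diagnostic(nid, f"unknown plugin type {node.plugin_type!r}"))
            continue
        spec = registry.get(node.plugin_type)
        n = len(node.input_ids)
        if not spec.min_inputs <= n <= spec.max_inputs:
            want = (
                str(spec.min_inputs)
                if spec.min_inputs == spec.max_inputs
                else f"{spec.min_inputs}..{spec.max_inputs}"
            )
            diags.append(
                Diagnostic(nid, f"plugin {node.plugin_type!r} takes {want} inputs, got {n}")
            )
        for ref in node.input_ids:
            if ref not in graph.nodes:
                diags.append(Diagnostic(nid, f"input reference {ref!r} names no node"))
        for p in spec.params:
            if p.required and p.name not in node.params:
                diags.append(Diagnostic(nid, f"required parameter {p.name!r} missing"))
    cyc = _find_cycle(graph)
    if cyc:
        diags.append(Diagnostic(cyc[0], f"cycle detected: {' -> '.join(cyc + [cyc[0]])}"))
    return diags


def topological_order(graph: PipelineGraph) -> list[str]:
    """Kahn's algorithm with lexicographic tie-breaking (deterministic)."""
    indeg = {nid: 0 for nid in graph.nodes}
    for node in graph.nodes.values():
        for dep in node.input_ids:
            if dep in graph.nodes:
                indeg[node.node_id] += 1
    ready = [nid for nid, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    order: list[str] = []
    consumers: dict[str, list[str]] = {nid: [] for nid in graph.nodes}
    for node in graph.nodes.values():
        for dep in node.input_ids:
            if dep in graph.nodes:
                consumers[dep].append(node.node_id)
    while ready:
        nid = heapq.heappop(ready)
        order.append(nid)
        for c in consumers[nid]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != len(graph.nodes):
        cyc = _find_cycle(graph)
        raise GraphError(f"graph contains a cycle: {' -> '.join(cyc or [])}")
    return order


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


@dataclass
class RunContext:
    """Run-level options passed to every plugin invocation."""

    seed: int = 0
    workers: int = 1
    base_dir: Path = field(default_factory=Path.cwd)
    node_id: str = ""

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.base_dir / p


def _full_params(spec: PluginSpec, node: PluginNode) -> dict:
    params = {p.name: p.default for p in spec.params}
    params.update(node.params)
    return params


def _run_node(graph, registry, ctx: RunContext, nid: str, results: dict) -> Table:
    node = graph.nodes[nid]
    spec = registry.get(node.plugin_type)
    inputs = [results[i] for i in node.input_ids]
    node_ctx = RunContext(ctx.seed, ctx.workers, ctx.base_dir, node_id=nid)
    logger.info("node %s (%s): starting", nid, node.plugin_type)
    try:
        out = spec.func(inputs, _full_params(spec, node), node_ctx)
    except Exception as e:
        raise ExecutionError(nid, e) from e
    if not isinstance(out, Table):
        raise ExecutionError(nid, TypeError(f"plugin returned {type(out).__name__}, not Table"))
    logger.info("node %s (%s): finished, %d rows", nid, node.plugin_type, out.n_rows)
    return out


def _execute_nodes(
    graph: PipelineGraph,
    registry: PluginRegistry,
    ctx: RunContext,
    wanted: set[str],
) -> dict[str, Table]:
    """Compute the outputs of ``wanted`` nodes and their ancestors."""
    needed: set[str] = set()
    stack = list(wanted)
    while stack:
        nid = stack.pop()
        if nid in needed:
            continue
        needed.add(nid)
        stack.extend(graph.nodes[nid].input_ids)
    order = [nid for nid in topological_order(graph) if nid in needed]
    results: dict[str, Table] = {}
    if ctx.workers <= 1:
        for nid in order:
            results[nid] = _run_node(graph, registry, ctx, nid, results)
        return results
    remaining = {nid: set(graph.nodes[nid].input_ids) for nid in order}
    with ThreadPoolExecutor(max_workers=ctx.workers) as pool:
        futures = {}
        failed: ExecutionError | None = None

        def submit_ready():
            for nid in sorted(remaining):
                if not remaining[nid] and nid not in futures:
                    futures[nid] = pool.submit(_run_node, graph, registry, ctx, nid, results)

        submit_ready()
        while any(nid not in results for nid in order):
            pending = {f: nid for nid, f in futures.items() if nid not in results}
            if not pending:
                break
            done, _ = wait(list(pending), return_when=FIRST_COMPLETED)
            for f in done:
                nid = pending[f]
                try:
                    results[nid] = f.result()
                except ExecutionError as e:
                    failed = e
                if failed:
                    break
                del remaining[nid]
                for other in remaining:
                    remaining[other].discard(nid)
            if failed:
                break
            submit_ready()
        if failed:
            raise failed
    return results


def execute(
    graph: PipelineGraph,
    registry: PluginRegistry | None = None,
    workers: int = 1,
    seed: int = 0,
    base_dir: str | Path | None = None,
) -> dict[str, int]:
    """Run the full pipeline; returns terminal-node row counts.

    The graph must validate cleanly.  A node failure aborts the run
    (downstream nodes never execute) with an :class:`ExecutionError`
    naming the node.
    """
    registry = registry or default_registry()
    diags = validate_graph(graph, registry)
    if diags:
        raise GraphError("invalid graph: " + "; ".join(str(d) for d in diags))
    ctx = RunContext(seed=seed, workers=workers, base_dir=Path(base_dir or Path.cwd()))
    terminals = graph.terminal_ids()
    results = _execute_nodes(graph, registry, ctx, set(terminals))
    return {nid: results[nid].n_rows for nid in terminals}


def preview(
    graph: PipelineGraph,
    node_id: str,
    row_limit: int,
    registry: PluginRegistry | None = None,
    seed: int = 0,
    base_dir: str | Path | None = None,
) -> Table:
    """First ``row_limit`` rows of one node's output (full schema).

    Only the node's ancestors are executed; writer side effects upstream
    of the node still occur, so preview terminal writers with care.
    """
    registry = registry or default_registry()
    if node_id not in graph.nodes:
        raise GraphError(f"unknown node id {node_id!r}")
    if row_limit < 0:
        raise ValueError("row_limit must be >= 0")
    ctx = RunContext(seed=seed, workers=1, base_dir=Path(base_dir or Path.cwd()))
    results = _execute_nodes(graph, registry, ctx, {node_id})
    return results[node_id].head(row_limit)
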