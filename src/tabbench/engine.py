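"""Script preprocessing and app execution.

Scripts run *line by line* in a backend session. Preprocessing turns the
script text into ordered executable units: each line is a unit, except that
lines enclosed between a bare ``{{`` line and a bare ``}}`` line form a
single block unit (for multi-line constructs), and a line starting with
``###applyParameters`` marks the injection point — the position at which
the input table and the user's parameter bindings are loaded into the
session. Without the directive, injection happens before the first unit.

Execution streams each unit's textual output into a transcript (the
console-pane record), supports cancellation at unit boundaries, and on
success collects the app's declared outputs (columns, tables, file paths)
from the session. Outputs are all-or-nothing: an errored or cancelled run
yields none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Literal, Mapping

import numpy as np
import pandas as pd

from .appspec import AppSpec, COLUMN_TYPES, ParamSpec, RANGE_TYPES, validate_value
from .backends import Backend, BackendError, BackendValue
from .errors import OutputError, ShapeError, StructureError, ValidationError

#: Well-known session variable holding the app's input table.
INPUT_TABLE_NAME = "input_table"

DIRECTIVE = "###applyParameters"


@dataclass(frozen=True)
class ScriptUnit:
    code: str
    line_span: tuple[int, int]  # 1-based, inclusive
    kind: Literal["line", "block"] = "line"


@dataclass(frozen=True)
class ScriptProgram:
    units: tuple[ScriptUnit, ...]
    inject_index: int  # parameters/input loaded before units[inject_index]

    def __post_init__(self):
        if not 0 <= self.inject_index <= len(self.units):
            raise ValueError("inject_index out of range")


@dataclass
class ExecutionResult:
    status: Literal["ok", "error", "cancelled"]
    transcript: list[str] = field(default_factory=list)
    outputs: dict[str, Any] = field(default_factory=dict)
    error: str | None = None


def preprocess_script(text: str) -> ScriptProgram:
    """Split script text into executable units and locate the injection point.

    Raises :class:`StructureError` for an unclosed or nested ``{{`` block,
    for a stray ``}}``, and for a repeated ``###applyParameters`` directive
    (the first occurrence wins; a second is an error).
    """
    units: list[ScriptUnit] = []
    inject_index: int | None = None
    block_start: int | None = None
    block_lines: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped == "{{":
            if block_start is not None:
                raise StructureError(f"nested '{{{{' at line {lineno}")
            block_start = lineno
            block_lines = []
            continue
        if stripped == "}}":
            if block_start is None:
                raise StructureError(f"'}}}}' without matching '{{{{' at line {lineno}")
            units.append(
                ScriptUnit(
                    code="\n".join(block_lines),
                    line_span=(block_start + 1, lineno - 1),
                    kind="block",
                )
            )
            block_start = None
            continue
        if block_start is not None:
            block_lines.append(line)
            continue
        if stripped.startswith(DIRECTIVE):
            if inject_index is not None:
                raise StructureError(
                    f"repeated {DIRECTIVE} directive at line {lineno}"
                )
            inject_index = len(units)
            continue
        units.append(ScriptUnit(code=line, line_span=(lineno, lineno)))
    if block_start is not None:
        raise StructureError(f"unclosed '{{{{' opened at line {block_start}")
    return ScriptProgram(tuple(units), inject_index if inject_index is not None else 0)


# ---------------------------------------------------------------------------
# Bindings


def check_bindings(spec: AppSpec, bindings: Mapping[str, Any]) -> None:
    """Every bound name must exist; every required parameter must be bound."""
    names = {p.variable_name for p in spec.params}
    for name in bindings:
        if name not in names:
            raise ValidationError(f"binding for unknown parameter {name!r}")
    for p in spec.required_params:
        if p.variable_name not in bindings:
            raise ValidationError(f"required parameter {p.variable_name!r} not bound")


def effective_bindings(spec: AppSpec, bindings: Mapping[str, Any]) -> dict[str, Any]:
    """Bindings merged over manifest defaults (explicit bindings win)."""
    merged: dict[str, Any] = {}
    for p in spec.params:
        if p.variable_name in bindings:
            merged[p.variable_name] = bindings[p.variable_name]
        elif p.default is not None:
            merged[p.variable_name] = p.default
    return merged


def encode_binding(spec: ParamSpec, value, table=None) -> BackendValue:
    """Translate a validated parameter value into a backend session value.

    Scalars map to typed scalars, range types to a length-2 numeric vector,
    column selections to (single- or multi-column) tabular values extracted
    from the input table, and output destinations to text scalars.
    """
    t = spec.type
    if t == "int":
        return BackendValue("integer", int(value))
    if t == "double":
        return BackendValue("numeric", float(value))
    if t == "boolean":
        return BackendValue("logical", bool(value))
    if t in ("string", "filename", "color", "string-items") or spec.is_output:
        return BackendValue("character", str(value))
    if t in RANGE_TYPES:
        lo, hi = value
        return BackendValue("vector", [float(lo), float(hi)])
    # column selections: carried as tabular values
    names = value if isinstance(value, (list, tuple)) else [value]
    if table is None:
        raise ValidationError(
            f"{spec.variable_name}: column binding requires the input table"
        )
    df = table.df if hasattr(table, "df") else table
    return BackendValue("table", df[list(names)].copy())


# ---------------------------------------------------------------------------
# Execution


def _inject(
    spec: AppSpec,
    table,
    bindings: Mapping[str, Any],
    backend: Backend,
) -> None:
    if table is not None:
        df = table.df if hasattr(table, "df") else table
        backend.set_value(INPUT_TABLE_NAME, BackendValue("table", df.copy()))
    schema = table if table is not None else None
    for p in spec.params:
        if p.variable_name not in bindings:
            continue
        raw = bindings[p.variable_name]
        if p.type in COLUMN_TYPES and raw in ("", [], None):
            continue  # optional column parameter left unselected
        value = validate_value(p, raw, schema)
        backend.set_value(p.variable_name, encode_binding(p, value, table))


def run_app(
    spec: AppSpec,
    table,
    bindings: Mapping[str, Any],
    backend: Backend,
    cancel: Callable[[], bool] | None = None,
) -> ExecutionResult:
    """Execute an app: preprocess its script, inject inputs, run the units.

    ``cancel`` is polled at unit boundaries; a cancelled run reports the
    transcript accumulated so far and no outputs. A failing unit yields
    status ``error`` with the backend's error text kept verbatim in the
    transcript (console-pane behavior).
    """
    check_bindings(spec, bindings)
    merged = effective_bindings(spec, bindings)
    with open(spec.script_ref, "r", encoding="utf-8") as fh:
        program = preprocess_script(fh.read())
    return run_program(spec, program, table, merged, backend, cancel)


def run_program(
    spec: AppSpec,
    program: ScriptProgram,
    table,
    bindings: Mapping[str, Any],
    backend: Backend,
    cancel: Callable[[], bool] | None = None,
) -> ExecutionResult:
    """Like :func:`run_app` but over an already-preprocessed program."""
    result = ExecutionResult(status="ok")
    injected = False
    for i, unit in enumerate(program.units):
        if i == program.inject_index:
            _inject(spec, table, bindings, backend)
            injected = True
        try:
            text = backend.evaluate(unit.code)
        except BackendError as exc:
            result.transcript.append(exc.output if exc.output is not None else str(exc))
            result.status = "error"
            result.error = str(exc)
            return result
        result.transcript.append(text)
        if cancel is not None and cancel():
            result.status = "cancelled"
            return result
    if not injected:  # inject_index == len(units), or empty script
        _inject(spec, table, bindings, backend)
    n_rows = len(table.df if hasattr(table, "df") else table) if table is not None else None
    result.outputs = collect_outputs(spec, bindings, backend, n_rows)
    return result


def collect_outputs(
    spec: AppSpec,
    bindings: Mapping[str, Any],
    backend: Backend,
    n_rows: int | None = None,
) -> dict[str, Any]:
    """Fetch declared outputs from the session after a successful run.

    For each output-column / output-table parameter bound to a non-empty
    destination name, the session variable named by the *parameter's*
    variable name is fetched and stored under the *destination* name; a
    blank destination skips that output. Column payloads must match the
    input table's row count. File outputs are the paths bound to
    save-dialog filename parameters.
    """
    outputs: dict[str, Any] = {}
    for p in spec.output_params:
        destination = str(bindings.get(p.variable_name, "") or "").strip()
        if not destination:
            continue
        try:
            value = backend.fetch(p.variable_name)
        except BackendError as exc:
            raise OutputError(
                f"output parameter {p.variable_name!r}: {exc}"
            ) from exc
        if p.type == "output-column":
            vec = np.atleast_1d(np.asarray(value))
            if n_rows is not None and len(vec) != n_rows:
                raise ShapeError(
                    f"output column {destination!r} has length {len(vec)},"
                    f" input table has {n_rows} rows"
                )
            outputs[destination] = vec
        else:  # output-table
            if not isinstance(value, pd.DataFrame):
                value = pd.DataFrame(np.atleast_2d(np.asarray(value)))
            outputs[destination] = value
    for p in spec.params:
        if p.type == "filename" and p.ui_hint == "save":
            path = str(bindings.get(p.variable_name, "") or "").strip()
            if path:
                outputs[path] = path
    return outputs
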