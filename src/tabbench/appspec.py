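"""App manifests: typed parameters, interface models, bundle discovery.

An *app bundle* is a script file (``analysis.R``) plus a same-prefix JSON
manifest (``analysis.json``) declaring the parameters the script exposes,
and optionally an icon image (``analysis.png``). The manifest's typed
parameter list is enough to generate a user interface automatically — here,
headlessly, an abstract widget model and a command-line argument schema.

The type system has exactly 15 tokens (int, double, boolean, string,
string-items, filename, color, range-int, range-double, column,
column-numerical, multi-column, multi-column-numerical, output-column,
output-table). Each maps to a fixed widget kind; ``column-numerical`` and
``multi-column-numerical`` restrict the choices to numeric columns of the
input table. A parameter that declares no type is a string.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from .errors import ManifestError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

PARAM_TYPES = (
    "int",
    "double",
    "boolean",
    "string",
    "string-items",
    "filename",
    "color",
    "range-int",
    "range-double",
    "column",
    "column-numerical",
    "multi-column",
    "multi-column-numerical",
    "output-column",
    "output-table",
)

# "ouput-column" appears in the wild as a misspelling of output-column;
# accepted on input, canonicalized on output.
_TYPE_ALIASES = {"ouput-column": "output-column"}

NUMERIC_TYPES = ("int", "double")
RANGE_TYPES = ("range-int", "range-double")
COLUMN_TYPES = ("column", "column-numerical", "multi-column", "multi-column-numerical")
OUTPUT_TYPES = ("output-column", "output-table")

WIDGET_KINDS = {
    "int": "numeric-spinner",
    "double": "numeric-spinner",
    "boolean": "checkbox",
    "string": "text-field",
    "string-items": "combo-box",
    "filename": "file-dialog",
    "color": "color-chooser",
    "range-int": "range-slider",
    "range-double": "range-slider",
    "column": "combo-box",
    "column-numerical": "combo-box",
    "multi-column": "list-select",
    "multi-column-numerical": "list-select",
    "output-column": "output-name-field",
    "output-table": "output-name-field",
}

NAMED_COLORS = {
    "black", "white", "red", "green", "blue", "yellow", "cyan", "magenta",
    "gray", "grey", "orange", "purple", "brown", "pink", "darkred",
    "darkgreen", "darkblue", "lightgray", "lightgrey",
}


def canonical_type(token: str) -> str:
    """Resolve a manifest type token, accepting the documented alias."""
    token = _TYPE_ALIASES.get(token, token)
    if token not in PARAM_TYPES:
        raise ManifestError(
            f"unknown type token {token!r}; legal tokens: {', '.join(PARAM_TYPES)}"
        )
    return token


def default_label(variable_name: str) -> str:
    """Generate a display label from a variable name.

    The ``input`` prefix is removed and remaining underscores become
    spaces: ``input_log`` -> ``log``, ``my_column_sum`` -> ``my column sum``.
    Applied only when the manifest declares no label.
    """
    if not variable_name:
        raise ValueError("variable name must be non-empty")
    name = variable_name
    if name.startswith("input_"):
        name = name[len("input_"):]
    elif name == "input":
        name = ""
    return name.replace("_", " ").strip()


@dataclass
class ParamSpec:
    """One typed parameter of an app manifest."""

    variable_name: str
    type: str = "string"
    label: str | None = None
    info: str | None = None
    default: Any = None
    min: float | None = None
    max: float | None = None
    items: list[str] | None = None
    ui_hint: str | None = None  # "load" | "save", filename params only
    category: str | None = None

    def __post_init__(self):
        self.type = canonical_type(self.type)
        if self.items is not None and self.default is not None:
            if self.default not in self.items:
                raise ManifestError(
                    f"parameter {self.variable_name!r}: default {self.default!r}"
                    f" is not one of its items"
                )
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ManifestError(
                f"parameter {self.variable_name!r}: min > max"
            )
        if self.ui_hint is not None and self.ui_hint not in ("load", "save"):
            raise ManifestError(
                f"parameter {self.variable_name!r}: ui hint must be 'load' or 'save'"
            )

    @property
    def is_output(self) -> bool:
        return self.type in OUTPUT_TYPES

    @property
    def required(self) -> bool:
        """Input parameters with no default must be bound before a run."""
        return self.default is None and not self.is_output

    @property
    def resolved_label(self) -> str:
        return self.label if self.label is not None else default_label(self.variable_name)


@dataclass
class CategorySpec:
    name: str
    collapsed: bool = False  # expanded by default


@dataclass
class AppSpec:
    """A parsed app manifest plus its on-disk references."""

    app_name: str
    script_ref: str
    params: list[ParamSpec] = field(default_factory=list)
    categories: list[CategorySpec] = field(default_factory=list)
    icon_ref: str | None = None

    def __post_init__(self):
        names = [p.variable_name for p in self.params]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ManifestError(f"duplicate parameter names: {sorted(dupes)}")

    def param(self, name: str) -> ParamSpec:
        for p in self.params:
            if p.variable_name == name:
                return p
        raise KeyError(name)

    @property
    def required_params(self) -> list[ParamSpec]:
        return [p for p in self.params if p.required]

    @property
    def output_params(self) -> list[ParamSpec]:
        return [p for p in self.params if p.is_output]


@dataclass
class WidgetModel:
    """Abstract interface element for one parameter."""

    variable_name: str
    widget_kind: str
    resolved_label: str
    choices: list[str] = field(default_factory=list)
    bounds: tuple[float, float] | None = None
    default: Any = None
    info: str | None = None
    category: str | None = None


# ---------------------------------------------------------------------------
# Parsing and serialization

_PARAM_KEYS = {"name", "type", "label", "info", "default", "min", "max",
               "items", "ui", "category"}


def _parse_param(name: str, body: Any) -> ParamSpec:
    if isinstance(body, str):  # shorthand: "input_x": "column-numerical"
        body = {"type": body}
    if not isinstance(body, Mapping):
        raise ManifestError(f"parameter {name!r}: entry must be an object or type string")
    unknown = set(body) - _PARAM_KEYS
    if unknown:
        raise ManifestError(f"parameter {name!r}: unknown keys {sorted(unknown)}")
    items = body.get("items")
    if items is not None:
        items = [str(x) for x in items]
    try:
        return ParamSpec(
            variable_name=name,
            type=body.get("type", "string"),
            label=body.get("label"),
            info=body.get("info"),
            default=body.get("default"),
            min=body.get("min"),
            max=body.get("max"),
            items=items,
            ui_hint=body.get("ui"),
            category=body.get("category"),
        )
    except ManifestError:
        raise
    except Exception as exc:  # defensive: any constructor failure names the param
        raise ManifestError(f"parameter {name!r}: {exc}") from exc


def parse_app_spec(manifest_text: str, app_name: str, script_ref: str) -> AppSpec:
    """Parse a JSON manifest into an :class:`AppSpec`.

    ``params`` may be an ordered object mapping names to parameter entries,
    or a list of entries each carrying a ``name`` key; order is preserved
    either way. Malformed JSON raises a :class:`ManifestError` naming the
    offending line.
    """
    try:
        doc = json.loads(manifest_text)
    except json.JSONDecodeError as exc:
        raise ManifestError(f"malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(doc, Mapping):
        raise ManifestError("manifest root must be a JSON object")

    raw_params = doc.get("params", {})
    params: list[ParamSpec] = []
    if isinstance(raw_params, Mapping):
        for name, body in raw_params.items():
            params.append(_parse_param(str(name), body))
    elif isinstance(raw_params, Sequence):
        for body in raw_params:
            if not isinstance(body, Mapping) or "name" not in body:
                raise ManifestError("list-form parameter entries need a 'name' key")
            params.append(_parse_param(str(body["name"]), body))
    else:
        raise ManifestError("'params' must be an object or a list")

    categories: list[CategorySpec] = []
    for entry in doc.get("categories", []):
        if isinstance(entry, str):
            categories.append(CategorySpec(entry))
        elif isinstance(entry, Mapping):
            categories.append(
                CategorySpec(str(entry["name"]), bool(entry.get("collapsed", False)))
            )
        else:
            raise ManifestError("category entries must be strings or objects")

    return AppSpec(app_name=app_name, script_ref=script_ref,
                   params=params, categories=categories)


def serialize_app_spec(spec: AppSpec) -> str:
    """Render an AppSpec back to manifest JSON (round-trips via parse)."""
    params: dict[str, dict] = {}
    for p in spec.params:
        body: dict[str, Any] = {"type": p.type}
        if p.label is not None:
            body["label"] = p.label
        if p.info is not None:
            body["info"] = p.info
        if p.default is not None:
            body["default"] = p.default
        if p.min is not None:
            body["min"] = p.min
        if p.max is not None:
            body["max"] = p.max
        if p.items is not None:
            body["items"] = p.items
        if p.ui_hint is not None:
            body["ui"] = p.ui_hint
        if p.category is not None:
            body["category"] = p.category
        params[p.variable_name] = body
    doc: dict[str, Any] = {"params": params}
    if spec.categories:
        doc["categories"] = [
            {"name": c.name, "collapsed": c.collapsed} for c in spec.categories
        ]
    return json.dumps(doc, indent=2)


# ---------------------------------------------------------------------------
# Discovery


def discover_apps(directory, script_ext: str = ".R") -> list[AppSpec]:
    """Scan a directory for app bundles (script + same-prefix manifest).

    Bundles are returned in lexicographic order of their name prefix, so the
    result is invariant under directory-listing order. A script without a
    manifest is not an app; a malformed manifest skips that single bundle
    with a logged warning rather than failing the scan. ``icon_ref`` is set
    when a same-prefix ``.png`` exists.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise OSError(f"not a readable directory: {directory}")
    specs: list[AppSpec] = []
    for script in sorted(directory.glob(f"*{script_ext}")):
        prefix = script.name[: -len(script_ext)]
        manifest = directory / f"{prefix}.json"
        if not manifest.is_file():
            continue
        try:
            spec = parse_app_spec(
                manifest.read_text(encoding="utf-8"), prefix, str(script)
            )
        except ManifestError as exc:
            logger.warning("skipping app %r: %s", prefix, exc)
            continue
        icon = directory / f"{prefix}.png"
        spec.icon_ref = str(icon) if icon.is_file() else None
        specs.append(spec)
    return specs


# ---------------------------------------------------------------------------
# Value validation


def _schema_columns(schema) -> tuple[list[str], list[str]]:
    """(all columns, numeric columns) from a Table or a name->is_numeric map."""
    if hasattr(schema, "numeric_columns"):
        return list(schema.columns), list(schema.numeric_columns())
    cols = list(schema)
    return cols, [c for c in cols if schema[c]]


def _check_bounds(spec: ParamSpec, x: float) -> None:
    if spec.min is not None and x < spec.min:
        raise ValidationError(
            f"{spec.variable_name}: value {x} below minimum {spec.min}"
        )
    if spec.max is not None and x > spec.max:
        raise ValidationError(
            f"{spec.variable_name}: value {x} above maximum {spec.max}"
        )


def _check_color(spec: ParamSpec, text: str) -> str:
    if text.startswith("#"):
        body = text[1:]
        if len(body) == 6 and all(c in "0123456789abcdefABCDEF" for c in body):
            return text
        raise ValidationError(f"{spec.variable_name}: bad hex color {text!r}")
    if text.lower() in NAMED_COLORS:
        return text
    raise ValidationError(f"{spec.variable_name}: unknown color {text!r}")


def _as_bool(spec: ParamSpec, value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str) and value.lower() in ("true", "false"):
        return value.lower() == "true"
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    raise ValidationError(f"{spec.variable_name}: not a boolean: {value!r}")


def validate_value(spec: ParamSpec, value, schema=None):
    """Check and normalize a value against a parameter's declared type.

    Column-typed parameters require a ``schema`` (a Table, or a mapping
    column name -> is-numeric flag); the numerical variants accept only
    numeric columns.
    """
    t = spec.type
    if t == "int":
        try:
            x = int(value)
        except (TypeError, ValueError):
            raise ValidationError(f"{spec.variable_name}: not an integer: {value!r}")
        if isinstance(value, float) and value != x:
            raise ValidationError(f"{spec.variable_name}: not an integer: {value!r}")
        _check_bounds(spec, x)
        return x
    if t == "double":
        try:
            x = float(value)
        except (TypeError, ValueError):
            raise ValidationError(f"{spec.variable_name}: not a number: {value!r}")
        _check_bounds(spec, x)
        return x
    if t == "boolean":
        return _as_bool(spec, value)
    if t in ("string", "filename") or t in OUTPUT_TYPES:
        return str(value)
    if t == "color":
        return _check_color(spec, str(value))
    if t == "string-items":
        text = str(value)
        if spec.items is not None and text not in spec.items:
            raise ValidationError(
                f"{spec.variable_name}: {text!r} is not one of {spec.items}"
            )
        return text
    if t in RANGE_TYPES:
        try:
            lo, hi = value
        except (TypeError, ValueError):
            raise ValidationError(
                f"{spec.variable_name}: range value needs exactly two numbers"
            )
        cast = int if t == "range-int" else float
        try:
            lo, hi = cast(lo), cast(hi)
        except (TypeError, ValueError):
            raise ValidationError(f"{spec.variable_name}: non-numeric range endpoint")
        if lo > hi:
            raise ValidationError(f"{spec.variable_name}: range low > high")
        _check_bounds(spec, lo)
        _check_bounds(spec, hi)
        return (lo, hi)
    if t in COLUMN_TYPES:
        if schema is None:
            raise ValidationError(
                f"{spec.variable_name}: column parameter requires a table schema"
            )
        cols, numeric = _schema_columns(schema)
        allowed = numeric if t.endswith("numerical") else cols
        if t.startswith("multi-column"):
            names = [str(v) for v in (value if isinstance(value, (list, tuple)) else [value])]
        else:
            names = [str(value)]
        for name in names:
            if name not in cols:
                raise SchemaError(f"{spec.variable_name}: unknown column {name!r}")
            if name not in allowed:
                raise SchemaError(
                    f"{spec.variable_name}: column {name!r} is not numeric"
                )
        return names if t.startswith("multi-column") else names[0]
    raise ManifestError(f"unhandled type {t!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Interface model and CLI schema


def interface_model(spec: AppSpec, schema=None) -> list[WidgetModel]:
    """Build the abstract widget list for an app.

    The widget kind is a pure function of the parameter type. Column-typed
    parameters list the (possibly numeric-only) columns of ``schema`` as
    choices; with no schema the choice list is empty (deferred until a table
    is assigned).
    """
    cols: list[str] = []
    numeric: list[str] = []
    if schema is not None:
        cols, numeric = _schema_columns(schema)
    widgets = []
    for p in spec.params:
        choices: list[str] = []
        if p.type == "string-items":
            choices = list(p.items or [])
        elif p.type in COLUMN_TYPES:
            choices = list(numeric if p.type.endswith("numerical") else cols)
        bounds = None
        if p.min is not None or p.max is not None:
            bounds = (p.min, p.max)
        widgets.append(
            WidgetModel(
                variable_name=p.variable_name,
                widget_kind=WIDGET_KINDS[p.type],
                resolved_label=p.resolved_label,
                choices=choices,
                bounds=bounds,
                default=p.default,
                info=p.info,
                category=p.category,
            )
        )
    return widgets


@dataclass
class CliArg:
    """One command-line flag derived from a parameter."""

    flag: str
    param: ParamSpec
    multiple: bool = False  # repeated flag for multi-column variants
    nargs: int = 1          # 2 for range types
    is_flag: bool = False   # presence flag for booleans
    default: Any = None


def render_cli(spec: AppSpec) -> list[CliArg]:
    """Derive a command-line argument schema from an app manifest.

    Every parameter becomes ``--<variable_name>``; booleans are presence
    flags, range types take two values, multi-column variants may be
    repeated (``--cols A --cols B``).
    """
    args = []
    for p in spec.params:
        args.append(
            CliArg(
                flag=f"--{p.variable_name}",
                param=p,
                multiple=p.type.startswith("multi-column"),
                nargs=2 if p.type in RANGE_TYPES else 1,
                is_flag=p.type == "boolean",
                default=p.default,
            )
        )
    return args
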