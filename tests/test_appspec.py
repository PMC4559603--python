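"""Manifest parsing, the 15-token type system, and interface generation."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tabbench.appspec import (
    PARAM_TYPES,
    WIDGET_KINDS,
    AppSpec,
    ParamSpec,
    default_label,
    discover_apps,
    interface_model,
    parse_app_spec,
    render_cli,
    serialize_app_spec,
    validate_value,
)
from tabbench.errors import ManifestError, SchemaError, ValidationError
from tabbench.fixtures import gen_app_bundle


# ---------------------------------------------------------------------------
# parse_app_spec


class TestParse:
    def test_simpleplot_manifest(self, app_dir):
        spec = next(s for s in discover_apps(app_dir) if s.app_name == "simpleplot")
        assert [p.variable_name for p in spec.params] == [
            "input_x", "input_y", "input_color", "input_log", "input_title",
        ]
        # untyped parameter defaults to string
        assert spec.param("input_title").type == "string"
        assert spec.param("input_x").type == "column-numerical"
        assert spec.param("input_color").type == "column"
        log = spec.param("input_log")
        assert log.items == ["", "x", "y", "xy"] and log.default == ""
        assert [p.variable_name for p in spec.required_params] == [
            "input_x", "input_y",
        ]

    def test_empty_parameter_list(self):
        spec = parse_app_spec('{"params": {}}', "empty", "empty.R")
        assert spec.params == []

    def test_unknown_type_lists_legal_tokens(self):
        text = json.dumps({"params": {"x": {"type": "float"}}})
        with pytest.raises(ManifestError) as err:
            parse_app_spec(text, "bad", "bad.R")
        for token in PARAM_TYPES:
            assert token in str(err.value)

    def test_misspelled_output_column_alias(self):
        text = json.dumps({"params": {"out": {"type": "ouput-column"}}})
        spec = parse_app_spec(text, "a", "a.R")
        assert spec.param("out").type == "output-column"

    def test_malformed_json_names_line(self):
        with pytest.raises(ManifestError, match="line 2"):
            parse_app_spec('{\n"params": }', "a", "a.R")

    def test_duplicate_parameter_names_rejected(self):
        params = [{"name": "x", "type": "int"}, {"name": "x", "type": "double"}]
        with pytest.raises(ManifestError, match="duplicate"):
            parse_app_spec(json.dumps({"params": params}), "a", "a.R")

    def test_default_must_belong_to_items(self):
        text = json.dumps(
            {"params": {"m": {"type": "string-items", "items": ["a"], "default": "z"}}}
        )
        with pytest.raises(ManifestError, match="items"):
            parse_app_spec(text, "a", "a.R")


_ident = st.from_regex(r"[a-z][a-z0-9_]{0,10}", fullmatch=True)


@st.composite
def app_specs(draw):
    n = draw(st.integers(0, 6))
    names = draw(
        st.lists(_ident, min_size=n, max_size=n, unique=True)
    )
    params = []
    for name in names:
        ptype = draw(st.sampled_from(PARAM_TYPES))
        kwargs = {}
        if ptype == "string-items":
            items = draw(st.lists(
                st.text(alphabet="abcxyz", min_size=1, max_size=4),
                min_size=1, max_size=4, unique=True))
            kwargs["items"] = items
            if draw(st.booleans()):
                kwargs["default"] = items[0]
        elif ptype in ("int", "double"):
            if draw(st.booleans()):
                kwargs["min"], kwargs["max"] = 0, 10
                kwargs["default"] = draw(st.integers(0, 10))
        elif ptype == "filename" and draw(st.booleans()):
            kwargs["ui_hint"] = draw(st.sampled_from(["load", "save"]))
        if draw(st.booleans()):
            kwargs["label"] = draw(st.text(alphabet="ab c", max_size=8))
        params.append(ParamSpec(name, ptype, **kwargs))
    return AppSpec("app", "app.R", params)


@settings(max_examples=120, deadline=None)
@given(app_specs())
def test_serialize_parse_round_trip(spec):
    """parse o serialize is the identity on generated app specs."""
    back = parse_app_spec(serialize_app_spec(spec), spec.app_name, spec.script_ref)
    assert [
        (p.variable_name, p.type, p.label, p.default, p.min, p.max, p.items, p.ui_hint)
        for p in back.params
    ] == [
        (p.variable_name, p.type, p.label, p.default, p.min, p.max, p.items, p.ui_hint)
        for p in spec.params
    ]


# ---------------------------------------------------------------------------
# default_label


@pytest.mark.parametrize(
    "name,expected",
    [
        ("input_log", "log"),
        ("my_column_sum", "my column sum"),
        ("x", "x"),
        ("input_two_words", "two words"),
    ],
)
def test_default_label(name, expected):
    assert default_label(name) == expected


@given(_ident)
def test_default_label_clean(name):
    """Labels never keep underscores or leading/trailing spaces."""
    label = default_label(name)
    assert "_" not in label
    assert label == label.strip()


# ---------------------------------------------------------------------------
# discover_apps


class TestDiscover:
    def _write(self, d, name, manifest=True, icon=False, body="x <- 1\n"):
        (d / f"{name}.R").write_text(body)
        if manifest:
            (d / f"{name}.json").write_text('{"params": {}}')
        if icon:
            (d / f"{name}.png").write_text("fake image bytes")

    def test_pair_without_icon(self, tmp_path):
        self._write(tmp_path, "a")
        apps = discover_apps(tmp_path)
        assert len(apps) == 1 and apps[0].icon_ref is None

    def test_script_without_manifest_is_not_an_app(self, tmp_path):
        self._write(tmp_path, "a", manifest=False)
        assert discover_apps(tmp_path) == []

    def test_icon_attached_by_prefix(self, tmp_path):
        self._write(tmp_path, "a", icon=True)
        apps = discover_apps(tmp_path)
        assert apps[0].icon_ref is not None and apps[0].icon_ref.endswith("a.png")

    def test_lexicographic_order(self, tmp_path):
        for name in ("zeta", "alpha", "mid"):
            self._write(tmp_path, name)
        assert [a.app_name for a in discover_apps(tmp_path)] == [
            "alpha", "mid", "zeta",
        ]

    def test_malformed_manifest_skips_single_app(self, tmp_path, caplog):
        self._write(tmp_path, "good")
        (tmp_path / "bad.R").write_text("")
        (tmp_path / "bad.json").write_text("{not json")
        with caplog.at_level("WARNING"):
            apps = discover_apps(tmp_path)
        assert [a.app_name for a in apps] == ["good"]
        assert any("bad" in rec.getMessage() for rec in caplog.records)

    def test_unreadable_directory(self, tmp_path):
        with pytest.raises(OSError):
            discover_apps(tmp_path / "missing")


# ---------------------------------------------------------------------------
# validate_value


class TestValidate:
    def test_string_items_membership(self):
        spec = ParamSpec("input_log", "string-items", items=["", "x", "y", "xy"])
        assert validate_value(spec, "y") == "y"
        with pytest.raises(ValidationError):
            validate_value(spec, "z")

    def test_int_bounds(self):
        spec = ParamSpec("n", "int", min=0, max=10)
        assert validate_value(spec, 7) == 7
        with pytest.raises(ValidationError):
            validate_value(spec, 11)

    def test_numerical_column_rejects_text(self, mixed_table):
        spec = ParamSpec("col", "column-numerical")
        assert validate_value(spec, "score", mixed_table) == "score"
        with pytest.raises(SchemaError):
            validate_value(spec, "gene_name", mixed_table)

    def test_plain_column_accepts_text(self, mixed_table):
        spec = ParamSpec("col", "column")
        assert validate_value(spec, "gene_name", mixed_table) == "gene_name"

    def test_multi_column(self, mixed_table):
        spec = ParamSpec("cols", "multi-column-numerical")
        assert validate_value(spec, ["score"], mixed_table) == ["score"]
        with pytest.raises(SchemaError):
            validate_value(spec, ["score", "gene_name"], mixed_table)

    def test_range_orders_and_bounds(self):
        spec = ParamSpec("r", "range-double", min=0, max=1)
        assert validate_value(spec, (0.1, 0.9)) == (0.1, 0.9)
        with pytest.raises(ValidationError):
            validate_value(spec, (0.9, 0.1))
        with pytest.raises(ValidationError):
            validate_value(spec, (0.1, 1.5))

    def test_color(self):
        spec = ParamSpec("c", "color")
        assert validate_value(spec, "#FF00aa") == "#FF00aa"
        assert validate_value(spec, "red") == "red"
        with pytest.raises(ValidationError):
            validate_value(spec, "#GG0000")


# ---------------------------------------------------------------------------
# interface_model


@pytest.mark.parametrize("ptype", PARAM_TYPES)
def test_widget_mapping_total(ptype):
    """Every type token maps to its fixed widget kind."""
    spec = AppSpec("a", "a.R", [ParamSpec("p", ptype)])
    widget = interface_model(spec)[0]
    assert widget.widget_kind == WIDGET_KINDS[ptype]


def test_widget_kind_examples():
    assert WIDGET_KINDS["range-double"] == "range-slider"
    assert WIDGET_KINDS["boolean"] == "checkbox"


def test_column_choices_from_schema(app_dir, mixed_table):
    spec = next(s for s in discover_apps(app_dir) if s.app_name == "simpleplot")
    widgets = {w.variable_name: w for w in interface_model(spec, mixed_table)}
    # plain column parameter lists every column, numeric or not
    assert widgets["input_color"].choices == ["gene_name", "score"]
    # numerical variant restricts to numeric columns
    assert widgets["input_x"].choices == ["score"]
    # labels resolve through the default rule
    assert widgets["input_log"].resolved_label == "log"


def test_column_choices_deferred_without_schema(app_dir):
    spec = next(s for s in discover_apps(app_dir) if s.app_name == "simpleplot")
    widgets = {w.variable_name: w for w in interface_model(spec)}
    assert widgets["input_color"].choices == []


# ---------------------------------------------------------------------------
# render_cli


def test_render_cli_simpleplot_flags(app_dir):
    spec = next(s for s in discover_apps(app_dir) if s.app_name == "simpleplot")
    assert [a.flag for a in render_cli(spec)] == [
        "--input_x", "--input_y", "--input_color", "--input_log", "--input_title",
    ]


def test_render_cli_empty():
    assert render_cli(AppSpec("a", "a.R")) == []


def test_render_cli_repeated_multi_column_flag():
    from tabbench.cli import parse_app_args

    spec = AppSpec("a", "a.R", [ParamSpec("cols", "multi-column")])
    bindings = parse_app_args(spec, ["--cols", "A", "--cols", "B"])
    assert bindings == {"cols": ["A", "B"]}


def test_render_cli_range_consumes_two_values():
    from tabbench.cli import parse_app_args

    spec = AppSpec("a", "a.R", [ParamSpec("r", "range-double"),
                                ParamSpec("flag", "boolean")])
    bindings = parse_app_args(spec, ["--r", "0.1", "0.9", "--flag"])
    assert bindings == {"r": ("0.1", "0.9"), "flag": True}
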