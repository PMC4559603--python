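"""Script preprocessing, parameter injection, execution, output capture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tabbench.appspec import AppSpec, ParamSpec
from tabbench.backends import Backend, BackendValue, MockBackend
from tabbench.datatable import Table
from tabbench.engine import (
    INPUT_TABLE_NAME,
    collect_outputs,
    encode_binding,
    preprocess_script,
    run_program,
)
from tabbench.errors import BackendError, OutputError, ShapeError, StructureError


# ---------------------------------------------------------------------------
# preprocess_script


class TestPreprocess:
    def test_plain_lines_inject_before_first(self):
        program = preprocess_script("a\nb\nc")
        assert [u.code for u in program.units] == ["a", "b", "c"]
        assert program.inject_index == 0

    def test_directive_sets_injection_point_and_emits_no_unit(self):
        program = preprocess_script("pre\n###applyParameters\npost")
        assert [u.code for u in program.units] == ["pre", "post"]
        assert program.inject_index == 1

    def test_block_is_one_unit_with_line_span(self):
        program = preprocess_script("{{\nx <- 1\ny <- 2\n}}")
        assert len(program.units) == 1
        unit = program.units[0]
        assert unit.kind == "block"
        assert unit.code == "x <- 1\ny <- 2"
        assert unit.line_span == (2, 3)

    def test_unclosed_block_names_line(self):
        with pytest.raises(StructureError, match="line 2"):
            preprocess_script("a\n{{\nx <- 1")

    def test_nested_block_rejected(self):
        with pytest.raises(StructureError, match="nested"):
            preprocess_script("{{\n{{\n}}")

    def test_stray_close_rejected(self):
        with pytest.raises(StructureError):
            preprocess_script("a\n}}")

    def test_repeated_directive_rejected(self):
        with pytest.raises(StructureError, match="repeated"):
            preprocess_script("###applyParameters\nx\n###applyParameters")

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.text(alphabet="abc <-123.", max_size=20), max_size=10))
    def test_lossless_on_marker_free_scripts(self, lines):
        """Unit concatenation reproduces a script with no markers."""
        lines = [
            ln for ln in lines
            if ln.strip() not in ("{{", "}}")
            and not ln.strip().startswith("###applyParameters")
        ]
        text = "\n".join(lines)
        program = preprocess_script(text)
        # lossless up to a trailing newline (scripts are line sequences)
        assert "\n".join(u.code for u in program.units) == "\n".join(text.splitlines())


# ---------------------------------------------------------------------------
# encode_binding


class TestEncodeBinding:
    def test_int_scalar(self):
        v = encode_binding(ParamSpec("n", "int"), 5)
        assert (v.kind, v.value) == ("integer", 5)

    def test_range_double_vector(self):
        v = encode_binding(ParamSpec("r", "range-double"), (0.1, 0.9))
        assert v.kind == "vector" and v.value == [0.1, 0.9]

    def test_multi_column_tabular(self, expr_table):
        v = encode_binding(
            ParamSpec("cols", "multi-column"), ["sample_0", "sample_1"], expr_table
        )
        assert v.kind == "table"
        assert list(v.value.columns) == ["sample_0", "sample_1"]
        assert len(v.value) == expr_table.n

    def test_output_destination_text(self):
        v = encode_binding(ParamSpec("out", "output-column"), "cluster_id")
        assert (v.kind, v.value) == ("character", "cluster_id")

    def test_boolean_logical(self):
        assert encode_binding(ParamSpec("b", "boolean"), True).kind == "logical"


# ---------------------------------------------------------------------------
# execution helpers


def _spec(params, script="unused"):
    return AppSpec("app", script, params)


def run(script_text, spec, table, bindings, backend, cancel=None):
    program = preprocess_script(script_text)
    return run_program(spec, program, table, bindings, backend, cancel)


class RecordingBackend(MockBackend):
    """Mock that records the order of set/evaluate calls."""

    def __init__(self, **kw):
        super().__init__(**kw)
        self.events = []

    def set_value(self, name, value):
        self.events.append(("set", name))
        super().set_value(name, value)

    def evaluate(self, code):
        self.events.append(("eval", code))
        return super().evaluate(code)


# ---------------------------------------------------------------------------
# run_program


class TestRun:
    def test_binding_reaches_session(self):
        backend = MockBackend()
        spec = _spec([ParamSpec("input_n", "int")])
        result = run("x <- input_n", spec, None, {"input_n": 3}, backend)
        assert result.status == "ok"
        assert backend.fetch("x") == 3

    def test_injection_order_and_uniqueness(self, expr_table):
        backend = RecordingBackend()
        spec = _spec([ParamSpec("input_n", "int")])
        run("pre <- 1\n###applyParameters\npost <- 2", spec, expr_table,
            {"input_n": 3}, backend)
        kinds = [k for k, _ in backend.events]
        # unit, then the injection block (table + params), then unit
        assert kinds == ["eval", "set", "set", "eval"]
        assert backend.events[1] == ("set", INPUT_TABLE_NAME)
        assert backend.events[2] == ("set", "input_n")

    def test_default_injection_before_first_unit(self, expr_table):
        backend = RecordingBackend()
        run("a <- 1", _spec([]), expr_table, {}, backend)
        assert [k for k, _ in backend.events] == ["set", "eval"]

    def test_output_column_collected_under_destination(self, expr_table):
        backend = MockBackend()
        spec = _spec([ParamSpec("output_cluster", "output-column")])
        script = f"output_cluster <- [0] * nrow({INPUT_TABLE_NAME})"
        result = run(script, spec, expr_table,
                     {"output_cluster": "kmeans_id"}, backend)
        assert result.status == "ok"
        assert set(result.outputs) == {"kmeans_id"}
        assert len(result.outputs["kmeans_id"]) == expr_table.n

    def test_cancel_after_first_unit(self):
        backend = MockBackend()
        calls = {"n": 0}

        def cancel():
            calls["n"] += 1
            return calls["n"] >= 1  # signalled after the first unit

        result = run("a <- 1\nb <- 2\nc <- 3", _spec([]), None, {}, backend, cancel)
        assert result.status == "cancelled"
        assert result.outputs == {}
        assert len(result.transcript) == 1

    def test_error_keeps_transcript_and_drops_outputs(self):
        backend = MockBackend()
        spec = _spec([ParamSpec("output_x", "output-column")])
        script = 'a <- 1\nfail("kaput")\nc <- 3'
        result = run(script, spec, None, {"output_x": "x"}, backend)
        assert result.status == "error"
        assert result.outputs == {}
        assert "kaput" in result.transcript[-1]  # error text kept verbatim
        assert len(result.transcript) == 2  # up to and including the failing unit

    def test_deterministic_replay(self, expr_table):
        spec = _spec([ParamSpec("input_n", "int")])
        script = "x <- input_n\nx\nx * 2"
        r1 = run(script, spec, expr_table, {"input_n": 4}, MockBackend())
        r2 = run(script, spec, expr_table, {"input_n": 4}, MockBackend())
        assert r1.transcript == r2.transcript
        assert r1.status == r2.status == "ok"

    def test_required_unbound_parameter_rejected(self, tmp_path):
        from tabbench.engine import run_app

        script = tmp_path / "a.R"
        script.write_text("x <- 1\n")
        spec = _spec([ParamSpec("input_n", "int")], str(script))
        from tabbench.errors import ValidationError

        with pytest.raises(ValidationError, match="input_n"):
            run_app(spec, None, {}, MockBackend())


# ---------------------------------------------------------------------------
# collect_outputs


class TestCollectOutputs:
    def test_output_table_payload(self):
        backend = MockBackend()
        backend.env["output_corr"] = pd.DataFrame(np.eye(10))
        spec = _spec([ParamSpec("output_corr", "output-table")])
        outputs = collect_outputs(spec, {"output_corr": "corr"}, backend)
        assert outputs["corr"].shape == (10, 10)

    def test_blank_destination_skipped(self):
        backend = MockBackend()
        backend.env["output_x"] = [1, 2, 3]
        spec = _spec([ParamSpec("output_x", "output-column")])
        assert collect_outputs(spec, {"output_x": ""}, backend) == {}
        assert collect_outputs(spec, {}, backend) == {}

    def test_missing_backend_variable_names_parameter(self):
        spec = _spec([ParamSpec("output_x", "output-column")])
        with pytest.raises(OutputError, match="output_x"):
            collect_outputs(spec, {"output_x": "dest"}, MockBackend())

    def test_column_length_mismatch(self):
        backend = MockBackend()
        backend.env["output_x"] = [1, 2, 3]
        spec = _spec([ParamSpec("output_x", "output-column")])
        with pytest.raises(ShapeError):
            collect_outputs(spec, {"output_x": "dest"}, backend, n_rows=5)

    def test_file_output_via_save_filename(self):
        spec = _spec([ParamSpec("input_file", "filename", ui_hint="save")])
        outputs = collect_outputs(spec, {"input_file": "/tmp/out.csv"}, MockBackend())
        assert outputs == {"/tmp/out.csv": "/tmp/out.csv"}


# ---------------------------------------------------------------------------
# backend contract (mock)


class TestMockBackend:
    @pytest.mark.parametrize(
        "value",
        [
            BackendValue("integer", 5),
            BackendValue("numeric", 2.5),
            BackendValue("logical", True),
            BackendValue("character", "hi"),
            BackendValue("vector", [0.1, 0.9]),
        ],
    )
    def test_set_then_fetch_round_trip(self, value):
        backend = MockBackend()
        backend.set_value("v", value)
        fetched = backend.fetch("v")
        if value.kind == "vector":
            assert list(fetched) == list(value.value)
        else:
            assert fetched == value.value

    def test_table_round_trip(self, expr_table):
        backend = MockBackend()
        backend.set_value("t", BackendValue("table", expr_table.df))
        pd.testing.assert_frame_equal(backend.fetch("t"), expr_table.df)

    def test_strict_mode_raises_on_unknown_line(self):
        with pytest.raises(BackendError):
            MockBackend(strict=True).evaluate("library(DESeq)")

    def test_lenient_mode_echoes_unknown_line(self):
        out = MockBackend().evaluate("library(DESeq)")
        assert "library(DESeq)" in out

    def test_bare_expression_is_printed(self):
        backend = MockBackend()
        backend.evaluate("x <- 6")
        assert backend.evaluate("x * 7") == "42"
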