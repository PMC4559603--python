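"""Formula parsing, precedence, and row-wise evaluation.

The random-formula test compares the vectorized evaluator against an
independent scalar tree-walk interpreter defined here: the oracle descends
the AST once per row with plain Python floats, so any vectorization bug in
the evaluator cannot also live in the oracle.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tabbench.datatable import Table
from tabbench.errors import FormulaError, SchemaError
from tabbench.formula import (
    BinOp,
    Func,
    Num,
    Ref,
    Unary,
    calculate,
    evaluate_formula,
    parse_formula,
    referenced_columns,
    serialize_formula,
)


# ---------------------------------------------------------------------------
# parsing


class TestParse:
    def test_precedence_multiplication_over_addition(self):
        ast = parse_formula("=A+B*C")
        assert isinstance(ast, BinOp) and ast.op == "+"
        assert isinstance(ast.right, BinOp) and ast.right.op == "*"

    def test_if_has_arity_three(self):
        ast = parse_formula("=IF(A>1, 1, 0)")
        assert isinstance(ast, Func) and ast.name == "IF" and len(ast.args) == 3

    def test_bracketed_reference_with_space(self):
        ast = parse_formula("=LOG2([read count]+1)")
        assert referenced_columns(ast) == ["read count"]

    def test_power_right_associative(self):
        ast = parse_formula("2^3^2")
        assert ast.op == "^" and isinstance(ast.right, BinOp)

    def test_power_binds_tighter_than_unary_minus(self):
        t = Table.from_dict({"z": [0.0]})
        assert calculate(t, "=-2^2")[0] == -4.0

    def test_comparisons_lowest_precedence(self):
        ast = parse_formula("A+1 > B*2")
        assert ast.op == ">"

    def test_function_names_case_insensitive(self):
        assert parse_formula("log2(8)") == parse_formula("LOG2(8)")

    @pytest.mark.parametrize(
        "bad", ["=FOO(1)", "=(A+B", "=IF(1,2)", "=A+", "=1 2", "", "="]
    )
    def test_parse_errors(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_error_carries_position(self):
        with pytest.raises(FormulaError) as err:
            parse_formula("=A+BAD(1)")
        assert err.value.position == 2


# ---------------------------------------------------------------------------
# evaluation examples


class TestEvaluate:
    def test_addition(self):
        t = Table.from_dict({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        assert calculate(t, "=A+B").tolist() == [4.0, 6.0]

    def test_log2_closed_form(self):
        t = Table.from_dict({"C": [8.0, 1.0]})
        assert calculate(t, "=LOG2(C)").tolist() == [3.0, 0.0]

    def test_identity_on_column(self):
        t = Table.from_dict({"X": [1.5, -2.0, 7.0]})
        assert calculate(t, "=X").tolist() == [1.5, -2.0, 7.0]

    def test_division_by_zero_is_missing(self):
        t = Table.from_dict({"A": [1.0, 2.0], "B": [0.0, 2.0]})
        out = calculate(t, "=A/B")
        assert np.isnan(out[0]) and out[1] == 1.0

    def test_log_of_nonpositive_is_missing(self):
        t = Table.from_dict({"A": [-1.0, 0.0, 10.0]})
        out = calculate(t, "=LOG10(A)")
        assert np.isnan(out[0]) and np.isnan(out[1]) and out[2] == 1.0

    def test_sqrt_of_negative_is_missing(self):
        out = calculate(Table.from_dict({"A": [-4.0, 4.0]}), "=SQRT(A)")
        assert np.isnan(out[0]) and out[1] == 2.0

    def test_missing_propagates(self):
        t = Table.from_dict({"A": [np.nan, 1.0], "B": [1.0, 1.0]})
        out = calculate(t, "=A+B")
        assert np.isnan(out[0]) and out[1] == 2.0

    def test_comparison_yields_indicator(self):
        t = Table.from_dict({"A": [0.5, 2.0]})
        assert calculate(t, "=A>1").tolist() == [0.0, 1.0]

    def test_row_wise_aggregates_across_arguments(self):
        t = Table.from_dict({"A": [1.0, 5.0], "B": [3.0, 2.0]})
        assert calculate(t, "=MAX(A,B)").tolist() == [3.0, 5.0]
        assert calculate(t, "=MEAN(A,B,2)").tolist() == [2.0, 3.0]

    def test_if_and_text_equality(self):
        t = Table.from_dict({"name": ["wt", "ko"], "v": [1.0, 2.0]})
        assert calculate(t, '=IF(name="ko", v, 0)').tolist() == [0.0, 2.0]

    def test_fold_change_labeling(self):
        # the +1 / -1 / 0 differential-label convention as a formula
        t = Table.from_dict({"ko": [8.0, 1.0, 2.0], "wt": [1.0, 8.0, 2.0]})
        labels = calculate(
            t, "=IF(LOG2(ko+1)-LOG2(wt+1)>=1, 1, IF(LOG2(ko+1)-LOG2(wt+1)<=-1, -1, 0))"
        )
        assert labels.tolist() == [1.0, -1.0, 0.0]

    def test_unknown_column_schema_error_before_evaluation(self):
        with pytest.raises(SchemaError, match="nope"):
            calculate(Table.from_dict({"A": [1.0]}), "=A+nope")

    def test_result_length_matches_rows_for_constants(self):
        t = Table.from_dict({"A": [1.0, 2.0, 3.0]})
        assert calculate(t, "=1+1").tolist() == [2.0, 2.0, 2.0]


# ---------------------------------------------------------------------------
# random formulas vs independent tree-walk oracle


def _oracle_eval(node, row):
    """Scalar recursive interpreter; NaN models the missing value."""
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Ref):
        return row[node.name]
    if isinstance(node, Unary):
        return -_oracle_eval(node.operand, row)
    if isinstance(node, BinOp):
        a = _oracle_eval(node.left, row)
        b = _oracle_eval(node.right, row)
        if node.op == "+":
            return a + b
        if node.op == "-":
            return a - b
        if node.op == "*":
            return a * b
        if node.op == "/":
            return float("nan") if b == 0 else a / b
        if node.op == "^":
            try:
                out = a ** b
            except (OverflowError, ZeroDivisionError, ValueError):
                return float("nan")
            if isinstance(out, complex) or math.isinf(out):
                return float("nan")
            return out
        if math.isnan(a) or math.isnan(b):
            return float("nan")
        return float(
            {"=": a == b, "<>": a != b, "<": a < b,
             "<=": a <= b, ">": a > b, ">=": a >= b}[node.op]
        )
    if isinstance(node, Func):
        args = [_oracle_eval(a, row) for a in node.args]
        name = node.name
        if name == "IF":
            if math.isnan(args[0]):
                return float("nan")
            return args[1] if args[0] != 0 else args[2]
        if name == "ABS":
            return abs(args[0])
        if name == "SQRT":
            return math.sqrt(args[0]) if args[0] >= 0 else float("nan")
        if name == "EXP":
            try:
                return math.exp(args[0])
            except OverflowError:
                return float("inf")
        if name in ("LOG", "LOG2", "LOG10"):
            x = args[0]
            if math.isnan(x) or x <= 0:
                return float("nan")
            base = {"LOG": 10.0, "LOG2": 2.0, "LOG10": 10.0}[name]
            if name == "LOG" and len(args) == 2:
                base = args[1]
            return math.log(x) / math.log(base)
        if name == "ROUND":
            digits = int(args[1]) if len(args) == 2 else 0
            scale = 10.0 ** digits
            x = args[0]
            if math.isnan(x):
                return float("nan")
            return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale
        if name == "MIN":
            return float("nan") if any(math.isnan(a) for a in args) else min(args)
        if name == "MAX":
            return float("nan") if any(math.isnan(a) for a in args) else max(args)
        if name == "SUM":
            return sum(args)
        if name == "MEAN":
            return sum(args) / len(args)
        if any(math.isnan(a) for a in args):
            return float("nan")
        if name == "AND":
            return float(all(a != 0 for a in args))
        if name == "OR":
            return float(any(a != 0 for a in args))
        if name == "NOT":
            return float(args[0] == 0)
    raise AssertionError(f"oracle cannot handle {node!r}")


def _random_ast(rng, columns, depth=0):
    choice = rng.random()
    if depth >= 3 or choice < 0.25:
        if rng.random() < 0.5:
            return Num(float(np.round(rng.uniform(-5, 5), 3)))
        return Ref(str(rng.choice(columns)))
    if choice < 0.65:
        op = str(rng.choice(["+", "-", "*", "/", "^", "<", "<=", ">", ">=", "=", "<>"]))
        left = _random_ast(rng, columns, depth + 1)
        right = _random_ast(rng, columns, depth + 1)
        if op == "^":  # keep exponent small and integral: real-valued powers
            right = Num(float(rng.integers(0, 3)))
        return BinOp(op, left, right)
    if choice < 0.72:
        return Unary("-", _random_ast(rng, columns, depth + 1))
    name = str(
        rng.choice(
            ["ABS", "SQRT", "EXP", "LOG2", "LOG10", "MIN", "MAX",
             "MEAN", "SUM", "IF", "AND", "OR", "NOT", "ROUND"]
        )
    )
    arity = {"IF": 3, "NOT": 1, "ABS": 1, "SQRT": 1, "EXP": 1,
             "LOG2": 1, "LOG10": 1, "ROUND": 1}.get(name, int(rng.integers(1, 4)))
    return Func(name, tuple(_random_ast(rng, columns, depth + 1) for _ in range(arity)))


def test_random_formulas_match_tree_walk_oracle(rng):
    """200 random formulas over random tables: vectorized == per-row oracle."""
    columns = ["a", "b", "c"]
    n = 17
    for trial in range(200):
        df = {c: np.round(rng.uniform(-10, 10, n), 3) for c in columns}
        df["a"][0] = np.nan  # make sure missing values flow through
        table = Table.from_dict(df)
        ast = _random_ast(rng, columns)
        result = evaluate_formula(ast, table)
        assert len(result) == n
        for i in range(n):
            row = {c: float(df[c][i]) for c in columns}
            expected = _oracle_eval(ast, row)
            got = float(result[i])
            if math.isnan(expected) or math.isinf(expected):
                assert math.isnan(got) or got == expected, (trial, i, ast)
            else:
                assert got == pytest.approx(expected, rel=1e-9, abs=1e-9), (
                    trial, i, serialize_formula(ast),
                )


@settings(max_examples=150, deadline=None)
@given(st.data())
def test_serialize_round_trip_preserves_semantics(data):
    """evaluate(parse(serialize(ast))) == evaluate(ast)."""
    seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    ast = _random_ast(rng, ["a", "b"])
    back = parse_formula(serialize_formula(ast))
    table = Table.from_dict(
        {"a": np.round(rng.uniform(-5, 5, 7), 3), "b": np.round(rng.uniform(-5, 5, 7), 3)}
    )
    np.testing.assert_array_equal(
        evaluate_formula(ast, table), evaluate_formula(back, table)
    )
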