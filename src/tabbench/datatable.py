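"""Core tabular data model: tables, sorting, filters, and histogram math.

A :class:`Table` is an ordered collection of named, equal-length columns
(numeric, text, or logical), the shared currency of every other module. On
top of it this module implements the interactive-analysis primitives:

* stable sorting with missing values last,
* one-dimensional range filters with equal-width / equal-count segmentation,
* two-dimensional region filters (rectangle, quad, polygon) with an
  even-odd interior rule and inclusive boundaries,
* histogram binning with log / CDF / percentage transforms.

A single interval convention is used throughout: half-open ``[low, high)``
with the maximum boundary closed, so a value never falls in two segments or
two bins and the extremes are never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateShapeError,
    EmptyDomainError,
    SchemaError,
    ShapeError,
)

ColumnKind = Literal["data", "calculated", "output"]


@dataclass
class Column:
    """A named column with provenance.

    ``kind`` records where the values came from: ``data`` columns are loaded
    or computed from sequencing data, ``calculated`` columns are derived from
    a stored formula (and re-derivable from it), ``output`` columns were
    written by an app run.
    """

    name: str
    kind: ColumnKind = "data"
    formula: str | None = None  # set iff kind == "calculated"


class Table:
    """Ordered named columns over ``n`` rows, backed by a pandas DataFrame.

    Column metadata (kind, source formula) lives beside the frame so that
    calculated columns can be re-derived when the underlying data changes.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        self.df = pd.DataFrame() if df is None else df.reset_index(drop=True)
        self.meta: dict[str, Column] = {
            name: Column(name) for name in self.df.columns
        }

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict[str, Sequence]) -> "Table":
        return cls(pd.DataFrame(data))

    @classmethod
    def read_csv(cls, path) -> "Table":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def copy(self) -> "Table":
        t = Table(self.df.copy())
        t.meta = {k: Column(v.name, v.kind, v.formula) for k, v in self.meta.items()}
        return t

    # -- basic protocol ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def __len__(self) -> int:
        return self.n

    def __contains__(self, name: str) -> bool:
        return name in self.df.columns

    def is_numeric(self, name: str) -> bool:
        self._require(name)
        return pd.api.types.is_numeric_dtype(self.df[name])

    def numeric_columns(self) -> list[str]:
        return [c for c in self.df.columns if self.is_numeric(c)]

    def column_values(self, name: str) -> np.ndarray:
        self._require(name)
        return self.df[name].to_numpy()

    def _require(self, name: str) -> None:
        if name not in self.df.columns:
            raise SchemaError(f"unknown column {name!r}")

    # -- mutation ----------------------------------------------------------

    def set_column(
        self,
        name: str,
        values: Sequence,
        kind: ColumnKind = "data",
        formula: str | None = None,
    ) -> bool:
        """Create or overwrite a column. Returns True if it was created."""
        values = np.asarray(values)
        if len(self.df.columns) and len(values) != self.n:
            raise ShapeError(
                f"column {name!r} has length {len(values)}, table has {self.n} rows"
            )
        created = name not in self.df.columns
        self.df[name] = values
        self.meta[name] = Column(name, kind, formula)
        return created

    def set_calculated(self, name: str, formula_text: str) -> bool:
        """Attach a formula-derived column; evaluated now, re-derivable later."""
        from . import formula as _formula

        ast = _formula.parse_formula(formula_text)
        values = _formula.evaluate_formula(ast, self)
        return self.set_column(name, values, kind="calculated", formula=formula_text)

    def recompute_calculated(self) -> None:
        """Re-derive every calculated column from its stored formula."""
        from . import formula as _formula

        for col in list(self.meta.values()):
            if col.kind == "calculated" and col.formula is not None:
                ast = _formula.parse_formula(col.formula)
                self.df[col.name] = _formula.evaluate_formula(ast, self)

    def drop_column(self, name: str) -> None:
        self._require(name)
        self.df = self.df.drop(columns=[name])
        self.meta.pop(name, None)


# ---------------------------------------------------------------------------
# Sorting


def sort_rows(table: Table, column: str, descending: bool = False) -> np.ndarray:
    """Return the stable row permutation that sorts ``table`` by ``column``.

    Missing values sort last regardless of direction; ties keep their
    original order. The result is an index array: ``perm[i]`` is the original
    row at sorted position ``i``.
    """
    table._require(column)
    series = table.df[column]
    order = series.sort_values(
        ascending=not descending, kind="stable", na_position="last"
    )
    return order.index.to_numpy()


# ---------------------------------------------------------------------------
# Range filters and segmentation


def _finite(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def segment_boundaries(
    values: Iterable[float], k: int, mode: str = "equal-width"
) -> np.ndarray:
    """Split the value domain into ``k`` segments; return ``k+1`` boundaries.

    ``equal-width`` spaces boundaries arithmetically between min and max.
    ``equal-count`` cuts the sorted values after ranks ``ceil(i*n/k)`` so
    segment populations differ by at most one when values are distinct
    (ties can unbalance segments, since equal values cannot be separated).
    """
    if k < 1:
        raise ValueError("segment count must be >= 1")
    arr = _finite(np.asarray(list(values), dtype=float))
    if arr.size == 0:
        raise EmptyDomainError("no finite values to segment")
    lo, hi = float(arr.min()), float(arr.max())
    if mode == "equal-width":
        return np.linspace(lo, hi, k + 1)
    if mode == "equal-count":
        s = np.sort(arr)
        n = s.size
        bounds = [lo]
        for i in range(1, k):
            cut = math.ceil(i * n / k)  # elements before the cut
            bounds.append(float(s[min(cut, n - 1)]))
        bounds.append(hi)
        return np.asarray(bounds)
    raise ValueError(f"unknown segmentation mode {mode!r}")


def assign_segments(values: Iterable[float], boundaries: Sequence[float]) -> np.ndarray:
    """Map each value to its segment index, or -1 for none.

    Membership is half-open ``[b_i, b_{i+1})`` with the final segment closed
    at the top. Values outside ``[b_0, b_k]`` and missing values map to -1.
    """
    b = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(b) < 0):
        raise ValueError("boundaries must be monotone non-decreasing")
    arr = np.asarray(list(values), dtype=float)
    idx = np.searchsorted(b, arr, side="right") - 1
    k = len(b) - 1
    out = np.where((idx >= 0) & (idx < k), idx, -1)
    out = np.where(arr == b[-1], k - 1, out)  # closed maximum
    out = np.where(np.isfinite(arr), out, -1)
    return out.astype(int)


@dataclass
class RangeFilter:
    """Persistent 1-D filter: keep rows whose value lies in ``[low, high]``.

    With ``segments > 1`` the interval is subdivided (equal-width over the
    data span, or equal-count quantile cuts); ``segment`` then selects one
    sub-interval, ``None`` keeps the whole range. The upper endpoint is
    closed per the package-wide interval convention.
    """

    column: str
    low: float
    high: float
    segments: int = 1
    mode: str = "equal-width"
    segment: int | None = None

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError("range filter requires low <= high")
        if self.segments < 1:
            raise ValueError("segments must be >= 1")

    @property
    def columns(self) -> list[str]:
        return [self.column]

    def mask(self, table: Table) -> np.ndarray:
        values = np.asarray(table.column_values(self.column), dtype=float)
        in_range = (values >= self.low) & (
            (values < self.high) | (values == self.high)
        )
        in_range &= np.isfinite(values)
        if self.segments == 1 or self.segment is None:
            return in_range
        kept = values[in_range]
        if kept.size == 0:
            return in_range
        bounds = segment_boundaries(kept, self.segments, self.mode)
        seg = assign_segments(values, bounds)
        return in_range & (seg == self.segment)


# ---------------------------------------------------------------------------
# 2-D region filters


def _collinear(vertices: np.ndarray) -> bool:
    if len(vertices) < 3:
        return True
    p0 = vertices[0]
    for p in vertices[1:]:
        for q in vertices[2:]:
            cross = (p[0] - p0[0]) * (q[1] - p0[1]) - (p[1] - p0[1]) * (q[0] - p0[0])
            if abs(cross) > 1e-12:
                return False
    return True


@dataclass
class Region2DFilter:
    """Persistent 2-D filter over an (x, y) column pair.

    ``rectangle`` is defined by two opposite corners and tested by coordinate
    comparison; ``quad`` (exactly 4 vertices) and ``polygon`` (>= 3) use the
    even-odd ray-casting rule. Boundary points count as inside for every
    shape kind.
    """

    x_column: str
    y_column: str
    shape: Literal["rectangle", "quad", "polygon"]
    vertices: Sequence[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if self.shape == "rectangle":
            if len(v) != 2:
                raise ValueError("rectangle needs exactly 2 defining corners")
        elif self.shape == "quad":
            if len(v) != 4:
                raise ValueError("quad needs exactly 4 vertices")
            if _collinear(v):
                raise DegenerateShapeError("quad has zero area")
        elif self.shape == "polygon":
            if len(v) < 3:
                raise ValueError("polygon needs at least 3 vertices")
            if _collinear(v):
                raise DegenerateShapeError("polygon has zero area")
        else:
            raise ValueError(f"unknown shape kind {self.shape!r}")

    @property
    def columns(self) -> list[str]:
        return [self.x_column, self.y_column]

    def mask(self, table: Table) -> np.ndarray:
        xs = np.asarray(table.column_values(self.x_column), dtype=float)
        ys = np.asarray(table.column_values(self.y_column), dtype=float)
        out = np.zeros(len(xs), dtype=bool)
        finite = np.isfinite(xs) & np.isfinite(ys)
        for i in np.flatnonzero(finite):
            out[i] = point_in_region((xs[i], ys[i]), self)
        return out


def _on_segment(px, py, ax, ay, bx, by, eps=1e-12) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    scale = max(abs(bx - ax), abs(by - ay), 1.0)
    if abs(cross) > eps * scale:
        return False
    dot = (px - ax) * (bx - ax) + (py - ay) * (by - ay)
    sq = (bx - ax) ** 2 + (by - ay) ** 2
    return -eps <= dot <= sq + eps


def point_in_region(point: tuple[float, float], region: Region2DFilter) -> bool:
    """Membership test for a single point against a 2-D region filter.

    Rectangles reduce to inclusive coordinate comparisons. Quads and polygons
    use even-odd ray casting (a horizontal ray crossing an odd number of
    edges means inside), with points on any edge or vertex counted inside.
    """
    px, py = float(point[0]), float(point[1])
    v = np.asarray(region.vertices, dtype=float)
    if region.shape == "rectangle":
        (x0, y0), (x1, y1) = v
        return min(x0, x1) <= px <= max(x0, x1) and min(y0, y1) <= py <= max(y0, y1)
    n = len(v)
    for i in range(n):
        ax, ay = v[i]
        bx, by = v[(i + 1) % n]
        if _on_segment(px, py, ax, ay, bx, by):
            return True
    inside = False
    for i in range(n):
        ax, ay = v[i]
        bx, by = v[(i + 1) % n]
        if (ay > py) != (by > py):
            x_cross = ax + (py - ay) / (by - ay) * (bx - ax)
            if px < x_cross:
                inside = not inside
    return inside


# ---------------------------------------------------------------------------
# Histograms


@dataclass
class HistogramSpec:
    """Binning request: ``bins`` equal-width bins over ``[lo, hi)`` (last bin
    closed) with an optional y-axis transform."""

    column: str
    bins: int
    lo: float
    hi: float
    transform: Literal["none", "log", "cdf", "percentage"] = "none"

    def __post_init__(self):
        if self.bins < 1:
            raise ValueError("bin count must be >= 1")
        if not self.lo < self.hi:
            raise ValueError("histogram range requires lo < hi")


def histogram_counts(values: Iterable[float], spec: HistogramSpec) -> np.ndarray:
    """Count values into the spec's bins; out-of-range and missing excluded."""
    arr = _finite(np.asarray(list(values), dtype=float))
    counts, _ = np.histogram(arr, bins=spec.bins, range=(spec.lo, spec.hi))
    return counts


def transform_counts(counts: Iterable[float], transform: str) -> np.ndarray:
    """Apply a histogram y-axis transform.

    ``percentage`` rescales to sum to 100 (all zeros when the total is 0);
    ``cdf`` is the cumulative proportion, ending at 1 for a nonzero total;
    ``log`` is log10(c+1) so empty bins remain displayable.
    """
    c = np.asarray(list(counts), dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if transform == "none":
        return c
    if transform == "percentage":
        return 100.0 * c / total if total > 0 else np.zeros_like(c)
    if transform == "cdf":
        return np.cumsum(c) / total if total > 0 else np.zeros_like(c)
    if transform == "log":
        return np.log10(c + 1.0)
    raise ValueError(f"unknown transform {transform!r}")
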