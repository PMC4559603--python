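"""Venn and Euler diagrams as data products.

Given up to five named subsets over a universe of row identifiers, this
module computes the cardinality of every inclusion/exclusion region (the
2^k − 1 non-empty membership masks) and produces layout geometry:

* :func:`venn_template` — fixed symmetric templates (2 and 3 circles, 4 and
  5 congruent rotated ellipses) in which every region has nonzero area; the
  counts label the template, areas are not proportional.
* :func:`euler_layout` — approximate area-proportional circle layouts for
  k ≤ 3: each circle's area is proportional to its set size, and the circle
  centers are optimized (lens-area inversion for the initial pairwise
  distances, then seeded Nelder–Mead refinement) to minimize the summed
  squared error between achieved and target region areas. Circles cannot
  realize every region pattern for k ≥ 4, which is why the proportional
  mode stops at 3 sets and larger collections fall back to the templates.

Layouts export as SVG or a JSON geometry description.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from shapely.affinity import rotate, scale, translate
from shapely.geometry import Point

from .errors import ArityError, DegenerateShapeError

MAX_SETS = 5


# ---------------------------------------------------------------------------
# Region cardinalities


@dataclass
class SetCollection:
    """k named member sets (1 <= k <= 5) over a universe of identifiers."""

    names: list[str]
    members: list[set]

    def __post_init__(self):
        if len(self.names) != len(self.members):
            raise ValueError("one name per member set")
        if not 1 <= len(self.names) <= MAX_SETS:
            raise ArityError(
                f"between 1 and {MAX_SETS} sets supported, got {len(self.names)}"
            )

    @classmethod
    def from_dict(cls, sets: Mapping[str, Iterable]) -> "SetCollection":
        names = list(sets)
        return cls(names, [set(sets[n]) for n in names])

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def universe(self) -> set:
        out: set = set()
        for m in self.members:
            out |= m
        return out


def region_cardinalities(sets: SetCollection) -> dict[tuple[bool, ...], int]:
    """Element count of each of the 2^k − 1 non-empty inclusion masks.

    Mask position i is True when the region lies inside set i. Every
    element of the universe lands in exactly one mask, so the counts sum to
    the union size. Masks with no elements are present with count 0.
    """
    k = sets.k
    counts: dict[tuple[bool, ...], int] = {
        mask: 0
        for mask in itertools.product((False, True), repeat=k)
        if any(mask)
    }
    for element in sets.universe:
        mask = tuple(element in m for m in sets.members)
        counts[mask] += 1
    return counts


def mask_label(names: Sequence[str], mask: Sequence[bool]) -> str:
    return "&".join(n for n, inside in zip(names, mask) if inside)


# ---------------------------------------------------------------------------
# Layout geometry


@dataclass
class Shape:
    """A circle or ellipse in layout coordinates."""

    kind: str  # "circle" | "ellipse"
    cx: float
    cy: float
    rx: float
    ry: float
    angle: float = 0.0  # degrees, ellipses only

    def to_shapely(self, quad_segs: int = 64):
        disc = Point(self.cx, self.cy).buffer(1.0, quad_segs=quad_segs)
        disc = scale(disc, self.rx, self.ry, origin=(self.cx, self.cy))
        if self.angle:
            disc = rotate(disc, self.angle, origin=(self.cx, self.cy))
        return disc


@dataclass
class Layout:
    """Diagram geometry plus region labels and counts."""

    names: list[str]
    shapes: list[Shape]
    counts: dict[tuple[bool, ...], int] = field(default_factory=dict)
    proportional: bool = False
    loss: float | None = None
    loss_trace: list[float] = field(default_factory=list)

    def region_areas(self, quad_segs: int = 64) -> dict[tuple[bool, ...], float]:
        """Area of every inclusion/exclusion region of the drawn shapes."""
        discs = [s.to_shapely(quad_segs) for s in self.shapes]
        areas: dict[tuple[bool, ...], float] = {}
        for mask in itertools.product((False, True), repeat=len(discs)):
            if not any(mask):
                continue
            region = None
            for disc, inside in zip(discs, mask):
                if inside:
                    region = disc if region is None else region.intersection(disc)
            for disc, inside in zip(discs, mask):
                if not inside:
                    region = region.difference(disc)
            areas[mask] = region.area
        return areas

    def to_json(self) -> str:
        doc = {
            "names": self.names,
            "proportional": self.proportional,
            "loss": self.loss,
            "shapes": [vars(s) for s in self.shapes],
            "regions": [
                {
                    "mask": list(mask),
                    "label": mask_label(self.names, mask),
                    "count": count,
                }
                for mask, count in sorted(self.counts.items())
            ],
        }
        return json.dumps(doc, indent=2)

    def to_svg(self, size: int = 400) -> str:
        """Render shapes (outline only) into a standalone SVG document."""
        xs = [s.cx for s in self.shapes]
        ys = [s.cy for s in self.shapes]
        r = max(max(s.rx, s.ry) for s in self.shapes)
        lo_x, hi_x = min(xs) - r, max(xs) + r
        lo_y, hi_y = min(ys) - r, max(ys) + r
        span = max(hi_x - lo_x, hi_y - lo_y) or 1.0
        f = size / span

        def tx(x):
            return (x - lo_x) * f

        def ty(y):
            return size - (y - lo_y) * f

        palette = ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd"]
        parts = [
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}">'
        ]
        for i, s in enumerate(self.shapes):
            color = palette[i % len(palette)]
            transform = ""
            if s.angle:
                transform = (
                    f' transform="rotate({-s.angle} {tx(s.cx):.2f} {ty(s.cy):.2f})"'
                )
            parts.append(
                f'<ellipse cx="{tx(s.cx):.2f}" cy="{ty(s.cy):.2f}"'
                f' rx="{s.rx * f:.2f}" ry="{s.ry * f:.2f}"'
                f' fill="{color}" fill-opacity="0.25" stroke="{color}"{transform}/>'
            )
            parts.append(
                f'<text x="{tx(s.cx):.2f}" y="{ty(s.cy):.2f}" text-anchor="middle"'
                f' font-family="sans-serif" font-size="14">{self.names[i]}</text>'
            )
        parts.append("</svg>")
        return "\n".join(parts)


# Fixed templates. 2 and 3 sets: symmetric circles. 4 and 5 sets: congruent
# rotated ellipses (the classic constructions); every one of the 2^k − 1
# regions has nonzero area, verified geometrically in the test suite.
_ELLIPSES_4 = [
    (0.350, 0.400, 0.36, 0.225, 140.0),
    (0.450, 0.500, 0.36, 0.225, 140.0),
    (0.544, 0.500, 0.36, 0.225, 40.0),
    (0.644, 0.400, 0.36, 0.225, 40.0),
]
_ELLIPSES_5 = [
    (0.428, 0.449, 0.435, 0.250, 155.0),
    (0.469, 0.543, 0.435, 0.250, 82.0),
    (0.558, 0.523, 0.435, 0.250, 10.0),
    (0.578, 0.432, 0.435, 0.250, 118.0),
    (0.489, 0.383, 0.435, 0.250, 46.0),
]


def venn_template(k: int, names: Sequence[str] | None = None) -> Layout:
    """Fixed symmetric diagram template for 2 <= k <= 5 sets."""
    if not 2 <= k <= MAX_SETS:
        raise ArityError(f"templates exist for 2 to {MAX_SETS} sets, got {k}")
    names = list(names) if names is not None else [f"S{i + 1}" for i in range(k)]
    if len(names) != k:
        raise ValueError("need one name per set")
    shapes: list[Shape]
    if k == 2:
        shapes = [
            Shape("circle", -0.5, 0.0, 1.0, 1.0),
            Shape("circle", 0.5, 0.0, 1.0, 1.0),
        ]
    elif k == 3:
        # circles at the corners of an equilateral triangle
        rad = 0.6
        shapes = [
            Shape(
                "circle",
                rad * math.cos(math.radians(90 + i * 120)),
                rad * math.sin(math.radians(90 + i * 120)),
                1.0,
                1.0,
            )
            for i in range(3)
        ]
    else:
        params = _ELLIPSES_4 if k == 4 else _ELLIPSES_5
        shapes = [
            Shape("ellipse", cx, cy, rx, ry, angle) for cx, cy, rx, ry, angle in params
        ]
    return Layout(names=names, shapes=shapes, proportional=False)


def venn_diagram(sets: SetCollection) -> Layout:
    """Template layout labelled with the collection's region counts."""
    if sets.k == 1:
        layout = Layout(
            names=list(sets.names),
            shapes=[Shape("circle", 0.0, 0.0, 1.0, 1.0)],
        )
    else:
        layout = venn_template(sets.k, sets.names)
    layout.counts = region_cardinalities(sets)
    return layout


# ---------------------------------------------------------------------------
# Area-proportional Euler layout (k <= 3 circles)


def _lens_area(d: float, r1: float, r2: float) -> float:
    """Intersection area of two circles with center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    a1 = math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    return (
        r1 * r1 * (a1 - math.sin(2 * a1) / 2)
        + r2 * r2 * (a2 - math.sin(2 * a2) / 2)
    )


def _distance_for_overlap(target: float, r1: float, r2: float) -> float:
    """Invert the lens-area formula: distance achieving a target overlap."""
    full = math.pi * min(r1, r2) ** 2
    if target <= 0:
        return (r1 + r2) * 1.05  # clearly disjoint
    if target >= full:
        return abs(r1 - r2) * 0.95
    return brentq(
        lambda d: _lens_area(d, r1, r2) - target,
        abs(r1 - r2) + 1e-12,
        r1 + r2 - 1e-12,
    )


def _target_areas(
    counts: Mapping[tuple[bool, ...], int], unit: float
) -> dict[tuple[bool, ...], float]:
    return {mask: c * unit for mask, c in counts.items()}


def euler_layout(
    counts: Mapping[tuple[bool, ...], int],
    names: Sequence[str] | None = None,
    seed: int = 0,
    n_starts: int = 4,
    quad_segs: int = 48,
) -> Layout:
    """Approximate area-proportional circle layout from region counts.

    One area unit per element: circle i gets radius sqrt(|S_i| / pi), pairwise
    distances are initialized by inverting the circle-lens area for the
    target pairwise overlap, and (for 3 sets) circle centers are refined by
    seeded multi-start Nelder–Mead minimizing the summed squared error
    between achieved and target region areas. The achieved loss is reported
    on the layout. Disjoint sets come out as non-overlapping circles with
    (near-)zero loss.
    """
    masks = list(counts)
    if not masks:
        raise ArityError("no region counts given")
    k = len(masks[0])
    if not 1 <= k <= 3:
        raise ArityError("area-proportional layout supports 1 to 3 sets")
    names = list(names) if names is not None else [f"S{i + 1}" for i in range(k)]

    set_sizes = [
        sum(c for mask, c in counts.items() if mask[i]) for i in range(k)
    ]
    if all(s == 0 for s in set_sizes):
        raise DegenerateShapeError("all sets are empty; nothing to lay out")
    radii = [math.sqrt(max(s, 1e-9) / math.pi) for s in set_sizes]
    targets = _target_areas(counts, unit=1.0)

    def pairwise_overlap(i: int, j: int) -> float:
        return sum(c for mask, c in counts.items() if mask[i] and mask[j])

    if k == 1:
        layout = Layout(
            names, [Shape("circle", 0.0, 0.0, radii[0], radii[0])],
            dict(counts), proportional=True, loss=0.0,
        )
        return layout

    d01 = _distance_for_overlap(pairwise_overlap(0, 1), radii[0], radii[1])
    if k == 2:
        shapes = [
            Shape("circle", 0.0, 0.0, radii[0], radii[0]),
            Shape("circle", d01, 0.0, radii[1], radii[1]),
        ]
        layout = Layout(names, shapes, dict(counts), proportional=True)
        layout.loss = _layout_loss(
            [(0.0, 0.0), (d01, 0.0)], radii, targets, quad_segs
        )
        return layout

    # k == 3: place circle 0 at origin, circle 1 on the x-axis at the
    # lens-derived distance, and optimize the free coordinates.
    d02 = _distance_for_overlap(pairwise_overlap(0, 2), radii[0], radii[2])
    d12 = _distance_for_overlap(pairwise_overlap(1, 2), radii[1], radii[2])
    # triangle-inequality-feasible initial position for circle 2
    x2 = (d01 * d01 + d02 * d02 - d12 * d12) / (2 * d01) if d01 > 0 else d02
    y2sq = d02 * d02 - x2 * x2
    y2 = math.sqrt(y2sq) if y2sq > 0 else 0.1 * max(radii)

    rng = np.random.default_rng(seed)
    trace: list[float] = []

    def loss_fn(theta: np.ndarray) -> float:
        centers = [(0.0, 0.0), (theta[0], 0.0), (theta[1], theta[2])]
        value = _layout_loss(centers, radii, targets, quad_segs)
        trace.append(min(value, trace[-1]) if trace else value)
        return value

    best = None
    x0 = np.array([d01, x2, y2])
    for start in range(n_starts):
        jitter = np.zeros(3) if start == 0 else rng.normal(0, 0.15 * max(radii), 3)
        res = minimize(
            loss_fn,
            x0 + jitter,
            method="Nelder-Mead",
            options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    shapes = [
        Shape("circle", 0.0, 0.0, radii[0], radii[0]),
        Shape("circle", float(theta[0]), 0.0, radii[1], radii[1]),
        Shape("circle", float(theta[1]), float(theta[2]), radii[2], radii[2]),
    ]
    layout = Layout(names, shapes, dict(counts), proportional=True, loss=float(best.fun))
    layout.loss_trace = trace  # best-so-far per evaluation; monotone
    return layout


def _layout_loss(centers, radii, targets, quad_segs: int) -> float:
    layout = Layout(
        names=[str(i) for i in range(len(radii))],
        shapes=[
            Shape("circle", cx, cy, r, r) for (cx, cy), r in zip(centers, radii)
        ],
    )
    achieved = layout.region_areas(quad_segs)
    return float(
        sum(
            (achieved.get(mask, 0.0) - target) ** 2
            for mask, target in targets.items()
        )
    )
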