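# Methods

This note documents the models, conventions and numerical choices behind
`tabbench`, and what the synthetic-data generators do and do not emulate.

## The app model

An app is a script plus a JSON manifest declaring an ordered list of typed
parameters. The manifest is the single source of truth for the interface:
widget kinds are a pure function of the parameter type (spinner for
`int`/`double`, checkbox for `boolean`, combo box for `string-items` and
the single-column types, list selection for the multi-column types, a
range slider for `range-*`, a name field for the output types), and a
missing type means `string`. Optional manifest keys are `label`, `info`,
`default`, `min`/`max` (numeric types), `items` (string types), `ui`
(`load`/`save`, filename only) and `category`. A parameter with no default
(and which is not an output) is required. The historically attested
misspelling `ouput-column` is accepted as an alias of `output-column` and
canonicalized on write.

Manifest keys and the params/categories layout were an open design point;
the package uses the minimal key set above with `params` as an ordered
JSON object (a list of objects with `name` keys is also accepted).
Categories carry an optional `collapsed` flag, default expanded. There is
no dedicated manifest type for file outputs; a `filename` parameter with
`ui: save` plays that role.

## Execution semantics

Scripts execute line by line. Preprocessing turns the text into units: one
per line, except that a bare `{{` line opens a block closed by a bare `}}`
line (one unit spanning the enclosed lines — multi-line R constructs would
otherwise break), and a line starting with `###applyParameters` marks the
injection point without emitting a unit. Without the directive the input
table and bindings are injected before the first unit. A repeated
directive, an unclosed `{{`, or a stray `}}` is a structure error naming
the line. Injection sets the input table under the fixed session name
`input_table` plus one session variable per bound parameter under its
variable name. Column-typed parameters travel as (single- or multi-column)
tabular values extracted from the input table; range types as a length-2
numeric vector; output destinations as text. An empty string bound to an
optional column parameter means "nothing selected" and is not injected.

Each unit's textual output is appended to a transcript (the console-pane
record). Error text from a failing unit is kept verbatim in the transcript
and the run reports `error`. Cancellation is polled at unit boundaries
only — matching line-by-line execution granularity — and a cancelled run,
like an errored one, yields no outputs (all-or-nothing). After a
successful run, each `output-column` / `output-table` parameter with a
non-empty destination name is resolved by fetching the session variable
named by the *parameter* and filing it under the *destination*; a column
payload must match the input table's row count. A fresh session is used
per run; session reuse across runs is deliberately not attempted.

Two backends implement the session contract (set / evaluate / fetch /
cancel). The R backend drives `Rscript` over a length-prefixed UTF-8 frame
protocol with JSON payloads (jsonlite on the R side; tabular values travel
column-major, missing values as JSON null). The mock backend interprets
`name <- expression` lines in-process over a registered function table and
is lenient by default — uninterpretable lines become echoed no-ops — so
real R scripts can be smoke-run without R; `strict=True` turns that into
an error.

## The data model

Tables are ordered named columns (numeric, text, logical) over n rows,
with per-column provenance: `data` (loaded or computed from sequencing
data), `calculated` (re-derivable from a stored formula), `output`
(written by an app). Subsets are materialized child tables defined by a
persistent filter over a parent; the hierarchy is a forest, and a child's
membership is always parent membership ∧ filter predicate (so filters
apply transitively down the hierarchy). Reactivity is explicit: mutating
operations call `refresh`, which re-derives calculated columns and
rebuilds every descendant subset from its parent's current data. This is
deterministic and testable where an event system would not be; the
invariant checked throughout is that a refreshed subset equals a
from-scratch recomputation. Applying an app output under a new name
creates a column (or table); an existing name overwrites in place. Table
and column names are separate namespaces, so an output table and an
output column may share a name.

### Interval convention

One rule everywhere: half-open `[low, high)` with the maximum boundary
closed. It applies to range filters, segment membership and histogram
bins, so no value is double-counted and the domain maximum is never
dropped. Whether the original interactive tools closed both ends is not
documented; this convention is declared, not inferred.

Equal-width segmentation spaces k+1 boundaries arithmetically over
[min, max]; equal-count cuts the sorted values after ranks ⌈i·n/k⌉, which
balances segment populations to within one element when values are
distinct (ties cannot be split and may unbalance segments — documented and
tested on distinct values). Missing values are excluded from every filter,
segment and histogram; never imputed.

### 2-D region filters

Rectangles are two opposite corners tested by inclusive coordinate
comparison. Quads (exactly 4 vertices) and polygons (≥ 3) use even-odd
ray casting with points on any edge or vertex counted inside; the even-odd
rule is implemented directly because library point-in-polygon predicates
follow the OGC fill rule, which differs on self-intersecting outlines
(e.g. a bowtie quad). A shape whose vertices are all collinear is
degenerate and rejected. Histogram transforms: `percentage` rescales to
sum 100; `cdf` is the cumulative proportion ending at 1; `log` is
log₁₀(c+1) so empty bins remain displayable (the base and zero-handling
were unspecified; this is the package's choice).

## Formulas

Calculated columns use an Excel-like expression language over column names
instead of cell addresses (the data model is columnar); `[bracketed
names]` admit spaces. Precedence is `^` > unary minus > `*` `/` > `+` `-`
> comparisons, left-associative except `^` — note `-2^2 = -4`. The
function set (ABS, LOG, LOG2, LOG10, SQRT, EXP, MIN, MAX, MEAN, SUM, IF,
AND, OR, NOT, ROUND) is declared minimal coverage; LOG defaults to base
10 and takes an optional base, ROUND rounds half away from zero,
and MIN/MAX/MEAN/SUM aggregate across their arguments within a row, never
down a column. The error policy is missing-value propagation: division by
zero, log of a non-positive value and sqrt of a negative produce NaN, and
NaN propagates through arithmetic, comparisons and aggregates. This keeps
columns numeric rather than introducing `#DIV/0!`-style text sentinels.
Evaluation is vectorized; the test suite holds an independent scalar
tree-walk interpreter and checks agreement on hundreds of random formulas.

## Genomic coordinates and signal

Internal coordinates are 0-based half-open everywhere. BED is native;
WIG (1-based, fixedStep/variableStep, optional span) and CSV region
tables (1-based inclusive) are converted at the parser, which is where the
conversions are tested. Signal tracks are sparse per-chromosome runs
`(start, end, value)`; overlapping spans within a WIG declaration are
last-writer-wins. Region summaries (sum, mean, max, count of nonzero
bases) treat uncovered bases as 0 and divide means by the full region
length; strand is parsed but ignored (summaries never condition on it).

RPKM is count / ((length/10³)·(total/10⁶)). For alignment-derived
coverage the read total is the mapped-read count; for WIG tracks, which
carry no read counts, the per-base sum stands in for the region count and
the track's total signal for the library size — an approximation implied
by normalizing directly from signal tracks, and documented as such. BAM
support is a thin adapter: per-base coverage through pysam, then identical
treatment to a WIG-derived track. Allelic contribution is a/(a+b) with
both-zero mapping to missing rather than 0 or 0.5.

## Set diagrams

Region cardinalities classify each element of the universe into exactly
one of the 2ᵏ−1 inclusion/exclusion masks (k ≤ 5). Venn templates are
fixed geometry — symmetric circle pairs/triples, and congruent rotated
ellipse templates for k = 4, 5 — chosen so every region has nonzero area
(verified geometrically in the tests); counts label the template, areas
are not proportional. Which published template the original tools used is
unknowable from the available description; any fixed template satisfying
the all-regions-drawable contract is equivalent for this purpose.

The area-proportional Euler mode is limited to k ≤ 3 because circles
cannot realize every region pattern for k ≥ 4; larger collections fall
back to the templates. The layout fixes each circle's area proportional to
its set size (one element = one area unit), initializes pairwise center
distances by inverting the circle-lens area formula with Brent's method,
and refines the free center coordinates by Nelder–Mead (four starts,
seeded jitter, fixed default seed 0) minimizing Σ(achieved − target)²
over region areas. Achieved areas are measured with shapely on 48-segment
circle approximations (96 in verification paths); the reported loss is
the objective at the optimum, and the recorded loss trace is
best-so-far, hence monotone. Disjoint targets produce non-overlapping
circles with near-zero loss; a subset relation produces containment
within tolerance.

## Synthetic data

The generators are pure functions of (config, seed). Tables are an id
column plus log-normal numeric columns (default log-mean 2, log-sd 1,
10 columns — the shape of a ten-sample expression comparison, where
log-normal marginals are a standard stand-in for expression intensity).
Tracks cover two small chromosomes (1000 and 600 bp by default) with
uniform, single-spike, or random run signal at ~50% coverage; regions tile
the chromosomes in fixed-length windows. Expected per-region summaries are
computed at generation time by a deliberately scalar per-base loop and
emitted beside the fixtures, so a failure localizes to the optimized
run-based implementation rather than the data.

What the fixtures do *not* emulate: read-level sequencing data (no
fragment lengths, duplicates, mapping ambiguity), biological correlation
structure between samples, real chromosome scales, or batch effects.
Passing tests therefore demonstrate the correctness of the mechanics —
parsing, summarization, normalization arithmetic, filter semantics — on
faithfully shaped small inputs, not statistical performance on real
libraries. Problem sizes throughout the suite (hundreds of rows, hundreds
of random trials, kilobase chromosomes) were chosen to exercise every code
path while keeping the whole suite fast.

## Known limitations

- The mock backend's expression language is intentionally tiny; real R
  scripts are only smoke-run under it (assignments of python-evaluable
  expressions execute, everything else is a no-op).
- The R backend holds one session per run and terminates the subprocess on
  cancel; there is no multi-session scheduling.
- No bigWig/bigBed, no peak calling, no aligner; WIG serialization writes
  span-1 variableStep, which is value-preserving but not
  representation-preserving.
- Euler layouts beyond 3 sets, exact-area layouts, and undo/history for
  the workspace are out of scope.
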