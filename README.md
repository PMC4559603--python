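# tabbench

A headless workbench for manifest-driven statistical apps over tabular and
genomic data.

Visual analysis workbenches for sequencing data let biologists run R-based
analyses without programming: each analysis is an *app bundle* — an R script
plus a JSON manifest declaring typed parameters — whose user interface is
generated automatically, and all apps read and write a shared tabular data
model with persistent filters, subset hierarchies and calculated columns.
`tabbench` implements that core as an importable Python library (plus a thin
CLI): everything except the windowing, for people who want the app model,
the execution engine and the reactive data model scriptable and testable.

## What it provides

- **App manifests** (`tabbench.appspec`) — a 15-token parameter type system
  (`int`, `double`, `boolean`, `string`, `string-items`, `filename`,
  `color`, `range-int`, `range-double`, `column`, `column-numerical`,
  `multi-column`, `multi-column-numerical`, `output-column`,
  `output-table`). Each type maps to a fixed widget kind; labels default to
  a rule over the variable name (strip the `input` prefix, underscores to
  spaces). Bundles are discovered on disk as `<prefix>.R` + `<prefix>.json`
  (+ optional `<prefix>.png` icon).
- **Execution engine** (`tabbench.engine`, `tabbench.backends`) — scripts
  run unit-by-unit in a backend session (each line is a unit; `{{ }}`
  fences a multi-line block; `###applyParameters` marks where the input
  table and parameter bindings are injected). Output is streamed to a
  transcript; declared outputs (columns, tables, file paths) are collected
  afterwards, all-or-nothing. Two backends ship: a real R interpreter
  driven as an `Rscript` subprocess, and an in-process mock for tests.
- **Reactive tables** (`tabbench.datatable`, `tabbench.workspace`) — named
  tables with data/calculated/output columns; 1-D range filters with
  equal-width or equal-count segmentation; 2-D rectangle/quad/polygon
  filters (even-odd rule, boundaries inside); filter-derived subsets
  forming a hierarchy that re-derives itself when data changes; histogram
  binning with log / CDF / percentage transforms.
- **Formulas** (`tabbench.formula`) — Excel-style calculated columns over
  column names (`=LOG2(ko+1)-LOG2(wt+1)`), evaluated row-wise with
  missing-value propagation.
- **Genomics** (`tabbench.genomics`) — BED/CSV region files, WIG
  (fixedStep/variableStep) signal tracks, per-base SAM/BAM coverage via
  pysam; per-region sum/mean/max/nonzero summaries;
  RPKM = count / ((length/10³)·(total/10⁶)); allelic contribution
  a/(a+b).
- **Set diagrams** (`tabbench.setops`) — region cardinalities for up to 5
  sets (all 2ᵏ−1 inclusion/exclusion masks), fixed symmetric Venn
  templates, and approximate area-proportional Euler layouts for ≤ 3 sets
  (circle areas ∝ set sizes, centers optimized against target region
  areas), exportable as SVG/JSON.
- **Fixtures** (`tabbench.fixtures`) — deterministic generators for
  expression-like tables, signal tracks with independently computed oracle
  sums, and complete app bundles (SimplePlot, correlation, fold-change
  labeler).

## Worked example

Label differentially expressed genes with a calculated column
(`examples/04_calculated_columns.py`):

```python
from tabbench import Table
table = Table.from_dict({"wt": wt, "ko": ko})          # 1000 simulated genes
table.set_calculated("log2_fc", "=LOG2(ko+1)-LOG2(wt+1)")
table.set_calculated("de_label", "=IF(log2_fc>=1, 1, IF(log2_fc<=-1, -1, 0))")
```

prints

```
rows: 1000
up-regulated   (+1): 105
down-regulated (-1): 118
no difference   (0): 777
```

— the +1/−1/0 convention for differential-expression output columns; about
10% of genes were simulated with a 4× increase and 10% with a 4× decrease,
and the labels recover those groups at the |log2 FC| ≥ 1 threshold.

Running the shipped correlation app in a live R session
(`examples/02_run_app_in_r.py`) executes its script unit-by-unit, injects
the 10-column table and parameters at `###applyParameters`, and fetches the
`output-table` result back:

```
status: ok
output table 'corr': 10 x 10
   sample_0  sample_1  sample_2  sample_3
0     1.000     0.045     0.025     0.052
...
```

Each script in `examples/` demonstrates one capability and prints what the
numbers mean; all inputs are generated on the fly.

## Command line

```bash
tabbench apps list <dir>                      # discover app bundles
tabbench run <dir> <app> --table t.csv --input_x sample_0 --input_y sample_1
tabbench workflow analysis.yaml               # chain apps over named tables
tabbench table calc --table t.csv --name fc \
    --formula "=LOG2(ko+1)-LOG2(wt+1)" --out out.csv
tabbench table add-track --table regions.csv --wig signal.wig \
    --stat sum --norm rpkm --name x_rpkm --out out.csv
tabbench fixtures make --template casestudy1 --seed 0
```

## Documentation

`docs/methods.md` describes the models and conventions in detail: the
interval convention, the formula error policy, the coordinate systems, the
Euler optimization, what the synthetic generators do and do not emulate,
and the package's known limitations.
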