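"""Synthetic data and app-bundle generators.

Everything the rest of the package needs for testing and demonstration is
generated here, deterministically from (config, seed): expression-like
tables (log-normal columns, the shape of a ten-sample RNA-seq comparison),
signal tracks with matching region files and independently computed
per-region oracle sums, and complete app bundles — a SimplePlot replica
(two required column parameters, a free color column, a four-item log-axis
choice with empty default, an untyped title), a correlation app
(multi-column numeric input, Pearson/Spearman choice, table output), and a
fold-change labeler emitting the +1 / −1 / 0 differential-expression label
convention as an output column.

The oracle sums are computed by a straight per-base loop at generation
time, independent of the optimized run-based summarization they later
check against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatable import Table


@dataclass
class TableConfig:
    """Shape of a generated expression-like table."""

    n_rows: int = 100
    n_columns: int = 10
    seed: int = 0
    prefix: str = "sample"
    lognormal_mean: float = 2.0
    lognormal_sigma: float = 1.0
    id_column: str = "gene_id"


@dataclass
class GenomeConfig:
    """Shape of a generated signal track + region file pair."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1000, "chr2": 600}
    )
    n_regions: int = 8
    region_length: int = 100
    signal: str = "random"  # "random" | "uniform" | "spike"
    uniform_value: float = 5.0
    density: float = 0.5  # fraction of covered bases (random model)


def gen_table(config: TableConfig | None = None, path=None) -> Table:
    """Deterministic expression-like table: an id column plus log-normal
    numeric columns. Identical config+seed gives byte-identical CSV."""
    config = config or TableConfig()
    rng = np.random.default_rng(config.seed)
    data: dict[str, list | np.ndarray] = {
        config.id_column: [f"g{i:05d}" for i in range(config.n_rows)]
    }
    for j in range(config.n_columns):
        data[f"{config.prefix}_{j}"] = np.round(
            rng.lognormal(config.lognormal_mean, config.lognormal_sigma, config.n_rows),
            4,
        )
    table = Table(pd.DataFrame(data))
    if path is not None:
        table.write_csv(path)
    return table


def gen_track_and_regions(
    config: GenomeConfig | None = None, directory=None
) -> tuple[str, str, pd.DataFrame]:
    """Generate a WIG track, a BED region file, and an oracle table.

    Returns ``(wig_text, bed_text, oracle)`` where the oracle holds
    per-region sum/mean/max/count_nonzero computed by an independent
    per-base loop over dense arrays. When ``directory`` is given the three
    artifacts are also written there (``signal.wig``, ``regions.bed``,
    ``oracle.csv``).
    """
    config = config or GenomeConfig()
    rng = np.random.default_rng(config.seed)

    dense: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths.items():
        arr = np.zeros(length)
        if config.signal == "uniform":
            arr[:] = config.uniform_value
        elif config.signal == "spike":
            arr[rng.integers(0, length)] = config.uniform_value
        else:
            covered = rng.random(length) < config.density
            arr[covered] = rng.integers(1, 20, covered.sum()).astype(float)
        dense[chrom] = arr

    # WIG: one fixedStep declaration per chromosome, full-length, step 1.
    wig_lines: list[str] = []
    for chrom, arr in dense.items():
        wig_lines.append(f"fixedStep chrom={chrom} start=1 step=1")
        wig_lines.extend(f"{v:g}" for v in arr)
    wig_text = "\n".join(wig_lines) + "\n"

    # Regions: tiling windows per chromosome, round-robin until n_regions.
    regions: list[tuple[str, int, int, str]] = []
    i = 0
    offsets = {chrom: 0 for chrom in dense}
    chroms = list(dense)
    while len(regions) < config.n_regions:
        chrom = chroms[i % len(chroms)]
        start = offsets[chrom]
        end = start + config.region_length
        if end > len(dense[chrom]):
            offsets[chrom] = 0
            start, end = 0, config.region_length
        regions.append((chrom, start, end, f"r{len(regions)}"))
        offsets[chrom] = end
        i += 1
    bed_text = "".join(f"{c}\t{s}\t{e}\t{n}\n" for c, s, e, n in regions)

    # Oracle: straight per-base loops, no run arithmetic.
    rows = []
    for chrom, start, end, name in regions:
        arr = dense[chrom][start:end]
        total = 0.0
        peak = 0.0
        nonzero = 0
        for v in arr:  # deliberately scalar: the independent reference
            total += v
            if v > peak:
                peak = v
            if v != 0:
                nonzero += 1
        rows.append(
            {
                "id": name,
                "chrom": chrom,
                "start": start,
                "end": end,
                "sum": total,
                "mean": total / (end - start),
                "max": peak,
                "count_nonzero": float(nonzero),
            }
        )
    oracle = pd.DataFrame(rows)

    if directory is not None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "signal.wig").write_text(wig_text, encoding="utf-8")
        (directory / "regions.bed").write_text(bed_text, encoding="utf-8")
        oracle.to_csv(directory / "oracle.csv", index=False)
    return wig_text, bed_text, oracle


# ---------------------------------------------------------------------------
# App bundles

_SIMPLEPLOT_MANIFEST = {
    "params": {
        "input_x": {"type": "column-numerical"},
        "input_y": {"type": "column-numerical"},
        "input_color": {"type": "column", "default": ""},
        "input_log": {
            "type": "string-items",
            "items": ["", "x", "y", "xy"],
            "default": "",
        },
        "input_title": {"default": ""},
    }
}

_SIMPLEPLOT_SCRIPT = """\
# SimplePlot: 2D scatter of two numeric columns of the input table.
###applyParameters
{{
x <- input_x[[1]]
y <- input_y[[1]]
plot(x, y, log = input_log, main = input_title)
}}
"""

_CORRELATION_MANIFEST = {
    "params": {
        "input_columns": {"type": "multi-column-numerical"},
        "input_method": {
            "type": "string-items",
            "items": ["pearson", "spearman"],
            "default": "pearson",
        },
        "output_corr": {"type": "output-table", "default": ""},
    }
}

_CORRELATION_SCRIPT = """\
# Pairwise correlation matrix of the selected numeric columns.
###applyParameters
output_corr <- cor(input_columns, method = input_method)
"""

_FOLD_CHANGE_MANIFEST = {
    "params": {
        "input_case": {"type": "column-numerical"},
        "input_control": {"type": "column-numerical"},
        "input_threshold": {"type": "double", "default": 1.0, "min": 0.0},
        "output_label": {"type": "output-column", "default": ""},
    }
}

_FOLD_CHANGE_SCRIPT = """\
# Label rows +1 (up), -1 (down) or 0 by log2 fold change against a threshold.
###applyParameters
{{
fc <- log2(input_case[[1]] + 1) - log2(input_control[[1]] + 1)
output_label <- ifelse(fc >= input_threshold, 1, ifelse(fc <= -input_threshold, -1, 0))
}}
"""

APP_TEMPLATES = {
    "simpleplot": (_SIMPLEPLOT_MANIFEST, _SIMPLEPLOT_SCRIPT),
    "correlation": (_CORRELATION_MANIFEST, _CORRELATION_SCRIPT),
    "fold_change_labeler": (_FOLD_CHANGE_MANIFEST, _FOLD_CHANGE_SCRIPT),
}


def gen_app_bundle(template: str, directory, script_ext: str = ".R") -> Path:
    """Write one app bundle (script + manifest) into ``directory``.

    Returns the script path; the manifest shares its name prefix.
    """
    if template not in APP_TEMPLATES:
        raise ValueError(
            f"unknown template {template!r}; choose from {sorted(APP_TEMPLATES)}"
        )
    manifest, script = APP_TEMPLATES[template]
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    script_path = directory / f"{template}{script_ext}"
    script_path.write_text(script, encoding="utf-8")
    (directory / f"{template}.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return script_path
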