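"""Genomic regions, signal tracks, and the normalizations built on them.

Regions come from BED-like feature files or CSV tables; base-resolution
signal comes from WIG text tracks (fixedStep and variableStep dialects) or
from per-base alignment coverage via pysam. Internally every coordinate is
0-based half-open — BED natively, WIG and CSV (1-based) converted at the
parser — so downstream code never reasons about conventions.

On top of region × track the module computes per-region summaries (sum,
mean, max, count of nonzero bases) and two field-standard normalizations:

* RPKM — reads per kilobase of region per million mapped reads,
  ``count / ((length/1000) · (total/1e6))``. When the signal comes from a
  WIG track with no read counts, the per-base sum stands in for the region
  count and the track total for the mapped total (an approximation).
* allelic contribution — the fraction of allele-assignable reads on one
  haplotype, ``a / (a + b)``; undefined (missing) when both counts are 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatable import Table
from .errors import DomainError, FormatError, RecordError, SchemaError

REGION_COLUMNS = ("chrom", "start", "end")


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise RecordError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
                " (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class SignalTrack:
    """Per-chromosome base-resolution signal stored as sparse runs.

    Each chromosome holds sorted, non-overlapping ``(start, end, value)``
    runs; bases not covered by a run have signal 0. ``total_signal`` is the
    value-weighted length over all runs; ``total_reads`` is set when the
    track came from alignments.
    """

    def __init__(self):
        self.runs: dict[str, list[tuple[int, int, float]]] = {}
        self.total_reads: int | None = None

    def add_run(self, chrom: str, start: int, end: int, value: float) -> None:
        """Insert a run; overlap with existing runs is last-writer-wins."""
        if start >= end:
            return
        runs = self.runs.setdefault(chrom, [])
        kept: list[tuple[int, int, float]] = []
        for s, e, v in runs:
            if e <= start or s >= end:  # disjoint
                kept.append((s, e, v))
                continue
            if s < start:  # left remnant survives
                kept.append((s, start, v))
            if e > end:  # right remnant survives
                kept.append((end, e, v))
        kept.append((start, end, float(value)))
        kept.sort()
        self.runs[chrom] = kept

    def finalize(self) -> "SignalTrack":
        """Merge adjacent equal-value runs and drop zero-value runs."""
        for chrom, runs in self.runs.items():
            merged: list[tuple[int, int, float]] = []
            for s, e, v in sorted(runs):
                if v == 0:
                    continue
                if merged and merged[-1][1] == s and merged[-1][2] == v:
                    merged[-1] = (merged[-1][0], e, v)
                else:
                    merged.append((s, e, v))
            self.runs[chrom] = merged
        return self

    @property
    def total_signal(self) -> float:
        return float(
            sum(v * (e - s) for runs in self.runs.values() for s, e, v in runs)
        )

    def chrom_signal(self, chrom: str) -> float:
        return float(sum(v * (e - s) for s, e, v in self.runs.get(chrom, [])))

    def values_over(self, region: GenomicRegion) -> np.ndarray:
        """Dense per-base signal over the region (0 where uncovered)."""
        out = np.zeros(region.length)
        for s, e, v in self.runs.get(region.chrom, []):
            lo = max(s, region.start)
            hi = min(e, region.end)
            if lo < hi:
                out[lo - region.start : hi - region.start] = v
        return out


# ---------------------------------------------------------------------------
# Region I/O


def _region_from_bed_fields(fields: Sequence[str], lineno: int) -> GenomicRegion:
    if len(fields) < 3:
        raise RecordError("BED record needs at least 3 columns", lineno)
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise RecordError(f"non-integer coordinates in {fields[:3]}", lineno)
    name = fields[3] if len(fields) > 3 else None
    strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
    if not (0 <= start < end):
        raise RecordError(f"invalid interval {chrom}:{start}-{end}", lineno)
    return GenomicRegion(chrom, start, end, strand, name)


def read_regions(path, format: str | None = None) -> list[GenomicRegion]:
    """Read genomic regions from a BED or CSV feature file.

    BED is 0-based half-open (columns chrom, start, end[, name, score,
    strand]). CSV needs chrom/start/end headers and is interpreted 1-based
    inclusive, converted internally. The format is inferred from the file
    extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "CSV" if path.suffix.lower() == ".csv" else "BED"
    format = format.upper()
    if format == "BED":
        regions = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                regions.append(_region_from_bed_fields(line.split("\t"), lineno))
        return regions
    if format == "CSV":
        df = pd.read_csv(path)
        missing = [c for c in REGION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"CSV region file lacks columns {missing}")
        regions = []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            start1, end1 = int(getattr(row, "start")), int(getattr(row, "end"))
            if start1 < 1 or end1 < start1:
                raise RecordError(
                    f"invalid 1-based interval {start1}-{end1}", i
                )
            regions.append(
                GenomicRegion(
                    str(getattr(row, "chrom")),
                    start1 - 1,  # 1-based inclusive -> 0-based half-open
                    end1,
                    getattr(row, "strand", "."),
                    str(getattr(row, "id")) if hasattr(row, "id") else None,
                )
            )
        return regions
    raise FormatError(f"unknown region format {format!r}")


def regions_to_table(regions: Iterable[GenomicRegion]) -> Table:
    """Region list as a workspace table with chrom/start/end columns."""
    regions = list(regions)
    return Table.from_dict(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "id": [r.id if r.id is not None else f"region_{i}"
                   for i, r in enumerate(regions)],
            "strand": [r.strand for r in regions],
        }
    )


def table_to_regions(table: Table) -> list[GenomicRegion]:
    for col in REGION_COLUMNS:
        if col not in table:
            raise SchemaError(f"table lacks coordinate column {col!r}")
    ids = table.column_values("id") if "id" in table else [None] * table.n
    strands = table.column_values("strand") if "strand" in table else ["."] * table.n
    return [
        GenomicRegion(str(c), int(s), int(e), str(st), i if i is None else str(i))
        for c, s, e, st, i in zip(
            table.column_values("chrom"),
            table.column_values("start"),
            table.column_values("end"),
            strands,
            ids,
        )
    ]


# ---------------------------------------------------------------------------
# WIG I/O


def read_wig(source) -> SignalTrack:
    """Parse WIG text (fixedStep and variableStep) into a signal track.

    WIG coordinates are 1-based with an optional ``span`` (default 1);
    converted to 0-based half-open runs. Overlapping spans within one
    declaration are last-writer-wins. Data before any declaration line is a
    format error.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text(encoding="utf-8")
    elif isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = str(source)

    track = SignalTrack()
    mode: str | None = None
    chrom = ""
    pos = 0  # next 0-based start for fixedStep
    step = 1
    span = 1

    def parse_decl(line: str, lineno: int) -> dict[str, str]:
        out = {}
        for tok in line.split()[1:]:
            if "=" not in tok:
                raise RecordError(f"bad declaration token {tok!r}", lineno)
            k, v = tok.split("=", 1)
            out[k] = v
        return out

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("fixedStep"):
            opts = parse_decl(line, lineno)
            try:
                chrom = opts["chrom"]
                pos = int(opts["start"]) - 1  # 1-based -> 0-based
            except KeyError as exc:
                raise RecordError(f"fixedStep needs {exc} attribute", lineno)
            step = int(opts.get("step", 1))
            span = int(opts.get("span", 1))
            mode = "fixed"
            continue
        if line.startswith("variableStep"):
            opts = parse_decl(line, lineno)
            try:
                chrom = opts["chrom"]
            except KeyError as exc:
                raise RecordError(f"variableStep needs {exc} attribute", lineno)
            span = int(opts.get("span", 1))
            mode = "variable"
            continue
        if mode is None:
            raise FormatError(
                f"data at line {lineno} before any fixedStep/variableStep declaration"
            )
        fields = line.split()
        if mode == "fixed":
            track.add_run(chrom, pos, pos + span, float(fields[0]))
            pos += step
        else:
            if len(fields) != 2:
                raise RecordError("variableStep data needs 'position value'", lineno)
            start = int(fields[0]) - 1
            track.add_run(chrom, start, start + span, float(fields[1]))
    return track.finalize()


def write_wig(track: SignalTrack, path=None) -> str:
    """Serialize a track as variableStep WIG (span-1 runs expanded);
    round-trips through :func:`read_wig` value-for-value."""
    lines: list[str] = []
    for chrom in sorted(track.runs):
        lines.append(f"variableStep chrom={chrom} span=1")
        for s, e, v in track.runs[chrom]:
            for base in range(s, e):
                lines.append(f"{base + 1} {v:g}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Alignment coverage (thin adapter; SAM/BAM through pysam)


def coverage_from_alignments(path, chroms: Sequence[str] | None = None) -> SignalTrack:
    """Per-base read coverage from a SAM/BAM file as a signal track.

    Coverage counts reads overlapping each base. ``total_reads`` is the
    number of mapped reads, so RPKM over such a track divides by a true
    read total.
    """
    import pysam

    track = SignalTrack()
    n_reads = 0
    with pysam.AlignmentFile(str(path)) as af:
        events: dict[str, dict[int, int]] = {}
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            n_reads += 1
            delta = events.setdefault(read.reference_name, {})
            delta[read.reference_start] = delta.get(read.reference_start, 0) + 1
            delta[read.reference_end] = delta.get(read.reference_end, 0) - 1
        for chrom, delta in events.items():
            if chroms is not None and chrom not in chroms:
                continue
            depth = 0
            prev = None
            for position in sorted(delta):
                if prev is not None and depth > 0:
                    track.add_run(chrom, prev, position, depth)
                depth += delta[position]
                prev = position
    track.total_reads = n_reads
    return track.finalize()


# ---------------------------------------------------------------------------
# Summaries and normalizations

SUMMARY_STATS = ("sum", "mean", "max", "count_nonzero")


def summarize_region(track: SignalTrack, region: GenomicRegion, stat: str = "sum") -> float:
    """Summarize track signal over the bases of a region.

    Bases without signal contribute 0; ``mean`` divides by the region
    length; strand is ignored. A region on an absent chromosome summarizes
    to 0 (0 mean).
    """
    if stat not in SUMMARY_STATS:
        raise ValueError(f"unknown stat {stat!r}; choose from {SUMMARY_STATS}")
    total = 0.0
    peak = 0.0
    nonzero = 0
    covered = 0
    for s, e, v in track.runs.get(region.chrom, []):
        lo, hi = max(s, region.start), min(e, region.end)
        if lo >= hi:
            continue
        width = hi - lo
        covered += width
        total += v * width
        peak = max(peak, v)
        if v != 0:
            nonzero += width
    if stat == "sum":
        return total
    if stat == "mean":
        return total / region.length
    if stat == "max":
        return peak if covered else 0.0
    return float(nonzero)


def rpkm(region_signal: float, region_length: int, total_mapped: float) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_length <= 0:
        raise DomainError("region length must be positive")
    if total_mapped <= 0:
        raise DomainError("total mapped reads must be positive")
    return region_signal / ((region_length / 1e3) * (total_mapped / 1e6))


def allelic_contribution(allele_count: float, other_count: float) -> float:
    """Fraction of allele-assignable reads on one haplotype: a / (a + b).

    Returns NaN when neither haplotype has any reads (undefined ratio).
    """
    if allele_count < 0 or other_count < 0:
        raise DomainError("read counts must be non-negative")
    total = allele_count + other_count
    if total == 0:
        return float("nan")
    return allele_count / total


def build_data_column(
    table: Table,
    track: SignalTrack,
    stat: str = "sum",
    normalization: str = "none",
) -> np.ndarray:
    """One summary value per region row of a coordinate table.

    ``normalization="rpkm"`` rescales each per-region value by region
    length and the track total (``total_reads`` when the track came from
    alignments, else the total signal). The result attaches to a table via
    ``Workspace.apply_output``.
    """
    if normalization not in ("none", "rpkm"):
        raise ValueError(f"unknown normalization {normalization!r}")
    regions = table_to_regions(table)
    values = np.array([summarize_region(track, r, stat) for r in regions])
    if normalization == "rpkm":
        total = track.total_reads if track.total_reads else track.total_signal
        if total <= 0:
            raise DomainError("cannot RPKM-normalize an empty track")
        values = np.array(
            [rpkm(v, r.length, total) for v, r in zip(values, regions)]
        )
    return values
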