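"""Summarize genomic signal over regions; RPKM and allelic contribution.

Generates a WIG signal track with a matching BED region file, attaches
per-region sums as a data column, normalizes them to RPKM (reads per
kilobase per million), and computes the allelic-contribution fraction
a/(a+b) for a pair of haplotype read counts.
"""

import io

from tabbench import allelic_contribution, read_wig
from tabbench.fixtures import GenomeConfig, gen_track_and_regions
from tabbench.genomics import GenomicRegion, build_data_column, regions_to_table

wig_text, bed_text, oracle = gen_track_and_regions(GenomeConfig(seed=0))
track = read_wig(wig_text)
print(f"track: {len(track.runs)} chromosomes, total signal {track.total_signal:g}")

regions = [
    GenomicRegion(r.chrom, r.start, r.end, ".", r.id) for r in oracle.itertuples()
]
table = regions_to_table(regions)
table.set_column("signal_sum", build_data_column(table, track, "sum"))
table.set_column(
    "signal_rpkm", build_data_column(table, track, "sum", normalization="rpkm")
)
print(table.df[["id", "chrom", "start", "end", "signal_sum", "signal_rpkm"]]
      .round(3).to_string(index=False))

# allelic contribution: fraction of allele-assignable reads on one haplotype
for cast, b6 in ((50, 50), (90, 10), (10, 0)):
    print(f"CAST={cast:3d} B6={b6:3d} -> contribution "
          f"{allelic_contribution(cast, b6):.2f}")
# 0.5 is balanced bi-allelic expression; 1.0 is mono-allelic. RPKM values
# here use the track's total signal as the library-size denominator.
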