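"""Venn region cardinalities and area-proportional Euler layouts.

Compares the up-regulated gene sets called by two methods, counts every
inclusion/exclusion region, and lays the sets out twice: as a fixed
symmetric Venn template (counts as labels) and as an approximate
area-proportional Euler diagram (circle areas match set sizes, overlap
areas optimized toward region counts).
"""

import numpy as np

from tabbench import SetCollection, euler_layout, region_cardinalities, venn_diagram
from tabbench.setops import mask_label

rng = np.random.default_rng(0)
universe = np.arange(500)
method_a = set(rng.choice(universe, 120, replace=False))
shared = set(rng.choice(sorted(method_a), 70, replace=False))
method_b = shared | set(rng.choice(universe, 40, replace=False))
# method B reproduces 70 of A's calls and adds some of its own

sets = SetCollection.from_dict({"methodA": method_a, "methodB": method_b})
counts = region_cardinalities(sets)
print("region cardinalities:")
for mask, count in sorted(counts.items()):
    print(f"  {mask_label(sets.names, mask):18s} {count}")
print("union size:", sum(counts.values()))

venn = venn_diagram(sets)
print(f"\nVenn template: {len(venn.shapes)} circles, "
      f"{len(venn.region_areas())} drawable regions")

euler = euler_layout(counts, names=sets.names, seed=0)
areas = euler.region_areas(quad_segs=96)
print(f"Euler layout loss: {euler.loss:.4g}")
for mask, target in sorted(counts.items()):
    print(f"  {mask_label(sets.names, mask):18s} target {target:4d} "
          f"achieved area {areas[mask]:7.1f}")
# Achieved region areas track the element counts (1 element = 1 area unit);
# the residual loss is the squared-area mismatch the circle geometry cannot
# remove exactly.
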