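"""Recombination rates and the PAR boundary on the bundled flycatcher map.

The package ships the best-order genetic map of the distal collared
flycatcher Z chromosome (three PAR scaffolds followed by differentiated
scaffolds).  This example reproduces the headline numbers: the 630-kb PAR,
its 64.3-cM female length (102.1 cM/Mb), the 7.3-cM male extension
(11.6 cM/Mb) and the extreme recombination rate of the 67-kb hotspot
interval next to the boundary.
"""

from parscout import datasets
from parscout import linkage as lk

gmap = datasets.distal_z_map()
lengths = datasets.scaffold_lengths()
order = datasets.scaffold_order()

par_bp = lk.region_physical_length([lengths[s] for s in datasets.PAR_SCAFFOLDS], gap_padding=5_000)
par_mb_reported = round(par_bp / 10_000) * 10 / 1_000  # published rounding: 630 kb
print(f"PAR physical length: {par_bp/1000:.1f} kb (reported as {par_mb_reported*1000:.0f} kb)")

boundary = lk.detect_par_boundary(gmap)
print(f"PAR boundary: after {boundary.boundary_marker} (next marker {boundary.next_marker})")
print(f"female map length across the PAR: {boundary.female_span_cm:.1f} cM "
      f"-> {boundary.female_span_cm / par_mb_reported:.1f} cM/Mb")

t = gmap.table.set_index("marker")
male_cm = t.at["N02597:626", "cum_male"]
print(f"male map extension across the PAR: {male_cm:.1f} cM "
      f"-> {male_cm / par_mb_reported:.1f} cM/Mb")

hot = lk.pair_rate(gmap, "N00378:115359", "N02597:626", lengths, order, gap_padding=0)
print(f"hotspot interval {hot.left} .. {hot.right}: {hot.genetic_length:.1f} cM over "
      f"{hot.physical_length/1000:.1f} kb = {hot.rate:.0f} cM/Mb")
# A >700 cM/Mb interval against a 102 cM/Mb regional average: female
# crossovers are concentrated in a narrow hotspot adjacent to the boundary.
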