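"""Clinical-table arithmetic: prevalence, tumor volume, growth inhibition.

Recomputes fusion prevalence percentages from a cancer-type counts
table (rounded half-away-from-zero to one decimal, the style such
tables are printed in) and demonstrates the two xenograft formulas.
"""

from pathlib import Path

from chimeraseq import tumor_growth_inhibition, tumor_volume
from chimeraseq.report import prevalence_table, read_counts_table

counts = read_counts_table(Path(__file__).parent / "data" / "fusion_prevalence_counts.tsv")
table = prevalence_table(counts)
print(table.to_string(index=False))
# e.g. ESCC 66/404 -> 16.3%, HNSCC 58/402 -> 14.4%, BC 0/132 -> 0.0%

v = tumor_volume(5, 8)
print(f"\ntumor volume for diameters a=5 mm, b=8 mm: V = 0.52 a^2 b = {v} mm^3")

tgi = tumor_growth_inhibition(Ti=250, T0=100, Vi=800, V0=200)
print(f"growth inhibition for treated 100->250 vs vehicle 200->800: {tgi:.1f}%")
# 100% means the treated tumors did not grow at all; 0% means they grew
# exactly as fast as the vehicle group.
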