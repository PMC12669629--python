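"""Enumerate the junction library and classify reading frames.

Every exon-boundary junction between the two genes (both orientations:
2 x 12 x 23 = 552 candidates) is classified by CDS phase arithmetic: a
junction is in frame when the donor's coding length and the acceptor's
upstream coding length agree modulo 3, so the chimeric protein retains
the acceptor's C-terminus.
"""

from collections import Counter

from chimeraseq import FixtureConfig, build_fixture, classify_frame, enumerate_junction_library

bundle = build_fixture(FixtureConfig(seed=7))
library = enumerate_junction_library(
    bundle.donor_model,
    bundle.acceptor_model,
    bundle.reference_sequences,
    flank=89,
)
models = {m.gene_id: m for m in (bundle.donor_model, bundle.acceptor_model)}

classes = Counter(
    classify_frame(j, models[j.donor_gene], models[j.acceptor_gene]) for j in library
)
print(f"junction library: {len(library)} candidates")
print(f"frame classes: {dict(classes)}")

for name in ("Pe2Te23", "Pe11Te17", "Pe4Te20"):
    j = next(x for x in library if x.name == name)
    status = classify_frame(j, models[j.donor_gene], models[j.acceptor_gene])
    print(f"{name}: donor exon {j.donor_exon} -> acceptor exon {j.acceptor_exon}: {status}")
# In-frame junctions encode a fusion protein ending with the acceptor's
# conserved C-terminal domain; frameshift junctions truncate after the
# donor portion.
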