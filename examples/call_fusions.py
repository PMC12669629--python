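"""Detect the planted fusion from simulated paired-end reads.

Runs the whole detection chain: QC, mismatch-limited alignment to the
wild-type genome and transcripts, collection of fusion-encompassing
mate pairs, rescue of fusion-spanning reads against the enumerated
junction library (>= 8 bases of overhang on each side), and the
>= 1 spanning + >= 1 encompassing calling rule.
"""

from chimeraseq import FixtureConfig, detect_fusions, generate_fixture

bundle, pairs = generate_fixture(FixtureConfig(seed=7))
result = detect_fusions(
    pairs,
    bundle.genome_references,
    bundle.wildtype_transcripts,
    [bundle.donor_model, bundle.acceptor_model],
)

print(f"read pairs: {result.n_pairs_input} in, {result.n_pairs_kept} after QC")
print(f"pair statuses: {result.pair_status_counts}")
print(f"junction library size: {len(result.junction_library)}")
for call in result.calls:
    print(
        f"call: {call.isoform}  {call.gene_5p} -> {call.gene_3p}  "
        f"spanning={call.n_spanning} encompassing={call.n_encompassing}  "
        f"{call.frame_status}"
    )
# Expect exactly one call, Pe2Te23 — donor exon 2 joined to acceptor
# exon 23 — backed by both evidence types; the frame status says whether
# that junction preserves the acceptor's codon phase.
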