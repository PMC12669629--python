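"""Independent oracles used across the suite.

These deliberately avoid the package's own alignment and frame code:
alignment is re-done as an exhaustive numpy scan, and frame status as a
direct translation of the fused sequence.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from chimeraseq.annotation import reverse_complement


def brute_force_hits(sequence: str, references: dict[str, str], max_mm: int):
    """Every ungapped placement with <= max_mm Hamming mismatches.

    Returns a set of (reference_id, position, strand, mismatches).
    """
    out = set()
    L = len(sequence)
    if L == 0:
        return out
    for strand, q in (("+", sequence), ("-", reverse_complement(sequence))):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        for name, ref in references.items():
            if len(ref) < L:
                continue
            ra = np.frombuffer(ref.upper().encode(), dtype=np.uint8)
            windows = sliding_window_view(ra, L)
            mm = (windows != qa).sum(axis=1)
            for pos in np.flatnonzero(mm <= max_mm):
                out.add((name, int(pos), strand, int(mm[pos])))
    return out


def hit_set(hits):
    """Canonical tuple view of AlignmentHit objects for set comparison."""
    return {(h.reference_id, h.position, h.strand, h.mismatches) for h in hits}


def translated_in_frame(junction, donor_model, acceptor_model, donor_seq, acceptor_seq):
    """Translation oracle: does the fused transcript retain the acceptor's
    C-terminal peptide in the donor's reading frame?

    Translates straight through internal stops, so the verdict is purely
    about codon phase (matching what the arithmetic classifier claims).
    """
    from Bio.Seq import Seq

    cs_d, _ = donor_model.cds_span
    cs_a, ce_a = acceptor_model.cds_span
    e_d = donor_model.exon_end_spliced(junction.donor_exon)
    s_a = acceptor_model.exon_start_spliced(junction.acceptor_exon)
    assert e_d > cs_d and s_a < ce_a, "oracle only defined for coding junctions"
    fused = donor_seq[:e_d] + acceptor_seq[s_a:]
    acceptor_cds_end_fused = e_d + (ce_a - s_a)
    coding = fused[cs_d:acceptor_cds_end_fused]
    coding = coding[: len(coding) // 3 * 3]
    protein = str(Seq(coding).translate())
    acceptor_protein = str(Seq(acceptor_seq[cs_a:ce_a]).translate()).rstrip("*")
    peptide = acceptor_protein[-8:]
    return peptide in protein
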