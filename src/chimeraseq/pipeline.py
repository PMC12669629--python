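"""End-to-end orchestration: QC → align → encompassing → rescue → call."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation import FusionJunction, GeneModel
from .caller import (
    EncompassingEvidence,
    FusionCall,
    GenePair,
    SpanningEvidence,
    build_candidate_library,
    call_fusions,
    collect_encompassing,
    rescue_spanning,
)
from .readproc import (
    CallerParams,
    GeneAnnotation,
    PairAlignment,
    ReadPair,
    ReadRecord,
    ReferenceIndex,
    align_pair,
    qc_filter,
)

__all__ = ["DetectionResult", "detect_fusions"]


@dataclass
class DetectionResult:
    """Everything the detection run produced, evidence included."""

    calls: list[FusionCall]
    n_pairs_input: int
    n_pairs_kept: int
    qc_log: list[tuple[str, str]]
    pair_status_counts: dict[str, int]
    encompassing: dict[GenePair, list[EncompassingEvidence]]
    spanning: list[SpanningEvidence]
    junction_library: list[FusionJunction]
    pair_alignments: list[PairAlignment] = field(repr=False, default_factory=list)


def detect_fusions(
    read_pairs: Sequence[ReadPair],
    genome_references: Mapping[str, str],
    transcript_references: Mapping[str, str],
    models: Sequence[GeneModel],
    params: CallerParams | None = None,
    transcript_to_gene: Mapping[str, str] | None = None,
) -> DetectionResult:
    """Run the full fusion-detection pipeline on mate pairs.

    ``genome_references`` and ``transcript_references`` are the wild-type
    reference sequences (the fusion allele is, by definition, absent from
    the reference).  ``models`` are the wild-type gene models; transcript
    reference names map to genes via ``transcript_to_gene`` (identity by
    default).  The junction library is enumerated only for gene pairs
    with at least one encompassing pair, with flank = read length − 1 so
    any read placement across a junction can be evaluated for overhang.
    """
    params = params or CallerParams()
    annotation = GeneAnnotation(models, transcript_to_gene)
    kept, qc_log = qc_filter(read_pairs, params)

    genome_index = ReferenceIndex(genome_references)
    transcript_index = ReferenceIndex(transcript_references)
    alignments = [
        align_pair(pair, genome_index, transcript_index, annotation, params)
        for pair in kept
    ]
    status_counts = Counter(pa.status for pa in alignments)
    encompassing = collect_encompassing(alignments, annotation)

    candidate_pairs = [pair for pair, evs in encompassing.items() if evs]
    read_length = max((len(p[0].sequence) for p in kept), default=0)
    models_by_id = {m.gene_id: m for m in models}
    library = (
        build_candidate_library(
            candidate_pairs, models_by_id, genome_references, flank=max(1, read_length - 1)
        )
        if candidate_pairs and read_length
        else []
    )

    unmapped: list[ReadRecord] = []
    for pair, pa in zip(kept, alignments):
        for read, hits in zip(pair, (pa.hits_mate1, pa.hits_mate2)):
            if not hits:
                unmapped.append(read)

    spanning = rescue_spanning(unmapped, library, params)
    calls = call_fusions(encompassing, spanning, params, models_by_id, library)
    return DetectionResult(
        calls=calls,
        n_pairs_input=len(read_pairs),
        n_pairs_kept=len(kept),
        qc_log=qc_log,
        pair_status_counts=dict(status_counts),
        encompassing=encompassing,
        spanning=spanning,
        junction_library=library,
        pair_alignments=alignments,
    )
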