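"""The fusion-detection algorithm.

Two complementary kinds of read evidence identify a fusion gene:

* **fusion-encompassing** mate pairs, whose two reads align uniquely to
  two different genes and bracket the junction without crossing it, and
* **fusion-spanning** reads, which fail to map to the genome or the
  reference transcripts and are rescued against an enumerated library of
  candidate exon-boundary junctions, provided they extend at least
  ``min_overhang`` (default 8) bases past the junction point on each side.

A fusion is called when a (gene pair, junction) accumulates at least
``min_spanning`` spanning reads and the gene pair at least
``min_encompassing`` encompassing pairs (defaults 1 and 1).  The junction
library is built only for gene pairs that already have encompassing
evidence, which bounds its size.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import (
    FusionJunction,
    GeneModel,
    classify_frame,
    enumerate_junction_library,
    isoform_name,
)
from .readproc import (
    DISCORDANT_INTERGENE,
    AlignmentHit,
    CallerParams,
    GeneAnnotation,
    PairAlignment,
    ReadRecord,
    ReferenceIndex,
    align_read,
)

__all__ = [
    "EncompassingEvidence",
    "SpanningEvidence",
    "FusionCall",
    "collect_encompassing",
    "build_candidate_library",
    "rescue_spanning",
    "call_fusions",
    "write_fusion_report",
    "read_fusion_report",
]


@dataclass(frozen=True)
class EncompassingEvidence:
    """A mate pair bridging two genes without crossing the junction."""

    pair_id: str
    gene_5p: str
    gene_3p: str
    orientation_confident: bool


@dataclass(frozen=True)
class SpanningEvidence:
    """A read rescued onto one candidate junction with sufficient overhang."""

    read_id: str
    donor_gene: str
    donor_exon: int
    acceptor_gene: str
    acceptor_exon: int
    junction_name: str
    overhang_left: int
    overhang_right: int
    mismatches: int


@dataclass(frozen=True)
class FusionCall:
    """A called fusion isoform with its evidence counts."""

    gene_5p: str
    gene_3p: str
    donor_exon: int
    acceptor_exon: int
    isoform: str
    n_spanning: int
    n_encompassing: int
    frame_status: str
    junction_sequence: str
    orientation_conflict: bool = False


GenePair = frozenset


def collect_encompassing(
    pair_alignments: Sequence[PairAlignment],
    annotation: GeneAnnotation,
) -> dict[GenePair, list[EncompassingEvidence]]:
    """Group discordant inter-gene mate pairs by unordered gene pair.

    Only pairs with status ``discordant_intergene`` contribute (that
    status already excludes multimapped, unmapped and gene-ambiguous
    pairs).  The 5'/3' order is inferred from each mate's strand relative
    to its gene's transcript sense: the mate reading the transcript
    forward sits in the 5' partner.  When the two senses do not resolve an
    order, the pair is kept with lexicographic order and
    ``orientation_confident=False``.
    """
    out: dict[GenePair, list[EncompassingEvidence]] = defaultdict(list)
    for pa in pair_alignments:
        if pa.status != DISCORDANT_INTERGENE:
            continue
        g1, g2 = pa.gene_mate1, pa.gene_mate2
        s1, s2 = pa.sense_mate1, pa.sense_mate2
        if s1 == "+" and s2 == "-":
            gene_5p, gene_3p, confident = g1, g2, True
        elif s1 == "-" and s2 == "+":
            gene_5p, gene_3p, confident = g2, g1, True
        else:
            gene_5p, gene_3p = sorted((g1, g2))
            confident = False
        out[frozenset((g1, g2))].append(
            EncompassingEvidence(pa.pair_id, gene_5p, gene_3p, confident)
        )
    return dict(out)


def build_candidate_library(
    candidate_pairs: Iterable[GenePair],
    models: Mapping[str, GeneModel],
    references: Mapping[str, str],
    flank: int,
) -> list[FusionJunction]:
    """Enumerate junctions (both orientations) per candidate gene pair."""
    library: list[FusionJunction] = []
    seen: set[GenePair] = set()
    for pair in candidate_pairs:
        if pair in seen:
            continue
        seen.add(pair)
        a, b = sorted(pair)
        library.extend(
            enumerate_junction_library(models[a], models[b], references, flank)
        )
    return library


def rescue_spanning(
    unmapped_reads: Sequence[ReadRecord],
    junction_library: Sequence[FusionJunction],
    params: CallerParams,
) -> list[SpanningEvidence]:
    """Align genome/transcript-unmapped reads to the junction library.

    A hit qualifies when the read extends at least ``min_overhang`` bases
    past the junction point on both sides (threshold inclusive: 8 means
    ≥ 8).  Among a read's qualifying hits only the minimal-mismatch
    stratum counts; a read whose best stratum touches two or more distinct
    junctions is discarded rather than multi-counted.
    """
    if not junction_library:
        return []
    by_name = {j.name: j for j in junction_library}
    index = ReferenceIndex({j.name: j.junction_sequence for j in junction_library})
    out: list[SpanningEvidence] = []
    for read in unmapped_reads:
        hits = align_read(read, index, params)
        qualifying: list[tuple[AlignmentHit, int, int]] = []
        for h in hits:
            point = by_name[h.reference_id].junction_point
            left = point - h.position
            right = h.position + h.length - point
            if min(left, right) >= params.min_overhang:
                qualifying.append((h, left, right))
        if not qualifying:
            continue
        best_mm = min(h.mismatches for h, _, _ in qualifying)
        best = [(h, l, r) for h, l, r in qualifying if h.mismatches == best_mm]
        junctions = {h.reference_id for h, _, _ in best}
        if len(junctions) != 1:
            continue
        hit, left, right = best[0]
        j = by_name[hit.reference_id]
        out.append(
            SpanningEvidence(
                read_id=f"{read.read_id}/{read.mate}",
                donor_gene=j.donor_gene,
                donor_exon=j.donor_exon,
                acceptor_gene=j.acceptor_gene,
                acceptor_exon=j.acceptor_exon,
                junction_name=j.name,
                overhang_left=left,
                overhang_right=right,
                mismatches=hit.mismatches,
            )
        )
    return out


def call_fusions(
    encompassing: Mapping[GenePair, Sequence[EncompassingEvidence]],
    spanning: Sequence[SpanningEvidence],
    params: CallerParams,
    models: Mapping[str, GeneModel],
    junction_library: Sequence[FusionJunction] = (),
) -> list[FusionCall]:
    """Apply the ≥ min_spanning + ≥ min_encompassing rule per junction.

    One call per (gene pair, junction) whose spanning count and whose gene
    pair's encompassing count meet the thresholds.  Calls carry the PeXTeY
    isoform name and the CDS-phase frame class, and are sorted by total
    evidence (descending), then name.  A call whose spanning orientation
    contradicts the majority encompassing 5'/3' order is flagged, not
    dropped.
    """
    by_name = {j.name: j for j in junction_library}
    span_by_junction: dict[str, list[SpanningEvidence]] = defaultdict(list)
    for ev in spanning:
        span_by_junction[ev.junction_name].append(ev)

    calls: list[FusionCall] = []
    for name, evs in span_by_junction.items():
        first = evs[0]
        pair = frozenset((first.donor_gene, first.acceptor_gene))
        enc = list(encompassing.get(pair, ()))
        if len(evs) < params.min_spanning or len(enc) < params.min_encompassing:
            continue
        junction = by_name.get(name)
        if junction is None:
            raise ValueError(f"junction {name} missing from the supplied library")
        frame = classify_frame(
            junction, models[first.donor_gene], models[first.acceptor_gene]
        )
        confident_orders = [
            (e.gene_5p, e.gene_3p) for e in enc if e.orientation_confident
        ]
        conflict = bool(confident_orders) and (
            max(
                set(confident_orders), key=confident_orders.count
            ) != (first.donor_gene, first.acceptor_gene)
        )
        calls.append(
            FusionCall(
                gene_5p=first.donor_gene,
                gene_3p=first.acceptor_gene,
                donor_exon=first.donor_exon,
                acceptor_exon=first.acceptor_exon,
                isoform=isoform_name(junction),
                n_spanning=len(evs),
                n_encompassing=len(enc),
                frame_status=frame,
                junction_sequence=junction.junction_sequence,
                orientation_conflict=conflict,
            )
        )
    calls.sort(key=lambda c: (-(c.n_spanning + c.n_encompassing), c.isoform))
    return calls


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "gene_5p",
    "gene_3p",
    "exon_5p",
    "exon_3p",
    "isoform",
    "n_spanning",
    "n_encompassing",
    "frame_status",
    "junction_seq",
]


def write_fusion_report(calls: Sequence[FusionCall], path: str | Path) -> None:
    """TSV report, one row per call, header always present."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "gene_5p": c.gene_5p,
                "gene_3p": c.gene_3p,
                "exon_5p": c.donor_exon,
                "exon_3p": c.acceptor_exon,
                "isoform": c.isoform,
                "n_spanning": c.n_spanning,
                "n_encompassing": c.n_encompassing,
                "frame_status": c.frame_status,
                "junction_seq": c.junction_sequence,
            }
            for c in calls
        ],
        columns=_REPORT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_fusion_report(path: str | Path):
    """Read a fusion report TSV back into a DataFrame."""
    import pandas as pd

    return pd.read_csv(
        path,
        sep="\t",
        dtype={
            "gene_5p": str,
            "gene_3p": str,
            "exon_5p": int,
            "exon_3p": int,
            "isoform": str,
            "n_spanning": int,
            "n_encompassing": int,
            "frame_status": str,
            "junction_seq": str,
        },
    )
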