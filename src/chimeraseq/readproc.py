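"""Read QC and mismatch-limited ungapped alignment.

The detection pipeline only needs a SOAP2-class mapping contract: report
every ungapped placement of a read, on either strand of any reference,
with at most ``max_mismatches`` Hamming mismatches, and flag the
minimal-mismatch stratum.  :func:`align_read` implements that contract
exactly with a seed-and-verify scheme: a placement with ≤ m mismatches
must contain at least one exact segment when the read is cut into m + 1
pieces (pigeonhole), so exact k-mer lookups of the segments enumerate all
candidate placements, which are then verified by direct Hamming count.

``N`` bases count as mismatches, never wildcards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import GeneModel, reverse_complement

__all__ = [
    "ReadRecord",
    "ReadPair",
    "AlignmentHit",
    "CallerParams",
    "PairAlignment",
    "GeneAnnotation",
    "ReferenceIndex",
    "qc_filter",
    "align_read",
    "align_pair",
    "gene_of",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "write_hit_table",
    "DEFAULT_ADAPTER",
]

# Illumina TruSeq read-through adapter
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

PHRED_OFFSET = 33

CONCORDANT = "concordant"
DISCORDANT_INTERGENE = "discordant_intergene"
UNMAPPED = "one_or_both_unmapped"
MULTIMAPPED = "multimapped"
AMBIGUOUS_GENE = "ambiguous_gene"


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read with Phred+33 quality string."""

    read_id: str
    mate: int
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}/{self.mate}: sequence and quality lengths differ"
            )
        if self.mate not in (1, 2):
            raise ValueError(f"{self.read_id}: mate must be 1 or 2")

    def mean_quality(self) -> float:
        if not self.qualities:
            return 0.0
        return sum(ord(c) - PHRED_OFFSET for c in self.qualities) / len(self.qualities)


ReadPair = tuple[ReadRecord, ReadRecord]


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped placement of a read on a reference."""

    reference_id: str
    position: int
    strand: str
    mismatches: int
    length: int
    best: bool = False


@dataclass
class CallerParams:
    """Tunable thresholds of the QC + detection pipeline.

    Defaults carry the published rules: at most 4 mismatches per hit, a
    spanning read must extend at least 8 bases past the junction point on
    each side, and a fusion call needs at least one spanning and one
    encompassing read.  The QC thresholds (mean quality, adapter prefix
    length) are implementation choices exposed here.
    """

    max_mismatches: int = 4
    min_overhang: int = 8
    min_spanning: int = 1
    min_encompassing: int = 1
    min_mean_quality: float = 20.0
    adapter_match_prefix: int = 10
    adapter_sequence: str = DEFAULT_ADAPTER

    def __post_init__(self) -> None:
        for name in (
            "max_mismatches",
            "min_overhang",
            "min_spanning",
            "min_encompassing",
            "adapter_match_prefix",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be >= 0")


@dataclass
class PairAlignment:
    """Joint alignment state of a mate pair against genome + transcripts."""

    pair_id: str
    hits_mate1: list[AlignmentHit]
    hits_mate2: list[AlignmentHit]
    status: str
    gene_mate1: str | None = None
    gene_mate2: str | None = None
    sense_mate1: str | None = None
    sense_mate2: str | None = None


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    pairs: Sequence[ReadPair], params: CallerParams
) -> tuple[list[ReadPair], list[tuple[str, str]]]:
    """Drop read pairs containing adapter or low-quality mates.

    A read is rejected iff it contains the first ``adapter_match_prefix``
    bases of the adapter as an exact substring, or its mean Phred quality
    is below ``min_mean_quality``.  Pairs are dropped whole; the log holds
    one ``(pair_id, reason)`` entry per rejected pair.  Idempotent.
    """
    probe = params.adapter_sequence[: params.adapter_match_prefix]
    kept: list[ReadPair] = []
    log: list[tuple[str, str]] = []
    for pair in pairs:
        reason = None
        for read in pair:
            if probe and probe in read.sequence:
                reason = "adapter"
                break
            if read.mean_quality() < params.min_mean_quality:
                reason = "low_quality"
                break
        if reason is None:
            kept.append(pair)
        else:
            log.append((pair[0].read_id, reason))
    return kept, log


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """Exact k-mer position index over a set of reference sequences.

    Indexes are built lazily per segment length, so one object serves
    reads of any length.
    """

    def __init__(self, references: Mapping[str, str]):
        self.references = {name: seq.upper() for name, seq in references.items()}
        self._kmer_maps: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def kmer_map(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._kmer_maps:
            table: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for name, seq in self.references.items():
                for pos in range(len(seq) - k + 1):
                    table[seq[pos:pos + k]].append((name, pos))
            self._kmer_maps[k] = dict(table)
        return self._kmer_maps[k]


def _segments(length: int, n_parts: int) -> list[tuple[int, int]]:
    """Cut [0, length) into n_parts near-equal non-empty segments."""
    n_parts = min(n_parts, length)
    base, extra = divmod(length, n_parts)
    out = []
    pos = 0
    for i in range(n_parts):
        size = base + (1 if i < extra else 0)
        out.append((pos, pos + size))
        pos += size
    return out


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count, short-circuiting past ``limit``."""
    count = 0
    for x, y in zip(a, b):
        if x != y:
            count += 1
            if count > limit:
                return count
    return count


def align_read(
    read: ReadRecord,
    references: Mapping[str, str] | ReferenceIndex,
    params: CallerParams,
) -> list[AlignmentHit]:
    """All ungapped placements of a read with ≤ max_mismatches mismatches.

    Both strands of every reference are scanned; hits in the
    minimal-mismatch stratum carry ``best=True``.  Ordering is
    deterministic: (reference_id, position, strand).
    """
    index = references if isinstance(references, ReferenceIndex) else ReferenceIndex(references)
    seq = read.sequence.upper()
    length = len(seq)
    if length == 0:
        return []
    max_mm = params.max_mismatches
    hits: list[AlignmentHit] = []
    for strand, query in (("+", seq), ("-", reverse_complement(seq))):
        candidates: set[tuple[str, int]] = set()
        for seg_start, seg_end in _segments(length, max_mm + 1):
            kmer = query[seg_start:seg_end]
            table = index.kmer_map(seg_end - seg_start)
            for ref_name, pos in table.get(kmer, ()):
                start = pos - seg_start
                if 0 <= start <= len(index.references[ref_name]) - length:
                    candidates.add((ref_name, start))
        for ref_name, start in candidates:
            ref = index.references[ref_name]
            mm = _hamming(query, ref[start:start + length], max_mm)
            if mm <= max_mm:
                hits.append(
                    AlignmentHit(
                        reference_id=ref_name,
                        position=start,
                        strand=strand,
                        mismatches=mm,
                        length=length,
                    )
                )
    if not hits:
        return []
    best_mm = min(h.mismatches for h in hits)
    hits = [
        AlignmentHit(
            reference_id=h.reference_id,
            position=h.position,
            strand=h.strand,
            mismatches=h.mismatches,
            length=h.length,
            best=(h.mismatches == best_mm),
        )
        for h in hits
    ]
    hits.sort(key=lambda h: (h.reference_id, h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Gene assignment and pair classification
# ---------------------------------------------------------------------------

class GeneAnnotation:
    """Gene models plus the transcript-reference → gene mapping.

    By convention each gene's transcript reference is named after its
    ``gene_id``; an explicit mapping can override that.
    """

    def __init__(
        self,
        models: Sequence[GeneModel],
        transcript_to_gene: Mapping[str, str] | None = None,
    ):
        self.models = list(models)
        self.by_gene = {m.gene_id: m for m in self.models}
        if transcript_to_gene is None:
            transcript_to_gene = {m.gene_id: m.gene_id for m in self.models}
        for tx, gene in transcript_to_gene.items():
            if gene not in self.by_gene:
                raise ValueError(
                    f"transcript reference {tx!r} maps to unknown gene {gene!r}"
                )
        self.transcript_to_gene = dict(transcript_to_gene)
        self._exons_by_ref: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
        for m in self.models:
            for s, e in m.exons:
                self._exons_by_ref[m.reference_name].append((s, e, m.gene_id))

    def genes_overlapping(self, hit: AlignmentHit) -> frozenset[str]:
        """Genes whose exons overlap a hit by ≥ 1 base (genomic or transcript)."""
        if hit.reference_id in self.transcript_to_gene:
            return frozenset({self.transcript_to_gene[hit.reference_id]})
        out = set()
        lo, hi = hit.position, hit.position + hit.length
        for s, e, gene in self._exons_by_ref.get(hit.reference_id, ()):
            if s < hi and lo < e:
                out.add(gene)
        return frozenset(out)

    def strand_of(self, gene_id: str) -> str:
        return self.by_gene[gene_id].strand


def gene_of(hit: AlignmentHit, annotation: GeneAnnotation) -> str | None:
    """Owning gene of a hit, or None for intergenic/intronic placements.

    Transcript hits resolve to their owning gene; genomic hits to the gene
    whose exon overlaps them by ≥ 1 base.  Returns None when no gene (or
    more than one — use :meth:`GeneAnnotation.genes_overlapping` for the
    full set) matches.
    """
    genes = annotation.genes_overlapping(hit)
    if len(genes) == 1:
        return next(iter(genes))
    return None


def _mate_summary(
    genome_hits: list[AlignmentHit],
    transcript_hits: list[AlignmentHit],
    annotation: GeneAnnotation,
) -> tuple[bool, bool, frozenset[str], str | None, str | None]:
    """(mapped, multimapped, genes, unique gene, transcript-sense strand)."""
    best_g = [h for h in genome_hits if h.best]
    best_t = [h for h in transcript_hits if h.best]
    mapped = bool(genome_hits or transcript_hits)
    multimapped = len(best_g) >= 2 or len(best_t) >= 2
    genes: set[str] = set()
    for h in best_g + best_t:
        genes |= annotation.genes_overlapping(h)
    gene = next(iter(genes)) if len(genes) == 1 else None
    sense = None
    if gene is not None:
        hit = best_t[0] if best_t else best_g[0]
        if hit.reference_id in annotation.transcript_to_gene:
            sense = hit.strand
        else:
            sense = "+" if hit.strand == annotation.strand_of(gene) else "-"
    return mapped, multimapped, frozenset(genes), gene, sense


def align_pair(
    pair: ReadPair,
    genome_index: ReferenceIndex,
    transcript_index: ReferenceIndex,
    annotation: GeneAnnotation,
    params: CallerParams,
) -> PairAlignment:
    """Align both mates and classify the pair.

    Classification precedence: multimapped (either mate has ≥ 2
    best-stratum hits within one reference space) > one_or_both_unmapped >
    ambiguous_gene (a mate's best hits overlap exons of > 1 gene) >
    discordant_intergene (two distinct uniquely-assigned genes) >
    concordant (same gene, or uninformative gene-less placements).
    """
    r1, r2 = pair
    g1 = align_read(r1, genome_index, params)
    t1 = align_read(r1, transcript_index, params)
    g2 = align_read(r2, genome_index, params)
    t2 = align_read(r2, transcript_index, params)
    mapped1, multi1, genes1, gene1, sense1 = _mate_summary(g1, t1, annotation)
    mapped2, multi2, genes2, gene2, sense2 = _mate_summary(g2, t2, annotation)

    if multi1 or multi2:
        status = MULTIMAPPED
    elif not (mapped1 and mapped2):
        status = UNMAPPED
    elif len(genes1) > 1 or len(genes2) > 1:
        status = AMBIGUOUS_GENE
    elif gene1 is not None and gene2 is not None and gene1 != gene2:
        status = DISCORDANT_INTERGENE
    else:
        status = CONCORDANT

    return PairAlignment(
        pair_id=r1.read_id,
        hits_mate1=g1 + t1,
        hits_mate2=g2 + t2,
        status=status,
        gene_mate1=gene1,
        gene_mate2=gene2,
        sense_mate1=sense1,
        sense_mate2=sense2,
    )


# ---------------------------------------------------------------------------
# FASTQ I/O and hit dumps
# ---------------------------------------------------------------------------

def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Load mate pairs from two Phred+33 FASTQ files, matched by order."""
    from Bio import SeqIO

    def load(path: str | Path, mate: int) -> list[ReadRecord]:
        out = []
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = "".join(
                chr(q + PHRED_OFFSET) for q in rec.letter_annotations["phred_quality"]
            )
            rid = rec.id.split("/")[0]
            out.append(ReadRecord(rid, mate, str(rec.seq), quals))
        return out

    mates1 = load(path1, 1)
    mates2 = load(path2, 2)
    if len(mates1) != len(mates2):
        raise ValueError("FASTQ mate files differ in read count")
    for a, b in zip(mates1, mates2):
        if a.read_id != b.read_id:
            raise ValueError(f"mate ids out of sync: {a.read_id} vs {b.read_id}")
    return list(zip(mates1, mates2))


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r1, r2 in pairs:
            f1.write(f"@{r1.read_id}/1\n{r1.sequence}\n+\n{r1.qualities}\n")
            f2.write(f"@{r2.read_id}/2\n{r2.sequence}\n+\n{r2.qualities}\n")


def write_hit_table(
    hits_by_read: Mapping[str, Sequence[AlignmentHit]], path: str | Path
) -> None:
    """SAM-flavored TSV dump of hits (read_id, ref, pos, strand, NM, best)."""
    with open(path, "w") as fh:
        fh.write("read_id\treference\tposition\tstrand\tmismatches\tbest\n")
        for read_id in sorted(hits_by_read):
            for h in hits_by_read[read_id]:
                fh.write(
                    f"{read_id}\t{h.reference_id}\t{h.position}\t{h.strand}"
                    f"\t{h.mismatches}\t{int(h.best)}\n"
                )
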