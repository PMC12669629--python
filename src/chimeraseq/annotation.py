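"""Gene-model arithmetic for fusion-transcript analysis.

A :class:`GeneModel` is one transcript isoform of a gene: an ordered exon
chain on a reference sequence plus an optional CDS span given in *spliced*
transcript coordinates.  On top of it this module provides

* GTF round-trip I/O (1-based inclusive on disk, 0-based half-open in
  memory),
* spliced-sequence extraction,
* exhaustive enumeration of exon-boundary fusion junctions between two
  genes (the candidate "junction library" that spanning reads are rescued
  against),
* the PeXTeY isoform nomenclature (first letter of each gene symbol plus
  the fused exon indices, e.g. ``Pe2Te23``), and
* reading-frame classification of a fusion junction from CDS phase
  arithmetic.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnnotationError",
    "GtfParseError",
    "FrameClassificationError",
    "GeneModel",
    "FusionJunction",
    "reverse_complement",
    "read_gtf",
    "write_gtf",
    "spliced_sequence",
    "enumerate_junction_library",
    "isoform_name",
    "parse_isoform_name",
    "classify_frame",
    "write_junction_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

IN_FRAME = "in_frame"
FRAMESHIFT = "frameshift"
DONOR_NONCODING = "donor_noncoding"
ACCEPTOR_NONCODING = "acceptor_noncoding"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Invalid gene-model geometry or lookup."""


class GtfParseError(AnnotationError):
    """Malformed or inconsistent GTF content."""


class FrameClassificationError(AnnotationError):
    """Frame classification requested without the needed CDS annotation."""


@dataclass(frozen=True)
class GeneModel:
    """One transcript model of a gene.

    Parameters
    ----------
    gene_id:
        Stable identifier, also used as the transcript reference name.
    symbol:
        Gene symbol; its first letter feeds the isoform nomenclature.
    reference_name:
        Name of the (genomic) reference sequence the exons live on.
    strand:
        ``+`` or ``-``.
    exons:
        ``(start, end)`` pairs in 0-based half-open reference coordinates,
        listed 5'→3' in *transcript* orientation (descending reference
        coordinate for minus-strand genes).
    cds_span:
        ``(start, end)`` in spliced-transcript coordinates (stop codon
        included), or ``None`` for non-coding models.
    """

    gene_id: str
    symbol: str
    reference_name: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 1:
            raise AnnotationError(f"{self.gene_id}: gene model needs at least one exon")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise AnnotationError(f"{self.gene_id}: bad exon interval ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                if s2 < e1:
                    raise AnnotationError(
                        f"{self.gene_id}: exons overlap or are out of order "
                        f"(({s1}, {e1}) then ({s2}, {e2}) on + strand)"
                    )
            else:
                if e2 > s1:
                    raise AnnotationError(
                        f"{self.gene_id}: exons overlap or are out of order "
                        f"(({s1}, {e1}) then ({s2}, {e2}) on - strand)"
                    )
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if not (0 <= cs < ce <= self.spliced_length):
                raise AnnotationError(
                    f"{self.gene_id}: cds_span {self.cds_span} outside "
                    f"[0, {self.spliced_length}]"
                )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_length(self, i: int) -> int:
        """Length of 1-based exon ``i``."""
        s, e = self.exons[i - 1]
        return e - s

    def exon_end_spliced(self, i: int) -> int:
        """Spliced coordinate just past the 3' end of 1-based exon ``i``."""
        if not (1 <= i <= self.exon_count):
            raise AnnotationError(f"{self.gene_id}: exon index {i} out of range")
        return sum(e - s for s, e in self.exons[:i])

    def exon_start_spliced(self, i: int) -> int:
        """Spliced coordinate of the 5' start of 1-based exon ``i``."""
        return self.exon_end_spliced(i) - self.exon_length(i)

    def spliced_offset(self, genomic_pos: int) -> int:
        """Map an exonic genomic position to its spliced-transcript offset."""
        off = 0
        for s, e in self.exons:
            if s <= genomic_pos < e:
                if self.strand == "+":
                    return off + (genomic_pos - s)
                return off + (e - 1 - genomic_pos)
            off += e - s
        raise AnnotationError(
            f"{self.gene_id}: genomic position {genomic_pos} is not exonic"
        )

    def spliced_to_genomic_intervals(self, start: int, end: int) -> list[tuple[int, int]]:
        """Project a spliced interval onto genomic (start, end) intervals.

        Returned intervals are 0-based half-open on the reference, ordered
        along transcript direction.
        """
        if not (0 <= start <= end <= self.spliced_length):
            raise AnnotationError(
                f"{self.gene_id}: spliced interval ({start}, {end}) out of bounds"
            )
        out: list[tuple[int, int]] = []
        off = 0
        for s, e in self.exons:
            length = e - s
            lo = max(start, off)
            hi = min(end, off + length)
            if lo < hi:
                if self.strand == "+":
                    out.append((s + (lo - off), s + (hi - off)))
                else:
                    out.append((e - (hi - off), e - (lo - off)))
            off += length
        return out


def spliced_sequence(model: GeneModel, references: Mapping[str, str]) -> str:
    """Concatenate a model's exon sequences in transcript orientation.

    Minus-strand exons are reverse-complemented individually; exons are
    already listed 5'→3' in transcript order.
    """
    if model.reference_name not in references:
        raise AnnotationError(
            f"{model.gene_id}: reference {model.reference_name!r} not provided"
        )
    ref = references[model.reference_name]
    parts = []
    for s, e in model.exons:
        if e > len(ref):
            raise AnnotationError(
                f"{model.gene_id}: exon ({s}, {e}) exceeds reference "
                f"{model.reference_name!r} length {len(ref)}"
            )
        chunk = ref[s:e]
        parts.append(reverse_complement(chunk) if model.strand == "-" else chunk)
    return "".join(parts)


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _attr_first(attrs, key: str, default: str | None = None) -> str | None:
    vals = attrs.get(key)
    if not vals:
        return default
    return vals[0]


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF file into :class:`GeneModel` objects.

    One model per ``transcript_id``; exon order follows ``exon_number``
    when present, otherwise strand-aware coordinate order.  CDS features
    are merged into a spliced-coordinate ``cds_span``.
    """
    import gffutils

    path = Path(path)
    has_features = False
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                has_features = True
                break
    if not has_features:
        return []

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons_by_tx: dict[str, list] = defaultdict(list)
    cds_by_tx: dict[str, list] = defaultdict(list)
    meta: dict[str, tuple[str, str, str, str]] = {}

    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        tx = _attr_first(feat.attributes, "transcript_id")
        gene = _attr_first(feat.attributes, "gene_id", tx)
        if tx is None:
            raise GtfParseError(f"{path}: {feat.featuretype} feature lacks transcript_id")
        symbol = _attr_first(feat.attributes, "gene_name", gene)
        meta.setdefault(tx, (gene, symbol, feat.seqid, feat.strand))
        interval = (feat.start - 1, feat.end)  # 1-based inclusive -> 0-based half-open
        if feat.featuretype == "exon":
            num = _attr_first(feat.attributes, "exon_number")
            exons_by_tx[tx].append((interval, int(num) if num is not None else None))
        else:
            cds_by_tx[tx].append(interval)

    models: list[GeneModel] = []
    for tx, exon_items in exons_by_tx.items():
        gene, symbol, seqid, strand = meta[tx]
        if all(num is not None for _, num in exon_items):
            exon_items.sort(key=lambda item: item[1])
        else:
            exon_items.sort(key=lambda item: item[0][0], reverse=(strand == "-"))
        exons = tuple(iv for iv, _ in exon_items)
        _check_exon_overlap(exons, strand, tx, path)
        model = GeneModel(
            gene_id=gene,
            symbol=symbol,
            reference_name=seqid,
            strand=strand,
            exons=exons,
        )
        if tx in cds_by_tx:
            lo, hi = None, None
            for gs, ge in cds_by_tx[tx]:
                a = model.spliced_offset(gs)
                b = model.spliced_offset(ge - 1)
                s_lo, s_hi = min(a, b), max(a, b) + 1
                lo = s_lo if lo is None else min(lo, s_lo)
                hi = s_hi if hi is None else max(hi, s_hi)
            model = replace(model, cds_span=(lo, hi))
        models.append(model)
    models.sort(key=lambda m: (m.reference_name, m.exons[0][0], m.gene_id))
    return models


def _check_exon_overlap(
    exons: Sequence[tuple[int, int]], strand: str, tx: str, path: Path
) -> None:
    order = sorted(exons)
    for (s1, e1), (s2, e2) in zip(order, order[1:]):
        if s2 < e1:
            lineno = _find_exon_line(path, tx, (s2, e2))
            raise GtfParseError(
                f"{path}:{lineno}: overlapping exons in transcript {tx!r}: "
                f"({s1}, {e1}) and ({s2}, {e2})"
            )
    _ = strand


def _find_exon_line(path: Path, tx: str, interval: tuple[int, int]) -> int:
    want_start, want_end = interval[0] + 1, interval[1]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "exon":
                continue
            if int(cols[3]) == want_start and int(cols[4]) == want_end and tx in cols[8]:
                return lineno
    return 0


def write_gtf(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (gene/transcript/exon/CDS features)."""
    lines = []
    for m in models:
        span_lo = min(s for s, _ in m.exons)
        span_hi = max(e for _, e in m.exons)
        attrs = f'gene_id "{m.gene_id}"; gene_name "{m.symbol}";'
        tx_attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}"; gene_name "{m.symbol}";'
        lines.append(_gtf_line(m.reference_name, "gene", span_lo, span_hi, m.strand, attrs))
        lines.append(_gtf_line(m.reference_name, "transcript", span_lo, span_hi, m.strand, tx_attrs))
        for i, (s, e) in enumerate(m.exons, start=1):
            lines.append(
                _gtf_line(
                    m.reference_name, "exon", s, e, m.strand,
                    tx_attrs + f' exon_number "{i}";',
                )
            )
        if m.cds_span is not None:
            for s, e in m.spliced_to_genomic_intervals(*m.cds_span):
                lines.append(_gtf_line(m.reference_name, "CDS", s, e, m.strand, tx_attrs))
    Path(path).write_text("".join(lines))


def _gtf_line(seqid: str, feature: str, start0: int, end0: int, strand: str, attrs: str) -> str:
    return (
        f"{seqid}\tchimeraseq\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"
    )


# ---------------------------------------------------------------------------
# Junction library and nomenclature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionJunction:
    """A candidate exon-boundary fusion junction.

    ``junction_sequence`` is up to ``flank`` spliced bases ending at the
    donor exon's 3' end followed by up to ``flank`` spliced bases starting
    at the acceptor exon's 5' start; ``junction_point`` is the offset of
    the joint within that sequence (i.e. the donor-side length).
    """

    donor_gene: str
    donor_exon: int
    acceptor_gene: str
    acceptor_exon: int
    donor_symbol: str
    acceptor_symbol: str
    name: str
    junction_sequence: str
    junction_point: int
    flank: int
    frame_status: str | None = None


def isoform_name(junction: FusionJunction) -> str:
    """PeXTeY-style name: first symbol letter + 'e' + exon index, twice."""
    if not junction.donor_symbol or not junction.acceptor_symbol:
        raise AnnotationError("isoform_name requires non-empty gene symbols")
    return (
        f"{junction.donor_symbol[0]}e{junction.donor_exon}"
        f"{junction.acceptor_symbol[0]}e{junction.acceptor_exon}"
    )


_NAME_RE = re.compile(r"^(?P<d>\D+)e(?P<i>\d+)(?P<a>\D+)e(?P<j>\d+)$")


def parse_isoform_name(name: str) -> tuple[int, int]:
    """Recover (donor exon, acceptor exon) indices from a PeXTeY name."""
    m = _NAME_RE.match(name)
    if m is None:
        raise AnnotationError(f"unparseable isoform name {name!r}")
    return int(m.group("i")), int(m.group("j"))


def enumerate_junction_library(
    model_a: GeneModel,
    model_b: GeneModel,
    references: Mapping[str, str],
    flank: int,
) -> list[FusionJunction]:
    """Enumerate every exon-boundary junction between two genes.

    Both orientations are produced (A-donor→B-acceptor and B-donor→
    A-acceptor): 2 × |exons(A)| × |exons(B)| junctions.  Flanks are drawn
    from the spliced transcript sequence (crossing each gene's own internal
    splice junctions) and truncated at transcript ends.
    """
    if flank < 1:
        raise AnnotationError("flank must be >= 1")
    seqs = {
        model_a.gene_id: spliced_sequence(model_a, references),
        model_b.gene_id: spliced_sequence(model_b, references),
    }
    out: list[FusionJunction] = []
    for donor, acceptor in ((model_a, model_b), (model_b, model_a)):
        donor_seq = seqs[donor.gene_id]
        acceptor_seq = seqs[acceptor.gene_id]
        for i in range(1, donor.exon_count + 1):
            d_end = donor.exon_end_spliced(i)
            left = donor_seq[max(0, d_end - flank):d_end]
            for j in range(1, acceptor.exon_count + 1):
                a_start = acceptor.exon_start_spliced(j)
                right = acceptor_seq[a_start:a_start + flank]
                junction = FusionJunction(
                    donor_gene=donor.gene_id,
                    donor_exon=i,
                    acceptor_gene=acceptor.gene_id,
                    acceptor_exon=j,
                    donor_symbol=donor.symbol,
                    acceptor_symbol=acceptor.symbol,
                    name=f"{donor.symbol[0]}e{i}{acceptor.symbol[0]}e{j}",
                    junction_sequence=left + right,
                    junction_point=len(left),
                    flank=flank,
                )
                out.append(junction)
    return out


def write_junction_fasta(junctions: Iterable[FusionJunction], path: str | Path) -> None:
    """Dump a junction library as FASTA (id = name, with orientation in it)."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(f">{j.name} {j.donor_gene}:e{j.donor_exon}|{j.acceptor_gene}:e{j.acceptor_exon} point={j.junction_point}\n")
            fh.write(j.junction_sequence + "\n")


# ---------------------------------------------------------------------------
# Frame classification
# ---------------------------------------------------------------------------

def classify_frame(
    junction: FusionJunction,
    donor_model: GeneModel,
    acceptor_model: GeneModel,
) -> str:
    """Classify a fusion junction by CDS phase arithmetic.

    Let ``e_d`` be the donor exon's 3' end and ``s_a`` the acceptor exon's
    5' start, both in spliced coordinates of their own transcripts.  The
    junction is

    * ``donor_noncoding`` when it precedes the donor CDS start (no coding
      donor contribution),
    * ``acceptor_noncoding`` when the acceptor exon starts at/after the
      acceptor CDS end (no acceptor coding tail to preserve),
    * ``in_frame`` when ``(e_d − cds_start_donor) ≡ (s_a − cds_start_acceptor)
      (mod 3)``, i.e. the acceptor's codon phase is preserved in the fused
      reading frame (including translated read-through of any acceptor
      5'UTR bases the fusion retains),
    * ``frameshift`` otherwise.

    This is pure phase arithmetic: stop codons (including the donor's own
    terminator when the junction lies in the donor 3'UTR) are not modeled.
    """
    if donor_model.cds_span is None or acceptor_model.cds_span is None:
        raise FrameClassificationError(
            f"{junction.name}: both models need cds_span for frame classification"
        )
    if donor_model.gene_id != junction.donor_gene or acceptor_model.gene_id != junction.acceptor_gene:
        raise FrameClassificationError(
            f"{junction.name}: models {donor_model.gene_id}/{acceptor_model.gene_id} "
            "do not match the junction's genes"
        )
    cs_d, _ = donor_model.cds_span
    cs_a, ce_a = acceptor_model.cds_span
    e_d = donor_model.exon_end_spliced(junction.donor_exon)
    s_a = acceptor_model.exon_start_spliced(junction.acceptor_exon)
    if e_d <= cs_d:
        return DONOR_NONCODING
    if s_a >= ce_a:
        return ACCEPTOR_NONCODING
    if (e_d - cs_d) % 3 == (s_a - cs_a) % 3:
        return IN_FRAME
    return FRAMESHIFT
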