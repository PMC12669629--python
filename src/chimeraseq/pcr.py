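"""In-silico PCR and genomic breakpoint localization.

Mirrors the two wet-lab confirmation steps of a fusion finding as pure
sequence arithmetic: amplicon prediction from a primer pair by exact
matching (RT-PCR on spliced transcripts, long-range PCR on genomic
templates), and localization of a genomic breakpoint from a chimeric
amplicon by maximal flank extension against the two partner loci, with
microhomology reported as the overlap of the two maximal extensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import GeneModel, reverse_complement

__all__ = [
    "PrimerPair",
    "Amplicon",
    "BreakpointCall",
    "PcrError",
    "BreakpointError",
    "in_silico_pcr",
    "in_silico_rtpcr",
    "localize_breakpoint",
    "read_primer_table",
    "write_amplicon_fasta",
    "write_breakpoint_bed",
]


class PcrError(ValueError):
    """Invalid primer input."""


class BreakpointError(ValueError):
    """Breakpoint localization failed (ambiguous anchors or no chimera)."""


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, each primer 5'→3' on the sense of its strand."""

    forward: str
    reverse: str
    max_product: int = 10000

    def __post_init__(self) -> None:
        for name in ("forward", "reverse"):
            seq = getattr(self, name)
            if len(seq) < 15:
                raise PcrError(f"{name} primer shorter than 15 bases")
            if set(seq) - set("ACGT"):
                raise PcrError(f"{name} primer contains non-ACGT characters")
        if self.max_product < 1:
            raise PcrError("max_product must be >= 1")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product.

    ``start``/``end`` are 0-based half-open template coordinates of the
    product (from the forward primer's 5' end to the reverse primer's 5'
    end, inclusive of both primers); ``strand`` is the template strand the
    forward primer annealed to.  ``label`` marks fusion-junction-crossing
    RT-PCR products with the junction's isoform name.
    """

    template_id: str
    start: int
    end: int
    strand: str
    sequence: str
    label: str | None = None


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    pos = haystack.find(needle)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def in_silico_pcr(
    templates: Mapping[str, str], primers: PrimerPair
) -> list[Amplicon]:
    """Predict all products of a primer pair over a set of templates.

    Exact matching only: a product arises wherever the forward primer
    matches one strand and, downstream of it on the same strand, the
    reverse complement of the reverse primer matches, with total length at
    most ``max_product``.  Both template strands are examined; the product
    sequence is reported on the strand the forward primer annealed to.
    """
    if not templates:
        raise PcrError("no templates supplied")
    fwd, rev = primers.forward, primers.reverse
    rc_rev = reverse_complement(rev)
    out: list[Amplicon] = []
    for name in sorted(templates):
        seq = templates[name].upper()
        n = len(seq)
        # forward primer on the plus strand
        for i in _find_all(seq, fwd):
            for j in _find_all(seq, rc_rev):
                if j < i:
                    continue
                end = j + len(rev)
                if end - i <= primers.max_product:
                    out.append(Amplicon(name, i, end, "+", seq[i:end]))
        # forward primer on the minus strand: reverse primer anneals plus
        for i in _find_all(seq, rev):
            for j in _find_all(seq, reverse_complement(fwd)):
                if j < i:
                    continue
                end = j + len(fwd)
                if end - i <= primers.max_product:
                    out.append(
                        Amplicon(name, i, end, "-", reverse_complement(seq[i:end]))
                    )
    return out


def in_silico_rtpcr(
    transcripts: Mapping[str, str],
    primers: PrimerPair,
    junctions: Mapping[str, tuple[int, str]] | None = None,
) -> list[Amplicon]:
    """In-silico PCR over spliced transcripts, labeling junction crossers.

    ``junctions`` maps a transcript name to (junction position in spliced
    coordinates, isoform name); an amplicon strictly containing that
    position inherits the isoform name as its label.
    """
    amps = in_silico_pcr(transcripts, primers)
    if not junctions:
        return amps
    out = []
    for a in amps:
        label = None
        if a.template_id in junctions:
            point, name = junctions[a.template_id]
            if a.start < point < a.end:
                label = name
        out.append(
            Amplicon(a.template_id, a.start, a.end, a.strand, a.sequence, label)
        )
    return out


@dataclass(frozen=True)
class BreakpointCall:
    """A localized genomic breakpoint.

    ``pos_a`` is the offset in locus A where identity to A ends (end of
    the maximal amplicon prefix match); ``pos_b`` the offset in locus B
    where identity resumes (start of the maximal suffix match).  When the
    two maximal extensions overlap by ``microhomology`` bases the true
    breakpoint is only determined up to that interval:
    donor side in [pos_a − microhomology, pos_a], acceptor side in
    [pos_b, pos_b + microhomology].
    """

    pos_a: int
    pos_b: int
    microhomology: int
    dist_donor_exon: int
    dist_acceptor_exon: int
    locus_a: str
    locus_b: str


def _unique_anchor(locus: str, anchor: str, side: str) -> int:
    hits = _find_all(locus, anchor)
    if len(hits) == 0:
        raise BreakpointError(f"no chimera: {side} anchor absent from its locus")
    if len(hits) > 1:
        raise BreakpointError(f"{side} anchor occurs {len(hits)} times in its locus")
    return hits[0]


def localize_breakpoint(
    amplicon: str,
    locus_a: str,
    locus_b: str,
    annotation: Sequence[GeneModel],
    anchor_length: int = 20,
    locus_a_name: str = "locus_A",
    locus_b_name: str = "locus_B",
) -> BreakpointCall:
    """Locate a genomic breakpoint from a chimeric amplicon.

    The first ``anchor_length`` bases must occur uniquely in locus A and
    the last ``anchor_length`` uniquely in locus B.  The maximal prefix of
    the amplicon matching A and maximal suffix matching B are extended
    from those anchors; their overlap is the junction microhomology, and
    any unexplained middle raises a "no chimera" error.  Distances are
    measured to the nearest annotated exon boundary: donor side to the 3'
    end of the last exon at/ before pos_a, acceptor side to the 5' start
    of the first exon at/after pos_b.
    """
    amplicon = amplicon.upper()
    n = len(amplicon)
    if n < 2 * anchor_length:
        raise BreakpointError("amplicon shorter than two anchors")
    a0 = _unique_anchor(locus_a, amplicon[:anchor_length], "locus A")
    b_anchor = _unique_anchor(locus_b, amplicon[-anchor_length:], "locus B")

    # maximal prefix extension along locus A
    x = anchor_length
    while x < n and a0 + x < len(locus_a) and amplicon[x] == locus_a[a0 + x]:
        x += 1
    # maximal suffix extension along locus B (leftwards)
    y = anchor_length
    while (
        y < n
        and b_anchor - (y - anchor_length) - 1 >= 0
        and amplicon[n - y - 1] == locus_b[b_anchor + anchor_length - y - 1]
    ):
        y += 1
    if x + y < n:
        raise BreakpointError(
            "no chimera: amplicon has a middle segment matching neither locus"
        )
    microhomology = x + y - n
    pos_a = a0 + x
    pos_b = b_anchor + anchor_length - y  # locus B offset of amplicon position n - y

    models_a = [m for m in annotation if m.reference_name == locus_a_name] or list(annotation)
    models_b = [m for m in annotation if m.reference_name == locus_b_name] or list(annotation)
    donor_exon_ends = sorted(
        e for m in models_a for _, e in m.exons if e <= pos_a
    )
    acceptor_exon_starts = sorted(
        s for m in models_b for s, _ in m.exons if s >= pos_b
    )
    dist_donor = pos_a - donor_exon_ends[-1] if donor_exon_ends else pos_a
    dist_acceptor = (
        acceptor_exon_starts[0] - pos_b if acceptor_exon_starts else len(locus_b) - pos_b
    )
    return BreakpointCall(
        pos_a=pos_a,
        pos_b=pos_b,
        microhomology=microhomology,
        dist_donor_exon=dist_donor,
        dist_acceptor_exon=dist_acceptor,
        locus_a=locus_a_name,
        locus_b=locus_b_name,
    )


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_primer_table(path: str | Path) -> dict[str, PrimerPair]:
    """Load primers from a TSV with columns name, forward, reverse, max_product."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.name)] = PrimerPair(
            forward=str(row.forward),
            reverse=str(row.reverse),
            max_product=int(row.max_product),
        )
    return out


def write_amplicon_fasta(amplicons: Iterable[Amplicon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, a in enumerate(amplicons):
            label = f" {a.label}" if a.label else ""
            fh.write(f">amplicon_{k} {a.template_id}:{a.start}-{a.end}({a.strand}){label}\n")
            fh.write(a.sequence + "\n")


def write_breakpoint_bed(calls: Iterable[BreakpointCall], path: str | Path) -> None:
    """BED of breakpoint (ambiguity) intervals on both partner loci."""
    with open(path, "w") as fh:
        for k, c in enumerate(calls):
            fh.write(
                f"{c.locus_a}\t{c.pos_a - c.microhomology}\t{c.pos_a}"
                f"\tbreakpoint_{k}_donor\t{c.microhomology}\t+\n"
            )
            fh.write(
                f"{c.locus_b}\t{c.pos_b}\t{c.pos_b + c.microhomology}"
                f"\tbreakpoint_{k}_acceptor\t{c.microhomology}\t+\n"
            )
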