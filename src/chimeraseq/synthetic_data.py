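"""Synthetic two-gene fusion fixture with per-read ground truth.

Emulates the geometry of a PLEKHA1–TACC2-style rearrangement: a 12-exon
donor gene and a 23-exon acceptor gene on separate loci, plus a fusion
allele in which the donor locus is disrupted a configurable distance
downstream of the fused donor exon (default 3.4 kb after exon 2) and
joined a configurable distance upstream of the fused acceptor exon
(default 2.7 kb before exon 23).  Transcripts (two wild-type, one
chimeric) are spliced from the annotation; paired-end reads are drawn
from the transcripts with ~200 bp fragments, substitution errors, and
optional adapter / low-quality contaminants.  Every read's origin is
recorded in a truth table so downstream stages can be tested against
coordinate arithmetic instead of re-alignment.

All randomness flows from one seeded generator held by the bundle, so a
fixed :class:`FixtureConfig` reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import (
    GeneModel,
    reverse_complement,
    spliced_sequence,
    write_gtf,
)
from .pcr import PrimerPair
from .readproc import DEFAULT_ADAPTER, ReadPair, ReadRecord

__all__ = [
    "FixtureConfig",
    "FixtureConfigError",
    "FixtureBundle",
    "TruthTable",
    "ReadOrigin",
    "PlantedJunction",
    "build_fixture",
    "simulate_read_pairs",
    "inject_artifacts",
    "generate_fixture",
    "write_fixture",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_Q_BASE = chr(35 + 33)   # constant Q35 baseline
_Q_LOW = chr(5 + 33)     # degraded reads


class FixtureConfigError(ValueError):
    """A FixtureConfig field is out of its valid range."""


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic fixture.

    Defaults mirror the emulated assay: 200 bp size-selected fragments,
    a 12-exon donor fused at exon 2 to exon 23 of a 23-exon acceptor,
    with the genomic breakpoint 3400 bases downstream of the donor exon
    and 2700 bases upstream of the acceptor exon.  Read length is an
    implementation choice (90 bases, typical short-read output and more
    than twice the 8-base overhang rule).
    """

    seed: int = 0
    read_length: int = 90
    insert_mean: float = 200.0
    insert_sd: float = 20.0
    coverage: float = 30.0
    error_rate: float = 0.005
    donor_exon_count: int = 12
    acceptor_exon_count: int = 23
    exon_length_range: tuple[int, int] = (120, 300)
    intron_length_range: tuple[int, int] = (3500, 4500)
    fused_donor_exon: int = 2
    fused_acceptor_exon: int = 23
    breakpoint_offset_donor: int = 3400
    breakpoint_offset_acceptor: int = 2700
    fusion_expression_fraction: float = 0.3
    contaminant_fraction: float = 0.02
    adapter_sequence: str = DEFAULT_ADAPTER
    artifact_mode: str = "mixed"   # "adapter" | "lowq" | "mixed"
    junction_microhomology: int = 0
    locus_flank: int = 1500
    donor_symbol: str = "PLEKHA1"
    acceptor_symbol: str = "TACC2"

    def validate(self) -> None:
        if self.read_length < 1:
            raise FixtureConfigError("read_length must be >= 1")
        if self.coverage <= 0:
            raise FixtureConfigError("coverage must be > 0")
        for name in ("error_rate", "fusion_expression_fraction", "contaminant_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise FixtureConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("exon_length_range", "intron_length_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise FixtureConfigError(f"{name} must satisfy 1 <= lo <= hi")
        if self.exon_length_range[0] < 100:
            raise FixtureConfigError("exon_length_range minimum must be >= 100")
        if not (1 <= self.fused_donor_exon <= self.donor_exon_count):
            raise FixtureConfigError(
                f"fused_donor_exon {self.fused_donor_exon} outside "
                f"[1, {self.donor_exon_count}]"
            )
        if not (1 <= self.fused_acceptor_exon <= self.acceptor_exon_count):
            raise FixtureConfigError(
                f"fused_acceptor_exon {self.fused_acceptor_exon} outside "
                f"[1, {self.acceptor_exon_count}]"
            )
        if self.junction_microhomology < 0:
            raise FixtureConfigError("junction_microhomology must be >= 0")
        margin = self.junction_microhomology + 2
        donor_room = (
            self.intron_length_range[0]
            if self.fused_donor_exon < self.donor_exon_count
            else self.locus_flank
        )
        if not (1 <= self.breakpoint_offset_donor <= donor_room - margin):
            raise FixtureConfigError(
                f"breakpoint_offset_donor {self.breakpoint_offset_donor} does not fit "
                f"strictly inside the flanking intron/flank (room {donor_room})"
            )
        acceptor_room = (
            self.intron_length_range[0]
            if self.fused_acceptor_exon > 1
            else self.locus_flank
        )
        if not (1 <= self.breakpoint_offset_acceptor <= acceptor_room - margin):
            raise FixtureConfigError(
                f"breakpoint_offset_acceptor {self.breakpoint_offset_acceptor} does not "
                f"fit strictly inside the flanking intron/flank (room {acceptor_room})"
            )
        if self.artifact_mode not in {"adapter", "lowq", "mixed"}:
            raise FixtureConfigError(f"unknown artifact_mode {self.artifact_mode!r}")


@dataclass(frozen=True)
class PlantedJunction:
    donor_gene: str
    donor_exon: int
    acceptor_gene: str
    acceptor_exon: int
    name: str


@dataclass
class ReadOrigin:
    source: str
    start: int
    strand: str
    n_errors: int
    artifact: bool = False


@dataclass
class TruthTable:
    planted_junction: PlantedJunction
    planted_breakpoint: tuple[int, int]
    reads: dict[str, ReadOrigin] = field(default_factory=dict)


@dataclass
class FixtureBundle:
    """Everything the fixture knows about itself."""

    config: FixtureConfig
    reference_sequences: dict[str, str]
    annotation: list[GeneModel]
    transcripts: dict[str, str]
    truth: TruthTable
    primers: dict[str, PrimerPair]
    breakpoint_pos_a: int
    breakpoint_pos_b: int
    junction_spliced_pos: int
    rng: np.random.Generator = field(repr=False, default=None)

    @property
    def donor_model(self) -> GeneModel:
        return self.annotation[0]

    @property
    def acceptor_model(self) -> GeneModel:
        return self.annotation[1]

    @property
    def chimera_model(self) -> GeneModel:
        return self.annotation[2]

    @property
    def genome_references(self) -> dict[str, str]:
        """The wild-type loci only — what the detection pipeline aligns to."""
        return {
            m.reference_name: self.reference_sequences[m.reference_name]
            for m in (self.donor_model, self.acceptor_model)
        }

    @property
    def wildtype_transcripts(self) -> dict[str, str]:
        return {
            m.gene_id: self.transcripts[m.gene_id]
            for m in (self.donor_model, self.acceptor_model)
        }

    @property
    def transcript_junctions(self) -> dict[str, tuple[int, str]]:
        """Junction position + isoform name per chimeric transcript."""
        return {
            self.chimera_model.gene_id: (
                self.junction_spliced_pos,
                self.truth.planted_junction.name,
            )
        }


# ---------------------------------------------------------------------------
# Fixture construction
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> bytearray:
    codes = rng.integers(0, 4, size=n)
    table = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    return bytearray(table[codes].tobytes())


def _gene_geometry(
    rng: np.random.Generator, cfg: FixtureConfig, n_exons: int
) -> tuple[list[tuple[int, int]], int]:
    """Exon coordinates and total locus length for one gene."""
    elo, ehi = cfg.exon_length_range
    ilo, ihi = cfg.intron_length_range
    exon_lens = rng.integers(elo, ehi + 1, size=n_exons)
    intron_lens = rng.integers(ilo, ihi + 1, size=max(0, n_exons - 1))
    exons = []
    pos = cfg.locus_flank
    for i, length in enumerate(exon_lens):
        exons.append((pos, pos + int(length)))
        pos += int(length)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    return exons, pos + cfg.locus_flank


def _spliced_to_genomic(model: GeneModel, p: int) -> int:
    """Genomic position of spliced offset ``p`` (plus-strand models)."""
    off = 0
    for s, e in model.exons:
        if p < off + (e - s):
            return s + (p - off)
        off += e - s
    raise ValueError(f"spliced offset {p} out of range")


def _install_cds(
    rng: np.random.Generator, locus: bytearray, model: GeneModel
) -> GeneModel:
    """Pick a CDS span for a plus-strand model and sanitize the codons.

    The CDS starts after a short 5'UTR in exon 1, ends (stop codon
    included) inside the last exon leaving a 3'UTR long enough to place a
    primer, opens with ATG, closes with TAA, and contains no internal stop
    codon (third codon bases of would-be stops are rewritten to C).
    Mutations are written through to the locus sequence.
    """
    spliced_len = model.spliced_length
    utr5 = int(rng.integers(30, 91))
    u3 = int(rng.integers(45, 81))
    cds_start = utr5
    cds_len = (spliced_len - u3) - cds_start
    cds_len -= cds_len % 3
    cds_end = cds_start + cds_len
    if cds_end <= model.exon_start_spliced(model.exon_count) + 3:
        raise FixtureConfigError(
            f"{model.gene_id}: last exon too short to host the CDS end"
        )

    def put(spliced_pos: int, base: str) -> None:
        locus[_spliced_to_genomic(model, spliced_pos)] = ord(base)

    for k, base in enumerate("ATG"):
        put(cds_start + k, base)
    for k, base in enumerate("TAA"):
        put(cds_end - 3 + k, base)
    spliced = spliced_sequence(model, {model.reference_name: locus.decode()})
    for codon_start in range(cds_start + 3, cds_end - 3, 3):
        if spliced[codon_start:codon_start + 3] in _STOPS:
            put(codon_start + 2, "C")
    return dataclasses.replace(model, cds_span=(cds_start, cds_end))


def build_fixture(config: FixtureConfig) -> FixtureBundle:
    """Generate the two-gene locus pair, fusion allele, and transcripts.

    The fusion allele is the exact concatenation of the donor locus prefix
    up to the breakpoint and the acceptor locus suffix from the
    breakpoint; by default one intronic base on each wild-type locus just
    outside that prefix/suffix is adjusted so the junction carries exactly
    ``junction_microhomology`` bases of homology (0 unless configured).
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    donor_exons, len_a = _gene_geometry(rng, cfg, cfg.donor_exon_count)
    acceptor_exons, len_b = _gene_geometry(rng, cfg, cfg.acceptor_exon_count)
    ref_a = f"locus_{cfg.donor_symbol}"
    ref_b = f"locus_{cfg.acceptor_symbol}"
    locus_a = _random_bases(rng, len_a)
    locus_b = _random_bases(rng, len_b)

    donor = GeneModel(
        gene_id=cfg.donor_symbol,
        symbol=cfg.donor_symbol,
        reference_name=ref_a,
        strand="+",
        exons=tuple(donor_exons),
    )
    acceptor = GeneModel(
        gene_id=cfg.acceptor_symbol,
        symbol=cfg.acceptor_symbol,
        reference_name=ref_b,
        strand="+",
        exons=tuple(acceptor_exons),
    )
    donor = _install_cds(rng, locus_a, donor)
    acceptor = _install_cds(rng, locus_b, acceptor)

    # Genomic breakpoint: prefix of locus A ends pos_a, suffix of locus B
    # starts pos_b.
    i, j = cfg.fused_donor_exon, cfg.fused_acceptor_exon
    pos_a = donor.exons[i - 1][1] + cfg.breakpoint_offset_donor
    pos_b = acceptor.exons[j - 1][0] - cfg.breakpoint_offset_acceptor

    # Engineer the junction microhomology on intronic bases that are NOT
    # part of the fusion allele, so the allele stays a pure concatenation.
    k = cfg.junction_microhomology
    if k > 0:
        locus_a[pos_a:pos_a + k] = locus_b[pos_b:pos_b + k]
    if locus_a[pos_a + k] == locus_b[pos_b + k]:
        current = chr(locus_a[pos_a + k])
        locus_a[pos_a + k] = ord(_BASES[(_BASES.index(current) + 1) % 4])
    if locus_b[pos_b - 1] == locus_a[pos_a - 1]:
        current = chr(locus_b[pos_b - 1])
        locus_b[pos_b - 1] = ord(_BASES[(_BASES.index(current) + 1) % 4])

    seq_a = locus_a.decode()
    seq_b = locus_b.decode()
    fusion_allele = seq_a[:pos_a] + seq_b[pos_b:]

    shift = pos_a - pos_b
    chimera_exons = tuple(donor.exons[:i]) + tuple(
        (s + shift, e + shift) for s, e in acceptor.exons[j - 1:]
    )
    chimera_id = f"{cfg.donor_symbol}-{cfg.acceptor_symbol}"
    chimera = GeneModel(
        gene_id=chimera_id,
        symbol=chimera_id,
        reference_name="fusion_allele",
        strand="+",
        exons=chimera_exons,
    )

    references = {ref_a: seq_a, ref_b: seq_b, "fusion_allele": fusion_allele}
    donor_tx = spliced_sequence(donor, references)
    acceptor_tx = spliced_sequence(acceptor, references)
    chimera_tx = spliced_sequence(chimera, references)
    transcripts = {
        cfg.donor_symbol: donor_tx,
        cfg.acceptor_symbol: acceptor_tx,
        chimera_id: chimera_tx,
    }

    # Primers: forward inside the fused donor exon, reverse in the
    # acceptor 3'UTR (within the last exon) — works on both the fusion
    # allele (long-range PCR) and the chimeric transcript (RT-PCR).
    exon_i_sp = donor_tx[donor.exon_start_spliced(i):donor.exon_end_spliced(i)]
    forward = exon_i_sp[10:31]
    ce_a = acceptor.cds_span[1]
    utr_site = acceptor_tx[ce_a + 5:ce_a + 26]
    reverse = reverse_complement(utr_site)
    primers = {"fusion": PrimerPair(forward=forward, reverse=reverse, max_product=50000)}

    name = f"{cfg.donor_symbol[0]}e{i}{cfg.acceptor_symbol[0]}e{j}"
    truth = TruthTable(
        planted_junction=PlantedJunction(
            donor_gene=cfg.donor_symbol,
            donor_exon=i,
            acceptor_gene=cfg.acceptor_symbol,
            acceptor_exon=j,
            name=name,
        ),
        planted_breakpoint=(cfg.breakpoint_offset_donor, cfg.breakpoint_offset_acceptor),
    )
    return FixtureBundle(
        config=cfg,
        reference_sequences=references,
        annotation=[donor, acceptor, chimera],
        transcripts=transcripts,
        truth=truth,
        primers=primers,
        breakpoint_pos_a=pos_a,
        breakpoint_pos_b=pos_b,
        junction_spliced_pos=donor.exon_end_spliced(i),
        rng=rng,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    mask = rng.random(len(seq)) < error_rate
    if not mask.any():
        return seq, 0
    out = list(seq)
    for pos in np.flatnonzero(mask):
        alternatives = [b for b in _BASES if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(out), int(mask.sum())


def simulate_read_pairs(
    bundle: FixtureBundle, config: FixtureConfig | None = None
) -> list[ReadPair]:
    """Draw FR-oriented read pairs from the fixture transcripts.

    Fragments come from the chimeric transcript with probability
    ``fusion_expression_fraction`` and otherwise from the wild-type
    transcripts in proportion to their length; insert length is normal
    (truncated below at the read length); mate 2 is the reverse-complement
    end of the fragment.  The truth table records each read's source,
    start, strand and realized substitution-error count.
    """
    cfg = config or bundle.config
    if cfg.read_length >= cfg.insert_mean:
        raise FixtureConfigError("read_length must be smaller than insert_mean")
    if not bundle.transcripts:
        raise FixtureConfigError("fixture has no transcripts to sample from")
    rng = bundle.rng if bundle.rng is not None else np.random.default_rng(cfg.seed)

    chimera_id = bundle.chimera_model.gene_id
    wt_names = [m.gene_id for m in (bundle.donor_model, bundle.acceptor_model)]
    wt_lengths = np.array([len(bundle.transcripts[n]) for n in wt_names], dtype=float)
    wt_probs = wt_lengths / wt_lengths.sum()

    total_len = sum(len(s) for s in bundle.transcripts.values())
    n_frags = int(round(cfg.coverage * total_len / (2 * cfg.read_length)))

    pairs: list[ReadPair] = []
    L = cfg.read_length
    for idx in range(n_frags):
        if rng.random() < cfg.fusion_expression_fraction:
            source = chimera_id
        else:
            source = wt_names[int(rng.choice(len(wt_names), p=wt_probs))]
        tx = bundle.transcripts[source]
        frag_len = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
        frag_len = max(L, min(frag_len, len(tx)))
        start = int(rng.integers(0, len(tx) - frag_len + 1))
        frag = tx[start:start + frag_len]

        seq1, err1 = _apply_errors(rng, frag[:L], cfg.error_rate)
        seq2, err2 = _apply_errors(rng, reverse_complement(frag)[:L], cfg.error_rate)
        pid = f"frag{idx:06d}"
        r1 = ReadRecord(pid, 1, seq1, _Q_BASE * L)
        r2 = ReadRecord(pid, 2, seq2, _Q_BASE * L)
        bundle.truth.reads[f"{pid}/1"] = ReadOrigin(source, start, "+", err1)
        bundle.truth.reads[f"{pid}/2"] = ReadOrigin(
            source, start + frag_len - L, "-", err2
        )
        pairs.append((r1, r2))
    return pairs


def inject_artifacts(
    pairs: Sequence[ReadPair],
    config: FixtureConfig,
    *,
    rng: np.random.Generator | None = None,
    truth: TruthTable | None = None,
    transcripts: Mapping[str, str] | None = None,
) -> list[ReadPair]:
    """Contaminate a fraction of reads with adapter or low-quality artifacts.

    Each read independently becomes an artifact with probability
    ``contaminant_fraction``: either the adapter is spliced into its
    sequence or its qualities are uniformly degraded (mode per
    ``artifact_mode``).  Truth entries, when provided, get the artifact
    flag and — for adapter reads — a recomputed error count against the
    source span.
    """
    if config.contaminant_fraction <= 0:
        return list(pairs)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    adapter = config.adapter_sequence
    out: list[ReadPair] = []
    for pair in pairs:
        new_pair = []
        for read in pair:
            if rng.random() >= config.contaminant_fraction:
                new_pair.append(read)
                continue
            if config.artifact_mode == "adapter":
                mode = "adapter"
            elif config.artifact_mode == "lowq":
                mode = "lowq"
            else:
                mode = "adapter" if rng.random() < 0.5 else "lowq"
            L = len(read.sequence)
            if mode == "adapter":
                if L > len(adapter):
                    p = int(rng.integers(0, L - len(adapter) + 1))
                else:
                    p = 0
                seq = (read.sequence[:p] + adapter + read.sequence[p + len(adapter):])[:L]
                new_read = ReadRecord(read.read_id, read.mate, seq, read.qualities)
            else:
                new_read = ReadRecord(
                    read.read_id, read.mate, read.sequence, _Q_LOW * L
                )
            new_pair.append(new_read)
            if truth is not None:
                origin = truth.reads.get(f"{read.read_id}/{read.mate}")
                if origin is not None:
                    origin.artifact = True
                    if mode == "adapter" and transcripts is not None:
                        src = transcripts[origin.source]
                        span = src[origin.start:origin.start + L]
                        expected = span if origin.strand == "+" else reverse_complement(span)
                        origin.n_errors = sum(
                            a != b for a, b in zip(new_read.sequence, expected)
                        )
        out.append(tuple(new_pair))
    return out


def generate_fixture(config: FixtureConfig) -> tuple[FixtureBundle, list[ReadPair]]:
    """build_fixture → simulate_read_pairs → inject_artifacts, one seed."""
    bundle = build_fixture(config)
    pairs = simulate_read_pairs(bundle)
    pairs = inject_artifacts(
        pairs,
        config,
        rng=bundle.rng,
        truth=bundle.truth,
        transcripts=bundle.transcripts,
    )
    return bundle, pairs


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _write_fasta(records: Mapping[str, str], path: Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    seqio_write(recs, str(path), "fasta")


def write_fixture(
    bundle: FixtureBundle, pairs: Sequence[ReadPair], outdir: str | Path
) -> dict[str, Path]:
    """Write the fixture to disk; returns the path of every file written.

    Layout: genome.fa (wild-type loci), fusion_allele.fa, transcripts.fa
    (wild-type), chimeric_transcript.fa, annotation.gtf (wild-type
    models), fusion_annotation.gtf (chimeric model), reads_1/2.fastq,
    primers.tsv, truth.tsv, config.json.
    """
    from .readproc import write_fastq_pairs

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "fusion_allele": outdir / "fusion_allele.fa",
        "transcripts": outdir / "transcripts.fa",
        "chimeric_transcript": outdir / "chimeric_transcript.fa",
        "annotation": outdir / "annotation.gtf",
        "fusion_annotation": outdir / "fusion_annotation.gtf",
        "reads_1": outdir / "reads_1.fastq",
        "reads_2": outdir / "reads_2.fastq",
        "primers": outdir / "primers.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    _write_fasta(bundle.genome_references, paths["genome"])
    _write_fasta(
        {"fusion_allele": bundle.reference_sequences["fusion_allele"]},
        paths["fusion_allele"],
    )
    _write_fasta(bundle.wildtype_transcripts, paths["transcripts"])
    chimera_id = bundle.chimera_model.gene_id
    _write_fasta({chimera_id: bundle.transcripts[chimera_id]}, paths["chimeric_transcript"])
    write_gtf([bundle.donor_model, bundle.acceptor_model], paths["annotation"])
    write_gtf([bundle.chimera_model], paths["fusion_annotation"])
    write_fastq_pairs(pairs, paths["reads_1"], paths["reads_2"])
    with open(paths["primers"], "w") as fh:
        fh.write("name\tforward\treverse\tmax_product\n")
        for name, p in bundle.primers.items():
            fh.write(f"{name}\t{p.forward}\t{p.reverse}\t{p.max_product}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("read_id\tsource\tstart\tstrand\tn_errors\tartifact\n")
        for read_id in sorted(bundle.truth.reads):
            o = bundle.truth.reads[read_id]
            fh.write(
                f"{read_id}\t{o.source}\t{o.start}\t{o.strand}\t{o.n_errors}"
                f"\t{int(o.artifact)}\n"
            )
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(bundle.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
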