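# Methods

## The detection model

The caller treats a fusion gene as an event supported by two independent
read classes from a paired-end RNA-seq library:

1. **Encompassing evidence.** After ungapped alignment of every mate to
   the reference genome and the reference transcripts (at most 4
   mismatches per hit, `N` counted as a mismatch), a pair whose mates map
   uniquely to two different genes is discordant-intergenic and nominates
   that gene pair. Pairs with a multi-mapping mate (two or more hits in
   the minimal-mismatch stratum within one reference space), an unmapped
   mate, or a mate overlapping exons of more than one gene are excluded.
2. **Spanning evidence.** For every nominated gene pair, all exon-boundary
   junctions are enumerated in both orientations (donor exon 3' end ×
   acceptor exon 5' start: 2·|exons(A)|·|exons(B)| candidates; 552 for the
   default 12 × 23 fixture). Reads that mapped nowhere are aligned to
   these junction sequences under the same mismatch cap; a hit counts only
   if the read extends at least `min_overhang` = 8 bases past the junction
   point on *each* side (inclusive threshold). A read whose best stratum
   ties across two or more junctions is discarded rather than
   multi-counted.

A fusion is called per (gene pair, junction) when spanning ≥ 1 and the
pair's encompassing count ≥ 1; both thresholds are parameters
(`CallerParams.min_spanning` / `min_encompassing`). Junction flanks are
drawn from spliced transcript sequence with flank = read length − 1, so
every possible read placement across the junction can be scored for
overhang. Because the overhang of a placement is fixed by the read's
composition boundary — junctions sharing a flank give the same overhang —
the 8-base rule also suppresses cross-assignment of short-overhang reads
to neighbouring junctions.

### Alignment

The aligner implements a SOAP2-class contract exactly: every ungapped
placement of the read, on either strand of any reference, with Hamming
distance ≤ `max_mismatches`, with the minimal-mismatch stratum flagged.
It is seed-and-verify: cut into `max_mismatches + 1` near-equal segments,
at least one segment of any qualifying placement is an exact k-mer match
(pigeonhole), so exact k-mer lookups enumerate all candidates, which are
verified by direct Hamming count. The contract is deliberately ungapped
and indel-free — the simulator emits substitution errors only — which
keeps an exhaustive brute-force scan available as an exact test oracle.

Design choices the underlying method leaves open, fixed here and exposed
as parameters: "multiple positions" means ≥ 2 best-stratum hits within a
single reference space (a read hitting the genome once and its transcript
once is not a multi-mapper); intronic-only genomic hits carry no gene
(gene assignment is exon-overlap based, the assay being transcriptomic);
rescue is per-read, not per-pair; spanning rescue reuses the global
mismatch cap.

### QC

A read is rejected if it contains the first 10 bases of the adapter as an
exact substring or its mean Phred quality is below 20; pairs are dropped
whole. Both thresholds are unspecified by the method and exposed in
`CallerParams`. The 10-base prefix keeps the false-positive rate of the
adapter test near 90·4⁻¹⁰ per read; the quality cut merely needs to
separate the simulator's two quality classes (Q35 baseline, Q5 degraded).

## Frame classification

With CDS spans in spliced coordinates, let `e_d` be the donor exon's 3'
end, `s_a` the acceptor exon's 5' start, and `cs_d`, `cs_a`, `ce_a` the
donor CDS start and acceptor CDS start/end. The junction is
`donor_noncoding` if `e_d ≤ cs_d`, `acceptor_noncoding` if `s_a ≥ ce_a`,
`in_frame` iff `(e_d − cs_d) ≡ (s_a − cs_a) (mod 3)`, else `frameshift`.
The single congruence also covers junctions upstream of the acceptor CDS
start, where the retained acceptor 5'UTR is translated through and shifts
the frame by its length. The classification is pure phase arithmetic: it
ignores stop codons, including junction-created stops and the donor's own
terminator when a junction lies in the donor 3'UTR. The test oracle
therefore translates the fused sequence straight through stops and asks
whether the acceptor's C-terminal peptide appears — the two views agree
on all 552 fixture junctions by construction of the question, not of the
fixture.

## Breakpoint localization

Given a chimeric amplicon and the two partner loci, the first and last 20
bases must occur uniquely in locus A and locus B respectively (anchor
uniqueness); the maximal amplicon prefix matching A and maximal suffix
matching B are extended from the anchors. Their overlap is the junction
microhomology; an unexplained middle is a "no chimera" error. With zero
microhomology the breakpoint is recovered at base precision; with
microhomology *k* the true breakpoint lies in the closed *k*-base interval
between the two maximal extensions, which is what gets reported (BED
intervals plus kb distances rounded to one decimal). In-silico PCR is
exact-match only — primers are treated as fully specific, with no
thermodynamics; a mismatch-tolerant mode is a deliberate non-goal.

## The synthetic fixture

The generator emulates the study conditions rather than any real genome:

| parameter | default | rationale |
|---|---|---|
| read_length | 90 nt | unstated by the assay (HiSeq-2000 class); > 2× the 8-base overhang rule |
| insert_mean / insert_sd | 200 / 20 nt | 200 bp size selection |
| coverage | 30× | transcript-level fold coverage; sets the pair count as `coverage·Σlen(tx)/(2·read_length)` |
| error_rate | 0.005/nt | substitution-only; the aligner contract is ungapped |
| donor/acceptor exons | 12 / 23 | the emulated gene pair's exon counts |
| fused exons | 2 → 23 | the recurrent isoform (`Pe2Te23`) |
| breakpoint offsets | 3400 / 2700 nt | the published genomic geometry |
| exon / intron lengths | 120–300 / 3500–4500 nt | introns sized so both breakpoint offsets fall strictly inside their flanking introns |
| fusion_expression_fraction | 0.3 | fraction of fragments drawn from the chimeric transcript |
| contaminant_fraction | 0.02 | adapter splice-ins and Q5-degraded reads, flagged in truth |

All randomness flows from a single seeded generator carried by the
bundle, so a fixed `FixtureConfig` yields byte-identical FASTA/FASTQ/GTF
output. Wild-type CDSs open with ATG, end with TAA, and contain no
internal stop (would-be stops have their third base rewritten), so frame
arithmetic is meaningful across the whole junction library. One intronic
base on each wild-type locus just outside the fusion-allele prefix/suffix
is adjusted so the genomic junction carries exactly
`junction_microhomology` bases of homology (0 by default) — the fusion
allele itself remains a pure concatenation, and breakpoint recovery is
base-exact for every seed; homology can be engineered for the
microhomology tests.

What the fixture does **not** model — and hence what passing tests do not
claim about real data: indels and structural sequencing errors, PCR
duplicates, expression heterogeneity beyond one fusion fraction, multiple
isoforms per gene, intra-exon fusion breakpoints in transcript space,
paralogy/homology between the partner genes (loci are independent random
sequence, which makes unique alignment easier than in real genomes), and
strandedness of the library.

## Numerical and degenerate-input conventions

Percentages are rounded half-away-from-zero to one decimal (`Decimal`,
not banker's rounding), matching how prevalence tables are printed; a
trailing zero (15 vs 15.0%) is treated as formatting. `tumor_volume`
requires `a ≤ b` (minimal/maximal diameter) and `tumor_growth_inhibition`
rejects `Vi = V0`. GTF I/O converts 1-based inclusive ↔ 0-based half-open
exactly once at the boundary; CDS features include the stop codon.
Zero-call detection runs exit successfully with a header-only report.
Ties in call ordering are broken by isoform name after total evidence.

## Problem sizes

The default fixture produces ≈ 1300–1450 read pairs over ≈ 150 kb of
reference — chosen so the full suite, including an end-to-end detection
run, an exhaustive-alignment equivalence check over 500 fuzzed instances,
a 552-junction translation census, and 200 random breakpoint
localizations, completes in well under a minute on one core. Coverage,
locus sizes and exon counts scale freely through `FixtureConfig` for
larger experiments.

## Known limitations

- Orientation reconciliation between spanning and encompassing evidence
  is reported (`orientation_conflict` flag), not enforced; the method
  being reimplemented does not describe one.
- Read-through (cis-SAGe) filtering, paralog filters, expression-based
  ranking and fusion allele-fraction estimation are out of scope.
- The cohort-scale published quantities (prevalence discovery itself, the
  in-frame fraction of the 28 observed isoforms, real hg18 breakpoint
  coordinates) are inputs or unpublished, not recomputable from sequence;
  the corresponding machinery is validated on planted ground truth
  instead.
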