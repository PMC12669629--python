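"""Gene-model arithmetic: GTF round trips, splicing, junctions, frames."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chimeraseq.annotation import (
    ACCEPTOR_NONCODING,
    DONOR_NONCODING,
    FRAMESHIFT,
    IN_FRAME,
    AnnotationError,
    FrameClassificationError,
    FusionJunction,
    GeneModel,
    GtfParseError,
    classify_frame,
    enumerate_junction_library,
    isoform_name,
    parse_isoform_name,
    read_gtf,
    reverse_complement,
    spliced_sequence,
    write_gtf,
)

# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------


def test_fixture_gtf_round_trip_preserves_models(default_fixture, tmp_path):
    bundle, _ = default_fixture
    models = [bundle.donor_model, bundle.acceptor_model]
    path = tmp_path / "two_genes.gtf"
    write_gtf(models, path)
    back = read_gtf(path)
    assert [m.exon_count for m in back] == [12, 23]
    assert sorted(back, key=lambda m: m.gene_id) == sorted(models, key=lambda m: m.gene_id)


def test_empty_gtf_gives_empty_model_list(tmp_path):
    path = tmp_path / "empty.gtf"
    path.write_text("# nothing here\n")
    assert read_gtf(path) == []


def test_overlapping_exons_raise_with_line_number(tmp_path):
    path = tmp_path / "bad.gtf"
    path.write_text(
        'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "g";\n'
        'chr1\tx\texon\t50\t150\t.\t+\t.\tgene_id "g"; transcript_id "g";\n'
    )
    with pytest.raises(GtfParseError, match=r"bad\.gtf:2"):
        read_gtf(path)


@st.composite
def gene_models(draw):
    strand = draw(st.sampled_from("+-"))
    n_exons = draw(st.integers(1, 6))
    lengths = draw(st.lists(st.integers(10, 60), min_size=n_exons, max_size=n_exons))
    gaps = draw(st.lists(st.integers(1, 50), min_size=n_exons, max_size=n_exons))
    exons = []
    pos = draw(st.integers(0, 100))
    for length, gap in zip(lengths, gaps):
        exons.append((pos, pos + length))
        pos += length + gap
    if strand == "-":
        exons = exons[::-1]
    spliced = sum(length for length in lengths)
    has_cds = draw(st.booleans())
    cds = None
    if has_cds and spliced >= 6:
        cs = draw(st.integers(0, spliced - 2))
        ce = draw(st.integers(cs + 1, spliced))
        cds = (cs, ce)
    gid = draw(st.sampled_from(["GENEA", "GENEB", "GENEC"]))
    return GeneModel(gid, gid, "chrT", strand, tuple(exons), cds)


@settings(max_examples=60, deadline=None)
@given(st.lists(gene_models(), min_size=1, max_size=3, unique_by=lambda m: m.gene_id))
def test_gtf_round_trip_is_identity_on_random_models(tmp_path_factory, models):
    path = tmp_path_factory.mktemp("gtf") / "models.gtf"
    write_gtf(models, path)
    back = read_gtf(path)
    assert sorted(back, key=lambda m: m.gene_id) == sorted(models, key=lambda m: m.gene_id)


# ---------------------------------------------------------------------------
# Spliced sequences
# ---------------------------------------------------------------------------


def test_single_exon_plus_strand_is_reference_substring():
    refs = {"chrT": "AACCGGTTACGTACGT"}
    m = GeneModel("g", "G", "chrT", "+", ((4, 10),))
    assert spliced_sequence(m, refs) == "GGTTAC"


def test_minus_strand_is_reverse_complement_of_mirrored_model():
    refs = {"chrT": "AACCGGTTACGTAAGGTTCCAGTC"}
    plus = GeneModel("g", "G", "chrT", "+", ((2, 8), (12, 18)))
    minus = GeneModel("g", "G", "chrT", "-", ((12, 18), (2, 8)))
    assert spliced_sequence(minus, refs) == reverse_complement(spliced_sequence(plus, refs))


def test_exon_beyond_reference_raises_bounds_error():
    m = GeneModel("g", "G", "chrT", "+", ((0, 50),))
    with pytest.raises(AnnotationError, match="exceeds"):
        spliced_sequence(m, {"chrT": "ACGT"})


def test_chimeric_model_splices_to_the_simulated_transcript(default_fixture):
    """The chimeric gene model on the fusion allele must reproduce the
    simulator's chimeric transcript byte-for-byte — independently, by
    slicing the wild-type spliced sequences at the fused exon boundaries."""
    bundle, _ = default_fixture
    chimera = spliced_sequence(bundle.chimera_model, bundle.reference_sequences)
    assert chimera == bundle.transcripts[bundle.chimera_model.gene_id]
    donor_sp = spliced_sequence(bundle.donor_model, bundle.reference_sequences)
    acceptor_sp = spliced_sequence(bundle.acceptor_model, bundle.reference_sequences)
    i = bundle.truth.planted_junction.donor_exon
    j = bundle.truth.planted_junction.acceptor_exon
    expected = (
        donor_sp[: bundle.donor_model.exon_end_spliced(i)]
        + acceptor_sp[bundle.acceptor_model.exon_start_spliced(j):]
    )
    assert chimera == expected


# ---------------------------------------------------------------------------
# Junction library
# ---------------------------------------------------------------------------


def test_junction_library_size_and_uniqueness(default_fixture, junction_library_552):
    bundle, _ = default_fixture
    lib = junction_library_552
    assert len(lib) == 2 * 12 * 23 == 552
    a_to_b = [j for j in lib if j.donor_gene == bundle.donor_model.gene_id]
    assert len(a_to_b) == 276
    keys = {(j.donor_gene, j.donor_exon, j.acceptor_gene, j.acceptor_exon) for j in lib}
    assert len(keys) == 552
    assert len({j.name for j in lib}) == 552


def test_junction_sequences_equal_independent_slices(default_fixture, junction_library_552):
    bundle, _ = default_fixture
    seqs = {
        m.gene_id: spliced_sequence(m, bundle.reference_sequences)
        for m in (bundle.donor_model, bundle.acceptor_model)
    }
    models = {m.gene_id: m for m in (bundle.donor_model, bundle.acceptor_model)}
    for j in junction_library_552:
        donor_seq = seqs[j.donor_gene]
        acceptor_seq = seqs[j.acceptor_gene]
        e = models[j.donor_gene].exon_end_spliced(j.donor_exon)
        s = models[j.acceptor_gene].exon_start_spliced(j.acceptor_exon)
        left = donor_seq[max(0, e - j.flank):e]
        right = acceptor_seq[s:s + j.flank]
        assert j.junction_sequence == left + right
        assert j.junction_point == len(left)


def test_oversized_flank_truncates_to_whole_transcripts():
    refs = {"chrT": "ACGTACGTACGTACGTACGTACGTACGT"}
    a = GeneModel("A", "A", "chrT", "+", ((0, 4), (8, 12)))
    b = GeneModel("B", "B", "chrT", "+", ((16, 20),))
    lib = enumerate_junction_library(a, b, refs, flank=1000)
    sa = spliced_sequence(a, refs)
    sb = spliced_sequence(b, refs)
    full = next(j for j in lib if j.donor_gene == "A" and j.donor_exon == 2)
    assert full.junction_sequence == sa + sb


# ---------------------------------------------------------------------------
# Nomenclature
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "i, j, expected",
    [(2, 23, "Pe2Te23"), (11, 17, "Pe11Te17"), (4, 20, "Pe4Te20")],
)
def test_isoform_names_follow_the_pexey_convention(i, j, expected):
    junction = FusionJunction(
        donor_gene="PLEKHA1",
        donor_exon=i,
        acceptor_gene="TACC2",
        acceptor_exon=j,
        donor_symbol="PLEKHA1",
        acceptor_symbol="TACC2",
        name="",
        junction_sequence="A",
        junction_point=0,
        flank=1,
    )
    assert isoform_name(junction) == expected


@given(st.integers(1, 99), st.integers(1, 99))
def test_isoform_name_parse_round_trip(i, j):
    name = f"Pe{i}Te{j}"
    assert parse_isoform_name(name) == (i, j)


# ---------------------------------------------------------------------------
# Frame classification
# ---------------------------------------------------------------------------


def _toy_models(cds_a=(6, 30), cds_b=(3, 27)):
    ref = {"chrT": "ACGTTGCAACGTACGTTGCAACGTACGTTGCAACGTACGTTGCAACGTACGT"}
    a = GeneModel("A", "ALPHA", "chrT", "+", ((0, 15), (20, 35)), cds_a)
    b = GeneModel("B", "BETA", "chrT", "+", ((0, 15), (20, 35)), cds_b)
    return a, b, ref


def _junction(a, b, ref, i, j, flank=10):
    lib = enumerate_junction_library(a, b, ref, flank)
    return next(
    	x for x in lib
        if x.donor_gene == a.gene_id and x.donor_exon == i and x.acceptor_exon == j
    )


def test_frame_class_matches_the_defining_congruence():
    a, b, ref = _toy_models(cds_a=(6, 30), cds_b=(3, 27))
    # donor exon 1 ends at spliced 15: L_d = 9; acceptor exon 2 starts at 15,
    # phase (15 - 3) % 3 = 0 != 9 % 3 = 0 -> equal: in frame
    j = _junction(a, b, ref, 1, 2)
    assert classify_frame(j, a, b) == IN_FRAME
    # shift acceptor CDS start by one: phase 2 vs 0 -> frameshift
    a2, b2, _ = _toy_models(cds_a=(6, 30), cds_b=(4, 28))
    j2 = _junction(a2, b2, ref, 1, 2)
    assert classify_frame(j2, a2, b2) == FRAMESHIFT


def test_junction_before_donor_cds_is_donor_noncoding():
    a, b, ref = _toy_models(cds_a=(20, 29), cds_b=(3, 27))
    j = _junction(a, b, ref, 1, 2)  # donor exon 1 ends at 15 <= cds start 20
    assert classify_frame(j, a, b) == DONOR_NONCODING


def test_junction_after_acceptor_cds_is_acceptor_noncoding():
    a, b, ref = _toy_models(cds_a=(6, 30), cds_b=(3, 12))
    j = _junction(a, b, ref, 1, 2)  # acceptor exon 2 starts at 15 >= cds end 12
    assert classify_frame(j, a, b) == ACCEPTOR_NONCODING


def test_missing_cds_raises_classification_error():
    a, b, ref = _toy_models()
    a_nocds = GeneModel("A", "ALPHA", "chrT", "+", a.exons, None)
    j = _junction(a, b, ref, 1, 2)
    with pytest.raises(FrameClassificationError):
        classify_frame(j, a_nocds, b)


def test_frame_class_is_invariant_to_flank_and_strand():
    a, b, ref = _toy_models()
    j_small = _junction(a, b, ref, 2, 1, flank=3)
    j_big = _junction(a, b, ref, 2, 1, flank=40)
    assert classify_frame(j_small, a, b) == classify_frame(j_big, a, b)

    # mirror gene A onto the minus strand with identical spliced content
    seq = ref["chrT"]
    mirrored_ref = {"chrM": reverse_complement(seq), "chrT": seq}
    n = len(seq)
    mirrored_exons = tuple((n - e, n - s) for s, e in a.exons)
    a_minus = GeneModel("A", "ALPHA", "chrM", "-", mirrored_exons, a.cds_span)
    assert spliced_sequence(a_minus, mirrored_ref) == spliced_sequence(a, ref)
    j_minus = _junction(a_minus, b, mirrored_ref, 2, 1, flank=10)
    assert classify_frame(j_minus, a_minus, b) == classify_frame(j_small, a, b)
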