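"""Fusion caller: evidence collection, junction rescue, the ≥1+≥1 rule."""

import numpy as np
import pytest

from chimeraseq.caller import (
    EncompassingEvidence,
    FusionCall,
    SpanningEvidence,
    call_fusions,
    collect_encompassing,
    read_fusion_report,
    rescue_spanning,
    write_fusion_report,
)
from chimeraseq.pipeline import detect_fusions
from chimeraseq.readproc import (
    CallerParams,
    GeneAnnotation,
    PairAlignment,
    ReadRecord,
)

from .helpers import brute_force_hits

PARAMS = CallerParams()


def _read(seq, rid="r1", mate=1):
    return ReadRecord(rid, mate, seq, "I" * len(seq))


# ---------------------------------------------------------------------------
# Overhang rule at the junction
# ---------------------------------------------------------------------------


def _planted_junction(bundle, junction_library):
    truth = bundle.truth.planted_junction
    return next(
        j
        for j in junction_library
        if (j.donor_gene, j.donor_exon, j.acceptor_gene, j.acceptor_exon)
        == (truth.donor_gene, truth.donor_exon, truth.acceptor_gene, truth.acceptor_exon)
    )


@pytest.mark.parametrize("overhang, rescued", [(7, False), (8, True), (9, True)])
def test_junction_overhang_threshold_is_inclusive_at_eight(
    default_fixture, junction_library_552, overhang, rescued
):
    """A spanning read must cross the junction by no less than 8 bases."""
    bundle, _ = default_fixture
    j = _planted_junction(bundle, junction_library_552)
    L = 90
    start = j.junction_point - (L - overhang)  # `overhang` bases right of the point
    read = _read(j.junction_sequence[start:start + L])
    evidence = rescue_spanning([read], junction_library_552, PARAMS)
    assert bool(evidence) == rescued
    if rescued:
        ev = evidence[0]
        assert ev.junction_name == j.name
        assert min(ev.overhang_left, ev.overhang_right) == overhang
        assert ev.mismatches == 0


def test_spanning_read_tied_between_junctions_is_discarded(
    default_fixture, junction_library_552
):
    bundle, _ = default_fixture
    j = _planted_junction(bundle, junction_library_552)
    # a duplicate junction under a second name produces a best-stratum tie
    import dataclasses

    twin = dataclasses.replace(j, name=j.name + "_twin")
    lib = list(junction_library_552) + [twin]
    read = _read(j.junction_sequence[j.junction_point - 45:j.junction_point + 45])
    assert rescue_spanning([read], lib, PARAMS) == []
    assert len(rescue_spanning([read], junction_library_552, PARAMS)) == 1


def test_empty_junction_library_rescues_nothing():
    assert rescue_spanning([_read("ACGT" * 25)], [], PARAMS) == []


# ---------------------------------------------------------------------------
# Encompassing collection (constructed pair alignments)
# ---------------------------------------------------------------------------


def _pa(status, pid="p", g1="GA", g2="GB", s1="+", s2="-"):
    return PairAlignment(
        pair_id=pid,
        hits_mate1=[],
        hits_mate2=[],
        status=status,
        gene_mate1=g1,
        gene_mate2=g2,
        sense_mate1=s1,
        sense_mate2=s2,
    )


def test_only_discordant_intergene_pairs_contribute_evidence(default_fixture):
    bundle, _ = default_fixture
    ann = GeneAnnotation([bundle.donor_model, bundle.acceptor_model])
    pas = [
        _pa("discordant_intergene", "p1"),
        _pa("multimapped", "p2"),
        _pa("concordant", "p3", g2="GA"),
        _pa("ambiguous_gene", "p4"),
        _pa("one_or_both_unmapped", "p5"),
    ]
    enc = collect_encompassing(pas, ann)
    assert set(enc) == {frozenset(("GA", "GB"))}
    (ev,) = enc[frozenset(("GA", "GB"))]
    assert (ev.pair_id, ev.gene_5p, ev.gene_3p, ev.orientation_confident) == (
        "p1", "GA", "GB", True,
    )


def test_orientation_inferred_from_mate_senses():
    ann_models = []
    pas = [
        _pa("discordant_intergene", "fwd", s1="+", s2="-"),
        _pa("discordant_intergene", "rev", s1="-", s2="+"),
        _pa("discordant_intergene", "odd", s1="+", s2="+"),
    ]
    enc = collect_encompassing(pas, GeneAnnotation(ann_models, transcript_to_gene={}))
    evs = {e.pair_id: e for e in enc[frozenset(("GA", "GB"))]}
    assert (evs["fwd"].gene_5p, evs["fwd"].gene_3p) == ("GA", "GB")
    assert (evs["rev"].gene_5p, evs["rev"].gene_3p) == ("GB", "GA")
    assert not evs["odd"].orientation_confident


# ---------------------------------------------------------------------------
# Calling rule
# ---------------------------------------------------------------------------


def _span(n, junction, rid0=0):
    return [
        SpanningEvidence(
            read_id=f"s{rid0 + k}/1",
            donor_gene=junction.donor_gene,
            donor_exon=junction.donor_exon,
            acceptor_gene=junction.acceptor_gene,
            acceptor_exon=junction.acceptor_exon,
            junction_name=junction.name,
            overhang_left=40,
            overhang_right=40,
            mismatches=0,
        )
        for k in range(n)
    ]


def _enc(n, g5="PLEKHA1", g3="TACC2"):
    pair = frozenset((g5, g3))
    return {
        pair: [
            EncompassingEvidence(f"e{k}", g5, g3, True) for k in range(n)
        ]
    }


def test_one_spanning_plus_one_encompassing_calls_the_fusion(
    default_fixture, junction_library_552
):
    bundle, _ = default_fixture
    j = _planted_junction(bundle, junction_library_552)
    models = {m.gene_id: m for m in (bundle.donor_model, bundle.acceptor_model)}
    calls = call_fusions(_enc(1), _span(1, j), PARAMS, models, junction_library_552)
    assert len(calls) == 1
    assert (calls[0].isoform, calls[0].n_spanning, calls[0].n_encompassing) == (
        "Pe2Te23", 1, 1,
    )


def test_encompassing_alone_never_calls(default_fixture, junction_library_552):
    bundle, _ = default_fixture
    models = {m.gene_id: m for m in (bundle.donor_model, bundle.acceptor_model)}
    assert call_fusions(_enc(5), [], PARAMS, models, junction_library_552) == []


def test_evidence_counts_are_reported_per_junction(default_fixture, junction_library_552):
    bundle, _ = default_fixture
    j = _planted_junction(bundle, junction_library_552)
    models = {m.gene_id: m for m in (bundle.donor_model, bundle.acceptor_model)}
    calls = call_fusions(_enc(2), _span(3, j), PARAMS, models, junction_library_552)
    assert [(c.n_spanning, c.n_encompassing) for c in calls] == [(3, 2)]


def test_fusion_report_round_trip(tmp_path, default_fixture, junction_library_552):
    bundle, _ = default_fixture
    j = _planted_junction(bundle, junction_library_552)
    models = {m.gene_id: m for m in (bundle.donor_model, bundle.acceptor_model)}
    calls = call_fusions(_enc(2), _span(3, j), PARAMS, models, junction_library_552)
    path = tmp_path / "report.tsv"
    write_fusion_report(calls, path)
    df = read_fusion_report(path)
    assert len(df) == 1
    row = df.iloc[0]
    assert (row.isoform, row.n_spanning, row.n_encompassing) == ("Pe2Te23", 3, 2)
    assert row.junction_seq == calls[0].junction_sequence

    empty = tmp_path / "empty.tsv"
    write_fusion_report([], empty)
    assert list(read_fusion_report(empty).columns) == list(df.columns)
    assert len(read_fusion_report(empty)) == 0


# ---------------------------------------------------------------------------
# Truth-table oracles on the noiseless fixture
# ---------------------------------------------------------------------------


def _truth_expectations(bundle, pairs, params):
    """Recompute expected evidence by brute force + coordinate arithmetic.

    Independent of the package's aligner: mapping status comes from an
    exhaustive numpy Hamming scan over the wild-type references, and
    junction crossing from truth-table coordinates.
    """
    chimera_id = bundle.chimera_model.gene_id
    J = bundle.junction_spliced_pos
    refs = dict(bundle.genome_references)
    refs.update(bundle.wildtype_transcripts)
    exp_spanning = set()
    exp_encompassing = set()
    for r1, r2 in pairs:
        origins = [bundle.truth.reads[f"{r.read_id}/{r.mate}"] for r in (r1, r2)]
        if origins[0].source != chimera_id:
            continue
        genes = []
        for read, origin in zip((r1, r2), origins):
            L = len(read.sequence)
            s = origin.start
            hits = brute_force_hits(read.sequence, refs, params.max_mismatches)
            if not hits:
                crossing_ok = s <= J - params.min_overhang and s + L >= J + params.min_overhang
                if crossing_ok:
                    exp_spanning.add(f"{read.read_id}/{read.mate}")
                genes.append(None)
            else:
                best_mm = min(h[3] for h in hits)
                best = {h for h in hits if h[3] == best_mm}
                hit_genes = set()
                for ref_name, pos, strand, _ in best:
                    if ref_name in bundle.wildtype_transcripts:
                        hit_genes.add(ref_name)
                    else:
                        model = (
                            bundle.donor_model
                            if ref_name == bundle.donor_model.reference_name
                            else bundle.acceptor_model
                        )
                        if any(
                            es < pos + L and pos < ee for es, ee in model.exons
                        ):
                            hit_genes.add(model.gene_id)
                genes.append(hit_genes.pop() if len(hit_genes) == 1 else None)
        if genes[0] and genes[1] and genes[0] != genes[1]:
            exp_encompassing.add(r1.read_id)
    return exp_spanning, exp_encompassing


def test_evidence_matches_truth_table_oracle_without_errors(clean_fixture):
    """At zero error rate the caller's spanning read set and encompassing
    pair set equal what coordinate arithmetic + an exhaustive alignment
    scan predict from the truth table."""
    bundle, pairs = clean_fixture
    params = CallerParams()
    result = detect_fusions(
        pairs,
        bundle.genome_references,
        bundle.wildtype_transcripts,
        [bundle.donor_model, bundle.acceptor_model],
        params,
    )
    exp_spanning, exp_encompassing = _truth_expectations(bundle, pairs, params)
    got_spanning = {ev.read_id for ev in result.spanning}
    assert got_spanning == exp_spanning
    pair_key = frozenset((bundle.donor_model.gene_id, bundle.acceptor_model.gene_id))
    got_encompassing = {ev.pair_id for ev in result.encompassing.get(pair_key, [])}
    assert got_encompassing == exp_encompassing
    assert exp_spanning and exp_encompassing  # the fixture carries real signal


def test_no_read_contributes_both_spanning_and_encompassing(default_fixture):
    bundle, pairs = default_fixture
    result = detect_fusions(
        pairs,
        bundle.genome_references,
        bundle.wildtype_transcripts,
        [bundle.donor_model, bundle.acceptor_model],
    )
    spanning_pairs = {ev.read_id.split("/")[0] for ev in result.spanning}
    encompassing_pairs = {
        ev.pair_id for evs in result.encompassing.values() for ev in evs
    }
    assert spanning_pairs.isdisjoint(encompassing_pairs)


def test_raising_thresholds_never_adds_calls(clean_fixture):
    bundle, pairs = clean_fixture
    args = (
        pairs,
        bundle.genome_references,
        bundle.wildtype_transcripts,
        [bundle.donor_model, bundle.acceptor_model],
    )
    baseline = detect_fusions(*args, CallerParams())
    base_keys = {(c.gene_5p, c.gene_3p, c.donor_exon, c.acceptor_exon) for c in baseline.calls}
    for stricter in (
        CallerParams(min_overhang=20),
        CallerParams(min_spanning=5),
        CallerParams(min_overhang=30, min_spanning=10, min_encompassing=5),
    ):
        res = detect_fusions(*args, stricter)
        keys = {(c.gene_5p, c.gene_3p, c.donor_exon, c.acceptor_exon) for c in res.calls}
        assert keys <= base_keys
        for c in res.calls:
            assert c.n_spanning >= stricter.min_spanning
            assert c.n_encompassing >= stricter.min_encompassing


def test_fusion_free_fixture_yields_zero_calls():
    from chimeraseq.synthetic_data import FixtureConfig, generate_fixture

    cfg = FixtureConfig(
        seed=55, fusion_expression_fraction=0.0, error_rate=0.0, coverage=6.0
    )
    bundle, pairs = generate_fixture(cfg)
    result = detect_fusions(
        pairs,
        bundle.genome_references,
        bundle.wildtype_transcripts,
        [bundle.donor_model, bundle.acceptor_model],
    )
    assert result.calls == []
    assert result.spanning == []
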