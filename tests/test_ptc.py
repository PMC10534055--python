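"""Overlap classification, alt-CDS reconstruction, PTC scan, and SNV index."""

import random

import pytest

from nmdescape.ptc import (
    AlleleMismatchError,
    OverlapStatus,
    build_alt_cds,
    build_snv_ptc_index,
    check_overlap,
    find_ptc,
    lookup_snv,
    map_alt_to_ref,
    annotate_variant,
)
from nmdescape.synthetic import (
    TranscriptDesign,
    make_fixture,
    synth_random_variants,
    tac_cds,
)
from nmdescape.transcripts import TranscriptSet, coordinate_map
from nmdescape.variants import Variant, left_normalize


def _single_exon_toy(strand="+", cds="ATGAAATGA", utr5=6, utr3=9):
    utr3_seq = utr3 if isinstance(utr3, str) else None
    utr3_len = len(utr3) if isinstance(utr3, str) else utr3
    g, ts, _ = make_fixture(
        [TranscriptDesign("T1", strand, exon_lengths=[utr5 + len(cds) + utr3_len],
                          intron_lengths=[], utr5_len=utr5, utr3_len=utr3_len,
                          cds_seq=cds, utr3_seq=utr3_seq,
                          contig="c1", tsl_label="NA")],
        seed=1,
    )
    return g, ts.transcripts["T1"]


def _multi_exon_toy(strand="+"):
    # 3 exons; CDS = 30 codons spread across them
    g, ts, _ = make_fixture(
        [TranscriptDesign("T3", strand, exon_lengths=[40, 50, 42],
                          intron_lengths=[30, 30], utr5_len=12, utr3_len=30,
                          cds_seq=tac_cds(30), contig="c1")],
        seed=2,
    )
    return g, ts.transcripts["T3"]


# ---------------------------------------------------------------------------
# overlap classification
# ---------------------------------------------------------------------------


def test_overlap_classification():
    g, tm = _multi_exon_toy("+")
    exon1 = tm.exons[0]
    cds1 = tm.cds_intervals[0]
    mid = (cds1[0] + cds1[1]) // 2
    assert check_overlap(Variant("c1", mid, "A", "T"), tm) is OverlapStatus.CODING
    # deletion straddling the first exon's 3' boundary
    v = Variant("c1", exon1[1] - 1, "AAAA", "A")
    assert check_overlap(v, tm) is OverlapStatus.SPLICE_EXCLUDED
    # donor dinucleotide SNV (intronic margin)
    v = Variant("c1", exon1[1] + 1, "G", "A")
    assert check_overlap(v, tm) is OverlapStatus.SPLICE_EXCLUDED
    # deep intronic
    v = Variant("c1", exon1[1] + 20, "A", "T")
    assert check_overlap(v, tm) is OverlapStatus.NONCODING
    # exonic base adjacent to the junction is NOT excluded when coding
    last_coding = tm.cds_intervals[0][1]
    if last_coding == exon1[1]:
        assert check_overlap(Variant("c1", last_coding, "A", "T"), tm) is (
            OverlapStatus.CODING
        )
    # 5'UTR position within the first exon
    v = Variant("c1", exon1[0] + 1, "A", "T")
    assert check_overlap(v, tm) is OverlapStatus.NONCODING
    # with margin 0 the donor SNV becomes plain intronic
    v = Variant("c1", exon1[1] + 1, "G", "A")
    assert check_overlap(v, tm, splice_margin=0) is OverlapStatus.NONCODING


def test_single_exon_transcript_has_no_splice_region():
    g, tm = _single_exon_toy()
    s, e = tm.exons[0]
    for pos in (s, e, s - 1, e + 1):
        assert check_overlap(Variant("c1", pos, "A", "T"), tm) is not (
            OverlapStatus.SPLICE_EXCLUDED
        )


# ---------------------------------------------------------------------------
# alt-CDS construction and the PTC scan
# ---------------------------------------------------------------------------


def test_build_alt_cds_snv_plus_strand():
    g, tm = _single_exon_toy("+")
    gpos = coordinate_map(tm, 4, "c2g")
    a = build_alt_cds(tm, g, Variant("c1", gpos, "A", "T"))
    assert a.alt_seq[: tm.cds_len] == "ATGTAATGA"
    assert (a.var_cds_pos, a.delta) == (4, 0)
    loc = find_ptc(a)
    assert loc is not None and loc.alt_first_nt == 4 and loc.in_cds
    assert loc.ref_nt_positions == (4, 5, 6)


def test_build_alt_cds_minus_strand_matches_plus():
    """The same transcript-space edit given in genomic alleles on either
    strand yields the same mutant CDS."""
    for strand in "+-":
        g, tm = _single_exon_toy(strand)
        gpos = coordinate_map(tm, 4, "c2g")
        contig = g.contigs["c1"]
        gref = contig[gpos - 1]
        galt = "T" if strand == "+" else "A"  # transcript-space A->T
        a = build_alt_cds(tm, g, Variant("c1", gpos, gref, galt))
        assert a.alt_seq[: tm.cds_len] == "ATGTAATGA"
        assert find_ptc(a).alt_first_nt == 4


def test_insertion_changes_length_and_delta():
    g, tm = _single_exon_toy("+")
    gpos = coordinate_map(tm, 6, "c2g")
    gref = g.contigs["c1"][gpos - 1]
    a = build_alt_cds(tm, g, Variant("c1", gpos, gref, gref + "G"))
    assert len(a.alt_seq) == tm.cds_len + 9 + 1
    assert a.delta == 1


def test_allele_mismatch_is_an_error():
    g, tm = _single_exon_toy("+")
    gpos = coordinate_map(tm, 4, "c2g")
    wrong = "C" if g.contigs["c1"][gpos - 1] != "C" else "G"
    with pytest.raises(AlleleMismatchError):
        build_alt_cds(tm, g, Variant("c1", gpos, wrong, "T"))


def test_reference_sequence_has_no_ptc():
    g, tm = _single_exon_toy("+")
    gpos = coordinate_map(tm, 4, "c2g")
    gref = g.contigs["c1"][gpos - 1]
    a = build_alt_cds(tm, g, Variant("c1", gpos, gref, gref))  # identity edit
    assert find_ptc(a) is None  # first stop is the canonical stop


def test_canonical_stop_swap_is_not_premature():
    # TAA -> TGA at the canonical stop: termination site unchanged
    g, tm = _single_exon_toy("+", cds="ATGAAATAA")
    gpos = coordinate_map(tm, 8, "c2g")  # middle base of the stop codon
    a = build_alt_cds(tm, g, Variant("c1", gpos, "A", "G"))
    assert a.alt_seq[: tm.cds_len] == "ATGAAATGA"
    assert find_ptc(a) is None


def test_stop_loss_readthrough_is_not_a_ptc():
    # destroy the canonical stop; a downstream in-frame stop in the 3'UTR
    # is readthrough, not premature termination
    g, tm = _single_exon_toy("+", cds="ATGAAATAA", utr3="TAATAA")
    gpos = coordinate_map(tm, 7, "c2g")
    a = build_alt_cds(tm, g, Variant("c1", gpos, "T", "C"))
    assert find_ptc(a) is None


def test_frameshift_finds_downstream_and_utr_stops():
    # 1bp deletion after ATG shifts TAC repeats into stop-free ACT repeats;
    # the 3'UTR carries TAA in all three frames, so the frameshift PTC must
    # be located there
    g, tm = _single_exon_toy("+", cds=tac_cds(12), utr3="TAAATAAATAAA")
    gpos = coordinate_map(tm, 3, "c2g")  # anchor at CDS 3, delete CDS 4
    ref2 = g.contigs["c1"][gpos - 1 : gpos + 1]
    a = build_alt_cds(tm, g, Variant("c1", gpos, ref2, ref2[0]))
    assert a.delta == -1
    loc = find_ptc(a)
    assert loc is not None
    # verify 5'-most by independent rescan of the literal mutant string
    for i in range(0, loc.alt_first_nt - 1, 3):
        assert a.alt_seq[i : i + 3] not in ("TAA", "TAG", "TGA")
    assert loc.ref_first_nt > tm.cds_len and not loc.in_cds


def test_map_alt_to_ref_cases():
    g, tm = _single_exon_toy("+", cds=tac_cds(20))
    gpos = coordinate_map(tm, 12, "c2g")
    gref = g.contigs["c1"][gpos - 1]
    # 4bp insertion at CDS pos 12
    a = build_alt_cds(tm, g, Variant("c1", gpos, gref, gref + "ACGT"))
    assert map_alt_to_ref(a, 5) == 5  # upstream: identity
    assert map_alt_to_ref(a, 14) == 12  # inside insertion: anchor clamp
    assert map_alt_to_ref(a, 20) == 16  # past insertion: -delta
    # 3bp deletion anchored at 12 (removes 13..15)
    ref4 = g.contigs["c1"][gpos - 1 : gpos + 3]
    d = build_alt_cds(tm, g, Variant("c1", gpos, ref4, ref4[0]))
    # explicit per-base alignment oracle
    ref_of = list(range(1, 13)) + list(range(16, tm.cds_len + 10))
    for alt_pos in range(1, 30):
        assert map_alt_to_ref(d, alt_pos) == ref_of[alt_pos - 1]
    with pytest.raises(ValueError):
        map_alt_to_ref(a, 0)


def test_insertion_content_determines_the_ptc():
    """Two same-position insertions, with and without an in-frame stop,
    must produce different PTC calls (content, not just size, matters)."""
    g, tm = _single_exon_toy("+", cds=tac_cds(30))
    gpos = coordinate_map(tm, 9, "c2g")  # after codon 3
    gref = g.contigs["c1"][gpos - 1]
    with_stop = find_ptc(build_alt_cds(tm, g, Variant("c1", gpos, gref, gref + "TAA")))
    without = find_ptc(build_alt_cds(tm, g, Variant("c1", gpos, gref, gref + "CAA")))
    assert with_stop is not None and with_stop.alt_first_nt == 10
    assert without is None  # in-frame sense insertion into a stop-free CDS


# ---------------------------------------------------------------------------
# SNV index
# ---------------------------------------------------------------------------


def test_tyr_codon_admits_exactly_two_stop_gains():
    """For a TAC codon only the third-base C->A and C->G edits create a stop."""
    g, tm = _single_exon_toy("+", cds=tac_cds(10))
    ts = TranscriptSet({tm.transcript_id: tm})
    idx = build_snv_ptc_index(ts, g)
    codon = 5  # CDS positions 13..15 = TAC
    hits = []
    for off, base in ((0, "T"), (1, "A"), (2, "C")):
        gpos = coordinate_map(tm, 12 + off + 1, "c2g")
        for alt in "ACGT":
            if alt == base:
                continue
            if idx.get(Variant("c1", gpos, base, alt), tm.transcript_id):
                hits.append((off, base, alt))
    assert sorted(hits) == [(2, "C", "A"), (2, "C", "G")]


def test_canonical_stop_codon_produces_no_index_entries():
    g, tm = _single_exon_toy("+", cds=tac_cds(10))
    ts = TranscriptSet({tm.transcript_id: tm})
    idx = build_snv_ptc_index(ts, g)
    for cds_pos in range(tm.cds_len - 2, tm.cds_len + 1):
        gpos = coordinate_map(tm, cds_pos, "c2g")
        gref = g.contigs["c1"][gpos - 1]
        for alt in "ACGT":
            if alt != gref:
                assert not idx.get(Variant("c1", gpos, gref, alt))


def test_index_equals_explicit_construction_everywhere(fixture_set):
    genome, ts = fixture_set
    idx = build_snv_ptc_index(ts, genome)
    for tm in ts:
        contig = genome.contigs[tm.contig]
        for cds_pos in range(1, tm.cds_len + 1):
            gpos = coordinate_map(tm, cds_pos, "c2g")
            gref = contig[gpos - 1]
            for galt in "ACGT":
                if galt == gref:
                    continue
                v = Variant(tm.contig, gpos, gref, galt)
                direct = find_ptc(build_alt_cds(tm, genome, v))
                looked = idx.get(v, tm.transcript_id)
                assert (direct is None) == (not looked)
                if direct is not None:
                    assert looked == [direct]


def test_lookup_misses(fixture_set):
    genome, ts = fixture_set
    idx = build_snv_ptc_index(ts, genome)
    assert lookup_snv(idx, Variant("chrUnknown", 5, "A", "T")) == []


def test_index_roundtrips_and_validates_fingerprint(tmp_path, fixture_set):
    genome, ts = fixture_set
    idx = build_snv_ptc_index(ts, genome)
    p = tmp_path / "idx.tsv"
    idx.save(p)
    from nmdescape.ptc import PtcIndex

    idx2 = PtcIndex.load(p, ts)
    assert len(idx2) == len(idx)
    assert list(idx2.trie.items()) == list(idx.trie.items())
    # a different transcript set is rejected
    smaller = TranscriptSet(dict(list(ts.transcripts.items())[:3]))
    with pytest.raises(ValueError):
        PtcIndex.load(p, smaller)


def test_annotation_with_and_without_index_is_identical(fixture_set):
    genome, ts = fixture_set
    idx = build_snv_ptc_index(ts, genome)
    rng = random.Random(3)
    for v in synth_random_variants(ts, genome, 300, seed=rng.randint(0, 999)):
        v = left_normalize(v, genome)
        assert annotate_variant(v, ts, genome, idx=None) == annotate_variant(
            v, ts, genome, idx=idx
        )


def test_deep_intronic_variant_yields_no_entries(fixture_set):
    genome, ts = fixture_set
    tm = next(t for t in ts if t.n_exons >= 2)
    exons = sorted(tm.exons)
    intron_mid = (exons[0][1] + exons[1][0]) // 2
    gref = genome.contigs[tm.contig][intron_mid - 1]
    galt = "A" if gref != "A" else "C"
    v = Variant(tm.contig, intron_mid, gref, galt)
    assert annotate_variant(v, ts, genome) == []
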