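"""Genome loading, annotation parsing, filtering, and coordinate arithmetic."""

import pytest

from nmdescape.synthetic import TranscriptDesign, make_fixture, random_cds, tac_cds
from nmdescape.transcripts import (
    FilterCriteria,
    TranscriptModel,
    coding_sequence,
    coordinate_map,
    exon_of_cds_pos,
    filter_transcript_set,
    load_genome,
    load_transcript_models,
)

from conftest import ALL_CONTIGS


# ---------------------------------------------------------------------------
# genome loading
# ---------------------------------------------------------------------------


def test_load_genome_uppercases_and_names_to_first_whitespace(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">chrT extra description\nacgt\n>chrU\nGGCCTT\n")
    g = load_genome(fa)
    assert g.contigs == {"chrT": "ACGT", "chrU": "GGCCTT"}


def test_load_genome_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_genome(tmp_path / "missing.fa")
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(Exception):
        load_genome(empty)


def test_fixture_genome_roundtrips_byte_identically(fixture_files, fixture_set):
    _fasta, _gtf, genome_from_file, _ts = fixture_files
    genome_in_memory, _ = fixture_set
    assert genome_from_file.contigs == genome_in_memory.contigs


# ---------------------------------------------------------------------------
# annotation parsing
# ---------------------------------------------------------------------------

_TOY_GENOME = ">c1\n" + "ACGT" * 40 + "\n"


def _toy_gtf(strand: str, with_stop_feature: bool) -> str:
    """Three-exon toy transcript; CDS covers all exonic bases.

    Exons c1:11-19, 31-39, 51-59 (9 bp each; total 27, divisible by 3).
    """
    a = 'gene_id "G"; transcript_id "T"; transcript_support_level "1";'
    rows = [
        ("exon", 11, 19), ("exon", 31, 39), ("exon", 51, 59),
    ]
    if with_stop_feature:
        if strand == "+":
            rows += [("CDS", 11, 19), ("CDS", 31, 39), ("CDS", 51, 56),
                     ("stop_codon", 57, 59)]
        else:
            rows += [("CDS", 14, 19), ("CDS", 31, 39), ("CDS", 51, 59),
                     ("stop_codon", 11, 13)]
    else:
        rows += [("CDS", 11, 19), ("CDS", 31, 39), ("CDS", 51, 59)]
    lines = [
        "\t".join(["c1", "toy", f, str(s), str(e), ".", strand, ".", a])
        for f, s, e in rows
    ]
    return "\n".join(lines) + "\n"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_exon_ordering_follows_transcript_orientation(tmp_path, strand):
    gtf = tmp_path / "t.gtf"
    gtf.write_text(_toy_gtf(strand, with_stop_feature=False))
    ts = load_transcript_models(gtf)
    tm = ts.transcripts["T"]
    starts = [s for s, _ in tm.exons]
    assert starts == sorted(starts, reverse=(strand == "-"))
    assert tm.cds_len == 27


@pytest.mark.parametrize("strand", ["+", "-"])
def test_separate_stop_codon_feature_is_merged_into_cds(tmp_path, strand):
    g = load_genome(_write(tmp_path, "g.fa", _TOY_GENOME))
    merged = load_transcript_models(
        _write(tmp_path, "a.gtf", _toy_gtf(strand, with_stop_feature=True))
    ).transcripts["T"]
    inclusive = load_transcript_models(
        _write(tmp_path, "b.gtf", _toy_gtf(strand, with_stop_feature=False))
    ).transcripts["T"]
    assert merged.cds_intervals == inclusive.cds_intervals
    assert coding_sequence(merged, g) == coding_sequence(inclusive, g)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _mini_tm(tid, n_exons, cds_len, tsl, biotype="protein_coding", contig="chr1"):
    """Structurally consistent throwaway transcript for filter tests."""
    exons, cds, pos = [], [], 101
    per = cds_len // n_exons
    widths = [per] * (n_exons - 1) + [cds_len - per * (n_exons - 1)]
    for w in widths:
        exons.append((pos, pos + w - 1))
        cds.append((pos, pos + w - 1))
        pos += w + 50
    return TranscriptModel(tid, "G", contig, "+", exons, cds, tsl, biotype)


def _ts_of(*tms):
    from nmdescape.transcripts import TranscriptSet

    return TranscriptSet({tm.transcript_id: tm for tm in tms})


def test_filter_criteria_defaults():
    ts = _ts_of(
        _mini_tm("ok", 2, 99, tsl=1),
        _mini_tm("mod3", 2, 100, tsl=1),
        _mini_tm("tsl2", 2, 99, tsl=2),
        _mini_tm("single_na", 1, 99, tsl=None),
        _mini_tm("multi_na", 2, 99, tsl=None),
        _mini_tm("lnc", 2, 99, tsl=1, biotype="lncRNA"),
        _mini_tm("scaffold", 2, 99, tsl=1, contig="GL000219.1"),
    )
    kept = filter_transcript_set(ts, FilterCriteria())
    assert set(kept.transcripts) == {"ok", "single_na"}
    assert kept.filter_report == {"biotype": 1, "tsl": 2, "cds_mod3": 1, "contig": 1}


def test_filter_is_idempotent(fixture_set):
    _genome, ts = fixture_set
    again = filter_transcript_set(ts, ALL_CONTIGS)
    assert set(again.transcripts) == set(ts.transcripts)
    assert all(n == 0 for n in again.filter_report.values())


# ---------------------------------------------------------------------------
# coordinate arithmetic
# ---------------------------------------------------------------------------


def test_coding_sequence_matches_per_base_oracle(fixture_set):
    genome, ts = fixture_set
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for tm in list(ts)[:6]:
        contig = genome.contigs[tm.contig]
        expected = []
        for s, e in tm.cds_intervals:
            block = [contig[p - 1] for p in range(s, e + 1)]
            if tm.strand == "-":
                block = [comp[b] for b in reversed(block)]
            expected.append("".join(block))
        assert coding_sequence(tm, genome) == "".join(expected)


def test_strand_symmetric_designs_give_identical_cds():
    cds = random_cds(40, __import__("random").Random(1))
    kw = dict(exon_lengths=[60, 80, 70], intron_lengths=[50, 50],
              utr5_len=30, utr3_len=60, cds_seq=cds)
    g, ts, _ = make_fixture(
        [TranscriptDesign("P", "+", contig="c1", **kw),
         TranscriptDesign("M", "-", contig="c2", **kw)]
    )
    assert coding_sequence(ts.transcripts["P"], g) == cds
    assert coding_sequence(ts.transcripts["M"], g) == cds


def test_coordinate_map_is_a_bijection(fixture_set):
    genome, ts = fixture_set
    tm = next(t for t in ts if t.n_exons >= 3)
    seen = set()
    for cds_pos in range(1, tm.cds_len + 1):
        gpos = coordinate_map(tm, cds_pos, "c2g")
        assert coordinate_map(tm, gpos, "g2c") == cds_pos
        seen.add(gpos)
    assert len(seen) == tm.cds_len
    # intronic / out-of-CDS genomic positions map to nothing
    intron_pos = sorted(tm.exons)[0][1] + 1
    assert coordinate_map(tm, intron_pos, "g2c") is None
    with pytest.raises(ValueError):
        coordinate_map(tm, tm.cds_len + 1, "c2g")


def test_exon_ordinal_counts_pure_utr_exons():
    # first exon entirely 5'UTR (width 40 < utr5 45)
    cds = tac_cds(30)
    g, ts, _ = make_fixture(
        [TranscriptDesign("U", "+", exon_lengths=[40, 80, 45],
                          intron_lengths=[30, 30], utr5_len=45, utr3_len=30,
                          cds_seq=cds, contig="c1")]
    )
    tm = ts.transcripts["U"]
    ordinal, width = exon_of_cds_pos(tm, 1)
    assert ordinal == 2 and width == 80
    with pytest.raises(ValueError):
        exon_of_cds_pos(tm, 0)


def test_spatial_index_agrees_with_linear_scan(fixture_set):
    genome, ts = fixture_set
    import random

    rng = random.Random(2)
    for _ in range(200):
        tm = rng.choice(list(ts))
        lo = min(s for s, _ in tm.cds_intervals)
        hi = max(e for _, e in tm.cds_intervals)
        start = rng.randint(max(1, lo - 300), hi + 300)
        end = start + rng.randint(0, 50)
        got = {t.transcript_id for t in ts.overlapping(tm.contig, start, end)}
        want = {
            t.transcript_id
            for t in ts
            if t.contig == tm.contig
            and min(s for s, _ in t.cds_intervals) <= end
            and max(e for _, e in t.cds_intervals) >= start
        }
        assert got == want
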