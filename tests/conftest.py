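import pytest

from nmdescape.synthetic import FixtureSpec, synth_fixture, synth_genome_and_annotation
from nmdescape.transcripts import (
    FilterCriteria,
    filter_transcript_set,
    load_genome,
    load_transcript_models,
)

#: filter settings for synthetic contigs (ctg1, ctg2, ...)
ALL_CONTIGS = FilterCriteria(contig_allowlist="all")

DEFAULT_SPEC = FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def fixture_set():
    """In-memory random fixture: (genome, filtered transcript set)."""
    genome, ts, _parts = synth_fixture(DEFAULT_SPEC)
    return genome, filter_transcript_set(ts, ALL_CONTIGS)


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory):
    """The same fixture written to disk and loaded back through the parsers."""
    out = tmp_path_factory.mktemp("fixture")
    fasta, gtf = synth_genome_and_annotation(DEFAULT_SPEC, out)
    genome = load_genome(fasta)
    ts = filter_transcript_set(load_transcript_models(gtf), ALL_CONTIGS)
    return fasta, gtf, genome, ts
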