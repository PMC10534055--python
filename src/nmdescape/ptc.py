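"""PTC detection: alt-allele CDS reconstruction, stop-codon scan, SNV index.

For every (variant, transcript) pair the mutant coding sequence (through the
annotated transcript 3' end, so frameshift-induced downstream stops are
visible) is reconstructed explicitly, scanned codon-by-codon from the start
codon, and the 5'-most novel stop codon located. Stop-gain SNVs for a whole
transcript set can be pre-enumerated into a trie index for lookup; non-SNV
variants are always constructed explicitly, which makes the calls sensitive
to both the size and the content of inserted sequence.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

from .rules import RuleParams, RuleResults, apply_rules
from .transcripts import (
    GenomeSequence,
    TranscriptModel,
    TranscriptSet,
    coordinate_map,
    exon_of_region_pos,
    revcomp,
)
from .trie import Trie
from .variants import Variant, variant_class

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: default splice-region margin: the two intronic bases at each junction
#: (the canonical donor/acceptor dinucleotides)
DEFAULT_SPLICE_MARGIN = 2


class OverlapStatus(enum.Enum):
    CODING = "coding"
    SPLICE_EXCLUDED = "splice_excluded"
    NONCODING = "noncoding"


def check_overlap(
    v: Variant, tm: TranscriptModel, splice_margin: int = DEFAULT_SPLICE_MARGIN
) -> OverlapStatus:
    """Classify a variant's reference span against one transcript.

    coding: the span lies entirely within one CDS interval (exonic bases
    adjacent to junctions are not excluded). splice_excluded: the span
    crosses an exon-intron boundary or touches the intronic ``splice_margin``
    bases at an internal junction. noncoding otherwise.
    """
    s, e = v.pos, v.pos + len(v.ref) - 1
    for cs, ce in tm.cds_intervals:
        if cs <= s and e <= ce:
            return OverlapStatus.CODING
    exons = sorted(tm.exons)
    n = len(exons)
    for i, (a, b) in enumerate(exons):
        if i > 0:  # internal boundary on the exon's 5' (genomic-left) side
            if s < a <= e:  # crosses the boundary
                return OverlapStatus.SPLICE_EXCLUDED
            if splice_margin > 0 and s <= a - 1 and e >= a - splice_margin:
                return OverlapStatus.SPLICE_EXCLUDED
        if i < n - 1:  # internal boundary on the genomic-right side
            if s <= b < e:
                return OverlapStatus.SPLICE_EXCLUDED
            if splice_margin > 0 and s <= b + splice_margin and e >= b + 1:
                return OverlapStatus.SPLICE_EXCLUDED
    return OverlapStatus.NONCODING


class AlleleMismatchError(ValueError):
    """Variant alleles inconsistent with the genome/transcript sequence."""


@dataclass(frozen=True)
class AltCdsResult:
    """Mutant CDS(+3'UTR) with the variant-induced coordinate bookkeeping."""

    alt_seq: str
    var_cds_pos: int  # 1-based CDS position of the transcript-5'-most affected base
    delta: int  # len(alt) - len(ref)
    canonical_stop_cds_pos: int  # CDS position of the canonical stop's first base
    ref_allele_len: int
    alt_allele_len: int
    tm: TranscriptModel


def build_alt_cds(
    tm: TranscriptModel, genome: GenomeSequence, v: Variant
) -> AltCdsResult:
    """Reconstruct the mutant coding(+3'UTR) sequence for one coding variant.

    Precondition: ``check_overlap(v, tm)`` is coding. On the minus strand the
    alleles are reverse-complemented and anchored at the transcript-
    orientation 5'-most affected base.
    """
    region = tm.region_seq(genome)
    if tm.strand == "+":
        start = coordinate_map(tm, v.pos, "g2c")
        ref_t, alt_t = v.ref, v.alt
    else:
        start = coordinate_map(tm, v.pos + len(v.ref) - 1, "g2c")
        ref_t, alt_t = revcomp(v.ref), revcomp(v.alt)
    if start is None:
        raise AlleleMismatchError(f"{v.key()} anchor outside CDS of {tm.transcript_id}")
    if region[start - 1 : start - 1 + len(ref_t)] != ref_t:
        raise AlleleMismatchError(
            f"{v.key()} REF inconsistent with {tm.transcript_id} sequence"
        )
    alt_seq = region[: start - 1] + alt_t + region[start - 1 + len(ref_t) :]
    return AltCdsResult(
        alt_seq=alt_seq,
        var_cds_pos=start,
        delta=len(v.alt) - len(v.ref),
        canonical_stop_cds_pos=tm.cds_len - 2,
        ref_allele_len=len(ref_t),
        alt_allele_len=len(alt_t),
        tm=tm,
    )


def map_alt_to_ref(a: AltCdsResult, alt_pos: int) -> int:
    """Map a mutant-CDS position to reference-CDS coordinates.

    Positions upstream of the variant map to themselves; positions inside
    the inserted/replaced span clamp to the variant anchor; positions beyond
    shift by -delta.
    """
    if not 1 <= alt_pos <= len(a.alt_seq):
        raise ValueError(f"alt position {alt_pos} outside [1, {len(a.alt_seq)}]")
    if alt_pos < a.var_cds_pos:
        return alt_pos
    if alt_pos <= a.var_cds_pos + a.alt_allele_len - 1:
        return a.var_cds_pos
    return alt_pos - a.delta


@dataclass(frozen=True)
class PtcLocation:
    """The 5'-most novel stop codon of a mutant coding sequence."""

    alt_first_nt: int  # 1-based position in alt_seq of the stop's first base
    alt_last_nt: int
    ref_first_nt: int  # mapped to reference-CDS(+3'UTR) coordinates
    ref_last_nt: int
    ref_nt_positions: tuple[int, int, int]
    exon_ordinal: int  # 1-based, transcript orientation, counting UTR exons
    exon_width: int  # full annotated genomic width of the containing exon
    in_cds: bool  # False when the stop lies in 3'UTR sequence (frameshift)


def find_ptc(a: AltCdsResult) -> PtcLocation | None:
    """Scan the mutant sequence in codons from position 1 for the first stop.

    Returns None when no stop exists before the transcript 3' end, or when
    termination is not premature: for frame-preserving variants
    (delta % 3 == 0) a first stop at or past the delta-shifted canonical
    stop position is the canonical stop itself (or a stop-loss readthrough
    stop), not a PTC.
    """
    s = a.alt_seq
    if len(s) < 3:
        raise ValueError("alt sequence shorter than one codon")
    for i in range(0, len(s) - 2, 3):
        if s[i : i + 3] not in STOP_CODONS:
            continue
        alt_first = i + 1
        if a.delta % 3 == 0 and alt_first >= a.canonical_stop_cds_pos + a.delta:
            return None
        refs = tuple(map_alt_to_ref(a, alt_first + k) for k in range(3))
        ordinal, width = exon_of_region_pos(a.tm, refs[0])
        return PtcLocation(
            alt_first_nt=alt_first,
            alt_last_nt=alt_first + 2,
            ref_first_nt=refs[0],
            ref_last_nt=refs[2],
            ref_nt_positions=refs,
            exon_ordinal=ordinal,
            exon_width=width,
            in_cds=refs[0] <= a.tm.cds_len,
        )
    return None


# ---------------------------------------------------------------------------
# precomputed SNV index
# ---------------------------------------------------------------------------

INDEX_MAGIC = "#nmdescape-ptc-index v1"


class PtcIndex:
    """Trie of all stop-gain SNVs of a transcript set.

    Keys are ``contig:zero-padded-pos:REF>ALT`` (padding width derived from
    the contig length so lexicographic order equals genomic order); payloads
    are lists of ``(transcript_id, PtcLocation)``.
    """

    def __init__(self, fingerprint: str, pad_widths: dict[str, int]):
        self.fingerprint = fingerprint
        self.pad_widths = dict(pad_widths)
        self.trie = Trie()

    def _key(self, contig: str, pos: int, ref: str, alt: str) -> str:
        width = self.pad_widths.get(contig, 9)
        return f"{contig}:{pos:0{width}d}:{ref}>{alt}"

    def add(
        self,
        contig: str,
        pos: int,
        ref: str,
        alt: str,
        transcript_id: str,
        loc: PtcLocation,
    ) -> None:
        key = self._key(contig, pos, ref, alt)
        payload = self.trie.get(key)
        if payload is None:
            payload = []
            self.trie[key] = payload
        payload.append((transcript_id, loc))

    def get(self, v: Variant, transcript_id: str | None = None):
        entries = self.trie.get(self._key(v.contig, v.pos, v.ref, v.alt)) or []
        if transcript_id is None:
            return list(entries)
        return [loc for tid, loc in entries if tid == transcript_id]

    def __len__(self) -> int:
        return len(self.trie)

    # -- flat-file serialization -------------------------------------------
    def save(self, path: str | Path) -> None:
        """Sorted key, tab, ';'-joined payload entries."""
        with open(path, "w") as fh:
            fh.write(INDEX_MAGIC + "\n")
            fh.write(f"#fingerprint\t{self.fingerprint}\n")
            pads = ",".join(f"{c}={w}" for c, w in sorted(self.pad_widths.items()))
            fh.write(f"#pad_widths\t{pads}\n")
            for key, payload in self.trie.items():
                cells = []
                for tid, loc in payload:
                    refs = ",".join(str(r) for r in loc.ref_nt_positions)
                    cells.append(
                        f"{tid}|{loc.alt_first_nt}|{loc.alt_last_nt}"
                        f"|{loc.ref_first_nt}|{loc.ref_last_nt}|{refs}"
                        f"|{loc.exon_ordinal}|{loc.exon_width}"
                        f"|{int(loc.in_cds)}"
                    )
                fh.write(key + "\t" + ";".join(cells) + "\n")

    @classmethod
    def load(cls, path: str | Path, ts: TranscriptSet | None = None) -> "PtcIndex":
        """Load a serialized index; validates the transcript-set fingerprint
        when ``ts`` is given."""
        with open(path) as fh:
            magic = fh.readline().rstrip("\n")
            if magic != INDEX_MAGIC:
                raise ValueError(f"not a PTC index file: {path}")
            fingerprint = fh.readline().rstrip("\n").split("\t")[1]
            pads_raw = fh.readline().rstrip("\n").split("\t")[1]
            pad_widths = {}
            if pads_raw:
                for tok in pads_raw.split(","):
                    c, w = tok.rsplit("=", 1)
                    pad_widths[c] = int(w)
            idx = cls(fingerprint, pad_widths)
            for line in fh:
                key, payload_raw = line.rstrip("\n").split("\t")
                payload = []
                for cell in payload_raw.split(";"):
                    parts = cell.split("|")
                    refs = tuple(int(x) for x in parts[5].split(","))
                    payload.append(
                        (
                            parts[0],
                            PtcLocation(
                                alt_first_nt=int(parts[1]),
                                alt_last_nt=int(parts[2]),
                                ref_first_nt=int(parts[3]),
                                ref_last_nt=int(parts[4]),
                                ref_nt_positions=refs,
                                exon_ordinal=int(parts[6]),
                                exon_width=int(parts[7]),
                                in_cds=bool(int(parts[8])),
                            ),
                        )
                    )
                idx.trie[key] = payload
        if ts is not None and idx.fingerprint != ts.fingerprint():
            raise ValueError(
                "PTC index fingerprint does not match the transcript set; "
                "rebuild the index for this annotation"
            )
        return idx


def build_snv_ptc_index(ts: TranscriptSet, genome: GenomeSequence) -> PtcIndex:
    """Enumerate every coding SNV of the transcript set and keep stop-gains.

    For each CDS position and each of the three alternative bases the SNV
    enters the index iff explicit construction finds a PTC.
    """
    pad_widths = {name: len(str(len(seq))) for name, seq in genome.contigs.items()}
    idx = PtcIndex(ts.fingerprint(), pad_widths)
    for tm in sorted(ts, key=lambda t: t.transcript_id):
        contig = genome.contigs[tm.contig]
        for cds_pos in range(1, tm.cds_len + 1):
            gpos = coordinate_map(tm, cds_pos, "c2g")
            gref = contig[gpos - 1]
            for galt in "ACGT":
                if galt == gref:
                    continue
                v = Variant(tm.contig, gpos, gref, galt)
                loc = find_ptc(build_alt_cds(tm, genome, v))
                if loc is not None:
                    idx.add(tm.contig, gpos, gref, galt, tm.transcript_id, loc)
    log.info("PTC index: %d stop-gain SNV keys", len(idx))
    return idx


def lookup_snv(idx: PtcIndex, v: Variant) -> list[tuple[str, PtcLocation]]:
    """Trie lookup of a (normalized) SNV; empty list on miss."""
    return idx.get(v)


# ---------------------------------------------------------------------------
# per-variant annotation
# ---------------------------------------------------------------------------


def annotate_variant(
    v: Variant,
    ts: TranscriptSet,
    genome: GenomeSequence,
    idx: PtcIndex | None = None,
    params: RuleParams | None = None,
    splice_margin: int = DEFAULT_SPLICE_MARGIN,
    counters: dict[str, int] | None = None,
) -> list[tuple[str, RuleResults]]:
    """Annotate one normalized variant against all overlapping transcripts.

    Returns one ``(transcript_id, RuleResults)`` per transcript whose overlap
    status is coding (the results may be all-false for non-PTC variants);
    splice-excluded and noncoding pairs yield no entry and are counted in
    ``counters``. SNVs are resolved through the precomputed index when one
    is supplied; non-SNVs are always constructed explicitly.
    """
    params = params or RuleParams()
    out: list[tuple[str, RuleResults]] = []
    span_end = v.pos + len(v.ref) - 1
    is_snv = variant_class(v) == "snv"
    for tm in ts.overlapping(v.contig, v.pos, span_end):
        status = check_overlap(v, tm, splice_margin)
        if status is not OverlapStatus.CODING:
            if counters is not None:
                counters[status.value] = counters.get(status.value, 0) + 1
            continue
        if is_snv and idx is not None:
            locs = idx.get(v, tm.transcript_id)
            loc = locs[0] if locs else None
        else:
            loc = find_ptc(build_alt_cds(tm, genome, v))
        out.append((tm.transcript_id, apply_rules(loc, tm, params)))
    return out
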