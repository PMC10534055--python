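"""Synthetic genomes, annotations, and variant sets with known rule structure.

This module generates multi-exon protein-coding transcripts on both strands
with valid CDS (start codon, terminal stop, length divisible by three, no
internal in-frame stop), writes them as FASTA + GENCODE-style GTF, and
places variants that trigger chosen NMD-escape rules. It also houses two
independent brute-force oracles used for equivalence testing:

* :func:`oracle_annotate` — a literal-string re-derivation of the whole
  annotation (rebuild the mutant spliced transcript, translate codon by
  codon, walk exons base by base, apply the rule definitions directly). It
  shares no code with :mod:`nmdescape.ptc` or :mod:`nmdescape.rules`.
* :func:`oracle_normalize` — exhaustive enumeration of all VCF
  representations of an edit inside a window, picking the minimal-position,
  minimal-length parsimonious one.

What the generator emulates: exon/intron structure, UTRs, canonical splice
dinucleotides, strand mixture, and controlled PTC placement. What it does
not: realistic base composition, overlapping genes, alternative isoform
sharing of exons, or population allele frequencies.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq

from .rules import RULE_NAMES, RuleParams, RuleResults
from .transcripts import GenomeSequence, TranscriptModel, TranscriptSet, revcomp
from .variants import Variant

log = logging.getLogger(__name__)

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ("TAA", "TAG", "TGA")


class InfeasibleDesignError(ValueError):
    """A transcript design or variant placement cannot be realized."""


# ---------------------------------------------------------------------------
# transcript designs
# ---------------------------------------------------------------------------


@dataclass
class TranscriptDesign:
    """Explicit transcript layout in transcript orientation.

    ``exon_lengths`` are total exon lengths whose sum must equal
    ``utr5_len + len(cds_seq) + utr3_len``. ``cds_seq`` includes the
    terminal stop codon.
    """

    transcript_id: str
    strand: str
    exon_lengths: list[int]
    intron_lengths: list[int]
    utr5_len: int
    utr3_len: int
    cds_seq: str
    gene_id: str = ""
    contig: str = "ctg1"
    tsl_label: str = "1"
    utr5_seq: str | None = None
    utr3_seq: str | None = None

    def __post_init__(self):
        if not self.gene_id:
            self.gene_id = "G_" + self.transcript_id
        spliced = self.utr5_len + len(self.cds_seq) + self.utr3_len
        if sum(self.exon_lengths) != spliced:
            raise InfeasibleDesignError(
                f"{self.transcript_id}: exon lengths sum to "
                f"{sum(self.exon_lengths)}, spliced length is {spliced}"
            )
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise InfeasibleDesignError("need one intron per internal junction")
        if any(il < 4 for il in self.intron_lengths):
            raise InfeasibleDesignError("introns must hold GT...AG (>= 4 bp)")
        cds = self.cds_seq
        if len(cds) % 3 != 0 or not cds.startswith("ATG") or cds[-3:] not in _STOPS:
            raise InfeasibleDesignError(f"{self.transcript_id}: invalid CDS")
        for i in range(0, len(cds) - 3, 3):
            if cds[i : i + 3] in _STOPS:
                raise InfeasibleDesignError(
                    f"{self.transcript_id}: internal in-frame stop at codon {i // 3 + 1}"
                )


def random_cds(n_codons: int, rng: random.Random) -> str:
    """Start codon + (n-2) random sense codons + random stop."""
    if n_codons < 2:
        raise InfeasibleDesignError("CDS needs at least start + stop codons")
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2))
    return "ATG" + body + rng.choice(_STOPS)


def _random_seq(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@dataclass
class _TxParts:
    """A realized transcript plus the interval split needed for GTF output."""

    tm: TranscriptModel
    tsl_label: str
    cds_nostop: list[tuple[int, int]]  # genomic ascending, stop codon removed
    stop_codon: list[tuple[int, int]]  # genomic ascending


def _split_stop(
    cds_intervals: list[tuple[int, int]], strand: str
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Remove the terminal 3 coding bases (transcript orientation) from CDS
    intervals, returning (cds_without_stop, stop_codon_intervals), both
    genomically ascending."""
    nostop = [list(iv) for iv in cds_intervals]  # transcript order
    stop: list[tuple[int, int]] = []
    remaining = 3
    i = len(nostop) - 1
    while remaining > 0 and i >= 0:
        s, e = nostop[i]
        take = min(e - s + 1, remaining)
        if strand == "+":
            stop.append((e - take + 1, e))
            nostop[i][1] = e - take
        else:
            stop.append((s, s + take - 1))
            nostop[i][0] = s + take
        remaining -= take
        if nostop[i][1] < nostop[i][0]:
            nostop.pop(i)
        i -= 1
    return sorted(tuple(iv) for iv in nostop), sorted(stop)


def realize_design(
    design: TranscriptDesign, offset: int, rng: random.Random
) -> tuple[str, _TxParts]:
    """Turn a design into a locus sequence (plus-strand of the genome) and a
    :class:`TranscriptModel` placed at 1-based genomic ``offset``."""
    utr5 = design.utr5_seq if design.utr5_seq is not None else _random_seq(
        design.utr5_len, rng
    )
    utr3 = design.utr3_seq if design.utr3_seq is not None else _random_seq(
        design.utr3_len, rng
    )
    spliced = utr5 + design.cds_seq + utr3

    spans: list[tuple[int, int]] = []  # exon spans in spliced coordinates
    o = 0
    for length in design.exon_lengths:
        spans.append((o + 1, o + length))
        o += length

    locus_parts: list[str] = []
    exon_local: list[tuple[int, int]] = []
    pos = 1
    for i, (a, b) in enumerate(spans):
        exon_local.append((pos, pos + (b - a)))
        locus_parts.append(spliced[a - 1 : b])
        pos += b - a + 1
        if i < len(spans) - 1:
            il = design.intron_lengths[i]
            locus_parts.append("GT" + _random_seq(il - 4, rng) + "AG")
            pos += il
    locus = "".join(locus_parts)

    cs, ce = design.utr5_len + 1, design.utr5_len + len(design.cds_seq)
    cds_local: list[tuple[int, int]] = []
    for (a, b), (ls, _le) in zip(spans, exon_local):
        s, e = max(a, cs), min(b, ce)
        if s <= e:
            cds_local.append((ls + (s - a), ls + (e - a)))

    if design.strand == "-":
        n = len(locus)
        locus = revcomp(locus)
        exon_g = [(n - e + 1, n - s + 1) for s, e in exon_local]
        cds_g = [(n - e + 1, n - s + 1) for s, e in cds_local]
    else:
        exon_g, cds_g = exon_local, cds_local

    shift = offset - 1
    exon_g = [(s + shift, e + shift) for s, e in exon_g]
    cds_g = [(s + shift, e + shift) for s, e in cds_g]
    tm = TranscriptModel(
        transcript_id=design.transcript_id,
        gene_id=design.gene_id,
        contig=design.contig,
        strand=design.strand,
        exons=exon_g,
        cds_intervals=cds_g,
        tsl=None if design.tsl_label == "NA" else int(design.tsl_label),
        biotype="protein_coding",
    )
    nostop, stop = _split_stop(cds_g, design.strand)
    return locus, _TxParts(tm, design.tsl_label, nostop, stop)


def make_fixture(
    designs: list[TranscriptDesign], seed: int = 0, spacer: int = 200
) -> tuple[GenomeSequence, TranscriptSet, list[_TxParts]]:
    """Realize designs into an in-memory genome + transcript set.

    Designs sharing a ``contig`` are laid out left to right with random
    spacers between loci.
    """
    rng = random.Random(seed)
    contig_parts: dict[str, list[str]] = {}
    contig_len: dict[str, int] = {}
    parts: list[_TxParts] = []
    for design in designs:
        segs = contig_parts.setdefault(design.contig, [])
        if design.contig not in contig_len:
            pad = _random_seq(spacer, rng)
            segs.append(pad)
            contig_len[design.contig] = spacer
        locus, part = realize_design(design, contig_len[design.contig] + 1, rng)
        segs.append(locus)
        contig_len[design.contig] += len(locus)
        tail = _random_seq(spacer, rng)
        segs.append(tail)
        contig_len[design.contig] += spacer
        parts.append(part)
    genome = GenomeSequence({c: "".join(p) for c, p in contig_parts.items()})
    ts = TranscriptSet({p.tm.transcript_id: p.tm for p in parts})
    return genome, ts, parts


# ---------------------------------------------------------------------------
# file emission (FASTA / GTF / VCF)
# ---------------------------------------------------------------------------


def write_fasta(genome: GenomeSequence, path: str | Path, seed: int | None = None):
    with open(path, "w") as fh:
        for name in genome.contigs:
            desc = f" seed={seed}" if seed is not None else ""
            fh.write(f">{name}{desc}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_gtf(parts: list[_TxParts], path: str | Path, seed: int | None = None):
    """GENCODE-dialect GTF: CDS excludes the stop codon, which is written as
    separate ``stop_codon`` feature(s)."""

    def attrs(tm: TranscriptModel, tsl: str, extra: str = "") -> str:
        return (
            f'gene_id "{tm.gene_id}"; transcript_id "{tm.transcript_id}"; '
            f'transcript_biotype "protein_coding"; '
            f'transcript_support_level "{tsl}";' + extra
        )

    lines = ["#!genome synthetic"]
    if seed is not None:
        lines.append(f"#!seed {seed}")
    for part in parts:
        tm = part.tm
        g0 = min(s for s, _ in tm.exons)
        g1 = max(e for _, e in tm.exons)
        base = [tm.contig, "synth"]
        tail = [".", tm.strand]
        lines.append(
            "\t".join(base + ["gene", str(g0), str(g1)] + tail + [".", attrs(tm, part.tsl_label)])
        )
        lines.append(
            "\t".join(
                base + ["transcript", str(g0), str(g1)] + tail + [".", attrs(tm, part.tsl_label)]
            )
        )
        for k, (s, e) in enumerate(tm.exons, start=1):
            lines.append(
                "\t".join(
                    base
                    + ["exon", str(s), str(e)]
                    + tail
                    + [".", attrs(tm, part.tsl_label, f' exon_number "{k}";')]
                )
            )
        # frame: bases to skip at the start of each CDS piece, transcript order
        tx_order = part.cds_nostop if tm.strand == "+" else part.cds_nostop[::-1]
        cum = 0
        frames = {}
        for s, e in tx_order:
            frames[(s, e)] = (3 - cum % 3) % 3
            cum += e - s + 1
        for s, e in part.cds_nostop:
            lines.append(
                "\t".join(
                    base
                    + ["CDS", str(s), str(e)]
                    + tail
                    + [str(frames[(s, e)]), attrs(tm, part.tsl_label)]
                )
            )
        stop_tx = part.stop_codon if tm.strand == "+" else part.stop_codon[::-1]
        cum = 0
        for s, e in stop_tx:
            frame = (3 - cum % 3) % 3
            cum += e - s + 1
            lines.append(
                "\t".join(
                    base
                    + ["stop_codon", str(s), str(e)]
                    + tail
                    + [str(frame), attrs(tm, part.tsl_label)]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_vcf(
    rows: list[tuple[Variant, str]],
    genome: GenomeSequence,
    path: str | Path,
    seed: int | None = None,
):
    """Write (variant, id-tag) rows as a sorted VCF v4.2 file."""
    lines = ["##fileformat=VCFv4.2"]
    if seed is not None:
        lines.append(f"##source=nmdescape-synth seed={seed}")
    for name, seq in genome.contigs.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    order = {c: i for i, c in enumerate(genome.contigs)}
    for v, tag in sorted(rows, key=lambda r: (order.get(r[0].contig, 99), r[0].pos)):
        lines.append(f"{v.contig}\t{v.pos}\t{tag}\t{v.ref}\t{v.alt}\t.\t.\t.")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# random fixture specification
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Parameters of the random transcript-set generator.

    Defaults give a compact but structurally varied set: up to five exons of
    80-320 bp, short introns, both strands equally represented, and modest
    UTRs. ``include_rule_coverage`` forces one intronless transcript and one
    transcript with a >407 bp exon so every escape rule is reachable.
    """

    n_transcripts: int = 20
    exon_count_range: tuple[int, int] = (1, 5)
    exon_length_range: tuple[int, int] = (80, 320)
    intron_length_range: tuple[int, int] = (40, 120)
    strand_mix: float = 0.5
    utr5_range: tuple[int, int] = (20, 120)
    utr3_range: tuple[int, int] = (30, 200)
    seed: int = 0
    transcripts_per_contig: int = 5
    include_rule_coverage: bool = True


def _designs_from_spec(spec: FixtureSpec) -> list[TranscriptDesign]:
    rng = random.Random(spec.seed)
    designs = []
    for i in range(spec.n_transcripts):
        n_ex = rng.randint(*spec.exon_count_range)
        if spec.include_rule_coverage and i == 0:
            n_ex = 1
        exon_lengths = [rng.randint(*spec.exon_length_range) for _ in range(n_ex)]
        if spec.include_rule_coverage and i == 1:
            n_ex = max(n_ex, 3)
            while len(exon_lengths) < n_ex:
                exon_lengths.append(rng.randint(*spec.exon_length_range))
            exon_lengths[len(exon_lengths) // 2] = 450
        spliced = sum(exon_lengths)
        utr5 = min(rng.randint(*spec.utr5_range), max(0, spliced - 90))
        utr3 = min(rng.randint(*spec.utr3_range), max(0, spliced - utr5 - 66))
        cds_len = spliced - utr5 - utr3
        utr3 += cds_len % 3
        cds_len -= cds_len % 3
        if cds_len < 6:
            raise InfeasibleDesignError("exon lengths cannot host a CDS")
        strand = "-" if rng.random() < spec.strand_mix else "+"
        designs.append(
            TranscriptDesign(
                transcript_id=f"TX{i + 1:03d}",
                gene_id=f"G{i + 1:03d}",
                strand=strand,
                exon_lengths=exon_lengths,
                intron_lengths=[
                    rng.randint(*spec.intron_length_range) for _ in range(n_ex - 1)
                ],
                utr5_len=utr5,
                utr3_len=utr3,
                cds_seq=random_cds(cds_len // 3, rng),
                contig=f"ctg{i // spec.transcripts_per_contig + 1}",
                tsl_label="NA" if n_ex == 1 else "1",
            )
        )
    return designs


def synth_fixture(spec: FixtureSpec):
    """In-memory (genome, transcript set, parts) for a :class:`FixtureSpec`."""
    return make_fixture(_designs_from_spec(spec), seed=spec.seed + 1)


def synth_genome_and_annotation(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the random fixture as FASTA + GTF; deterministic given the seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, _ts, parts = synth_fixture(spec)
    fasta = out_dir / "genome.fa"
    gtf = out_dir / "annotation.gtf"
    write_fasta(genome, fasta, seed=spec.seed)
    write_gtf(parts, gtf, seed=spec.seed)
    return fasta, gtf


# ---------------------------------------------------------------------------
# independent annotation oracle
# ---------------------------------------------------------------------------

_ORC_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _oracle_status(v: Variant, tm: TranscriptModel, splice_margin: int = 2) -> str:
    """Literal per-base overlap classification (independent of ptc.check_overlap)."""
    span = set(range(v.pos, v.pos + len(v.ref)))
    for s, e in tm.cds_intervals:
        if span <= set(range(s, e + 1)):
            return "coding"
    exons = sorted(tm.exons)
    for i, (a, b) in enumerate(exons):
        if i > 0:
            if {a - 1, a} <= span:
                return "splice_excluded"
            if span & set(range(a - splice_margin, a)):
                return "splice_excluded"
        if i < len(exons) - 1:
            if {b, b + 1} <= span:
                return "splice_excluded"
            if span & set(range(b + 1, b + splice_margin + 1)):
                return "splice_excluded"
    return "noncoding"


def oracle_annotate(
    v: Variant,
    tm: TranscriptModel,
    genome: GenomeSequence,
    params: RuleParams | None = None,
    splice_margin: int = 2,
) -> RuleResults:
    """Brute-force annotation of one (variant, transcript) pair.

    Rebuilds the whole mutant spliced transcript base by base, translates it
    with Biopython, locates the first stop, re-derives exon membership by
    cumulative exon walking, and applies the rule definitions directly.
    """
    params = params or RuleParams()
    none = RuleResults()
    if _oracle_status(v, tm, splice_margin) != "coding":
        return none
    contig = genome.contigs[tm.contig]

    walk: list[int] = []
    for a, b in tm.exons:
        walk.extend(range(a, b + 1) if tm.strand == "+" else range(b, a - 1, -1))
    if tm.strand == "+":
        seq = "".join(contig[p - 1] for p in walk)
    else:
        seq = "".join(_ORC_COMP[contig[p - 1]] for p in walk)

    idx_of = {p: i for i, p in enumerate(walk)}
    cds_idxs = sorted(
        idx_of[p] for s, e in tm.cds_intervals for p in range(s, e + 1)
    )
    css = cds_idxs[0]

    span_idxs = sorted(idx_of[p] for p in range(v.pos, v.pos + len(v.ref)))
    i0, i1 = span_idxs[0], span_idxs[-1]
    if tm.strand == "+":
        alt_tx = v.alt
    else:
        alt_tx = "".join(_ORC_COMP[c] for c in reversed(v.alt))
    mutant = seq[:i0] + alt_tx + seq[i1 + 1 :]
    # explicit per-base alignment: mutant index -> reference walk index
    ref_of = list(range(i0)) + [i0] * len(alt_tx) + list(range(i1 + 1, len(seq)))

    coding_m = mutant[css:]
    coding_m = coding_m[: len(coding_m) // 3 * 3]
    protein = str(Seq(coding_m).translate())
    k = protein.find("*")
    if k < 0:
        return none
    m0 = css + 3 * k
    delta = len(v.alt) - len(v.ref)
    alt_first = m0 - css + 1
    canonical_1b = cds_idxs[-3] - css + 1
    if delta % 3 == 0 and alt_first >= canonical_1b + delta:
        return none  # canonical stop, or stop-loss readthrough

    ref_idxs = [ref_of[m0 + j] for j in range(3)]
    ref_cds = [ri - css + 1 for ri in ref_idxs]

    widths = [e - s + 1 for s, e in tm.exons]

    def ordinal_of(walk_idx: int) -> tuple[int, int]:
        cum = 0
        for o, w in enumerate(widths, start=1):
            cum += w
            if walk_idx < cum:
                return o, w
        raise AssertionError("walk index outside exons")

    # "last coding exon" = the exon holding the 3'-most coding base; when a
    # stop codon is split across the final junction this is the downstream
    # exon (a PTC upstream of that junction still has an EJC after it)
    o_last, _ = ordinal_of(cds_idxs[-1])
    first_coding_of_last_exon = (
        min(ci for ci in cds_idxs if ordinal_of(ci)[0] == o_last) - css + 1
    )
    flag_last = ref_cds[0] >= first_coding_of_last_exon

    coding_ords = sorted({ordinal_of(ci)[0] for ci in cds_idxs})
    if len(tm.exons) >= 2 and len(coding_ords) >= 2:
        pen_ord = coding_ords[-2]
        boundary = max(ci for ci in cds_idxs if ordinal_of(ci)[0] == pen_ord) - css + 1
        upstream = [q for q in ref_cds if q <= boundary]
        flag_pen = bool(upstream) and boundary - max(upstream) <= params.d_pen
    else:
        flag_pen = False

    flag_css = alt_first <= params.d_css
    _o_ptc, width_ptc = ordinal_of(ref_idxs[0])
    flag_407 = width_ptc > params.exon_size_min
    flag_single = len(tm.exons) == 1

    flags = {
        "last_exon": flag_last,
        "penultimate": flag_pen,
        "css_proximal": flag_css,
        "exon407": flag_407,
        "single_exon": flag_single,
    }
    return RuleResults(
        is_ptc=True,
        escape_any=any(flags[name] for name in params.enabled),
        **flags,
    )


# ---------------------------------------------------------------------------
# normalization oracle
# ---------------------------------------------------------------------------


def oracle_normalize(v: Variant, genome: GenomeSequence, window: int = 30) -> Variant:
    """Exhaustively enumerate VCF representations of the same edit within a
    window and return the minimal-position, minimal-length parsimonious one."""
    contig = genome.contigs[v.contig]
    w0 = max(1, v.pos - window)
    w1 = min(len(contig), v.pos + len(v.ref) - 1 + window)
    orig = contig[w0 - 1 : w1]
    off = v.pos - w0
    edited = orig[:off] + v.alt + orig[off + len(v.ref) :]
    delta = len(edited) - len(orig)
    best: tuple[int, str, str] | None = None
    for p0 in range(len(orig)):
        if orig[:p0] != edited[:p0]:
            break  # representations further right cannot preserve the prefix
        for rlen in range(0, len(orig) - p0 + 1):
            alen = rlen + delta
            if alen < 1:
                continue
            r = orig[p0 : p0 + rlen]
            a = edited[p0 : p0 + alen]
            if not r:
                continue
            if orig[:p0] + a + orig[p0 + rlen :] != edited:
                continue
            if r[-1] == a[-1]:
                continue  # shared trailing base: not parsimonious
            if len(r) >= 2 and len(a) >= 2 and r[0] == a[0]:
                continue  # shared leading base beyond the anchor
            cand = (w0 + p0, r, a)
            if best is None or (cand[0], len(cand[1])) < (best[0], len(best[1])):
                best = cand
    if best is None:
        raise ValueError(f"no parsimonious representation found for {v.key()}")
    return Variant(v.contig, best[0], best[1], best[2], v.source_id)


# ---------------------------------------------------------------------------
# variant placement
# ---------------------------------------------------------------------------

_PLACEMENT_TARGETS = set(RULE_NAMES) | {"none", "splice", "sensitive"}


def _class_candidates(
    tm: TranscriptModel,
    genome: GenomeSequence,
    vclass: str,
    cds_positions: list[int],
    rng: random.Random,
):
    """Yield candidate Variants of one class anchored at given CDS positions."""
    contig = genome.contigs[tm.contig]
    g2c_inv = tm.region_positions()
    ins_pool = ["TAA", "TTA", "T", "TG", "CTAG", "TCA"]
    for cds_pos in cds_positions:
        gpos = g2c_inv[cds_pos - 1]
        gref = contig[gpos - 1]
        if vclass == "snv":
            for galt in "ACGT":
                if galt != gref:
                    yield Variant(tm.contig, gpos, gref, galt)
        elif vclass == "ins":
            for ins in ins_pool:
                yield Variant(tm.contig, gpos, gref, gref + ins)
        elif vclass == "del":
            for k in (1, 2, 3, 4, 6):
                if gpos + k <= len(contig):
                    yield Variant(tm.contig, gpos, contig[gpos - 1 : gpos + k], gref)
        elif vclass == "delins":
            for rl, alt in ((2, "TAA"), (3, "A"), (2, "CC"), (3, "TGAT")):
                ref = contig[gpos - 1 : gpos - 1 + rl]
                if len(ref) == rl and not alt.startswith(ref):
                    yield Variant(tm.contig, gpos, ref, alt)
        else:
            raise ValueError(f"unknown variant class {vclass!r}")


def _position_order(tm: TranscriptModel, target: str) -> list[int]:
    """CDS anchor positions to try, most promising first."""
    n = tm.cds_len
    if target == "css_proximal":
        return list(range(4, min(n - 3, 160)))
    if target == "penultimate":
        b = tm.penultimate_junction_cds
        lo, hi = max(4, b - 60), min(n - 3, b + 3)
        return list(range(hi, lo - 1, -1))
    if target == "last_exon":
        return list(range(max(4, tm.last_cds_exon_start_cds), n - 3))
    if target == "exon407":
        # positions inside the widest exon
        from .transcripts import exon_of_cds_pos

        widest = max(range(1, tm.n_exons + 1), key=lambda o: tm.exons[o - 1][1] - tm.exons[o - 1][0])
        out = [
            p
            for p in range(4, n - 3)
            if exon_of_cds_pos(tm, p)[0] == widest
        ]
        return out
    # none / sensitive / single_exon: mid-CDS first
    mid = list(range(max(4, n // 3), n - 3))
    return mid + list(range(4, max(4, n // 3)))


def _splice_candidates(tm: TranscriptModel, genome: GenomeSequence):
    contig = genome.contigs[tm.contig]
    exons = sorted(tm.exons)
    for i, (s, e) in enumerate(exons):
        if i < len(exons) - 1 and e + 2 <= len(contig):
            # deletion crossing the exon end into the intron
            yield Variant(tm.contig, e - 1, contig[e - 2 : e + 2], contig[e - 2])
            # SNV in the donor dinucleotide
            yield Variant(tm.contig, e + 1, contig[e], "A" if contig[e] != "A" else "C")
        if i > 0 and s - 2 >= 1:
            yield Variant(tm.contig, s - 2, contig[s - 3 : s + 1], contig[s - 3])


def synth_variants(
    ts: TranscriptSet,
    genome: GenomeSequence,
    placements: list[tuple[str, str, str]],
    out_path: str | Path,
    seed: int = 0,
) -> Path:
    """Emit a VCF whose variants trigger the requested rule profiles.

    Each placement is ``(transcript_id, target, variant_class)`` with target
    one of the five rule names, "none" (coding but no PTC), "sensitive"
    (PTC, no escape), or "splice" (splice-excluded decoy). Every emitted
    variant is verified against the brute-force oracle during the search;
    an infeasible placement raises :class:`InfeasibleDesignError`.
    """
    rng = random.Random(seed)
    rows: list[tuple[Variant, str]] = []
    for tid, target, vclass in placements:
        if target not in _PLACEMENT_TARGETS:
            raise ValueError(f"unknown placement target {target!r}")
        tm = ts.transcripts[tid]
        found = None
        if target == "splice":
            for v in _splice_candidates(tm, genome):
                if _oracle_status(v, tm) == "splice_excluded":
                    found = v
                    break
        else:
            candidates = _class_candidates(
                tm, genome, vclass, _position_order(tm, target), rng
            )
            for v in candidates:
                if _oracle_status(v, tm) != "coding":
                    continue
                rr = oracle_annotate(v, tm, genome)
                if target == "none":
                    ok = not rr.is_ptc
                elif target == "sensitive":
                    ok = rr.is_ptc and not rr.escape_any
                else:
                    ok = rr.is_ptc and getattr(rr, target)
                if ok:
                    found = v
                    break
        if found is None:
            raise InfeasibleDesignError(
                f"no {vclass} variant on {tid} triggers {target!r}"
            )
        rows.append((found, f"{tid}_{target}_{vclass}"))
    out_path = Path(out_path)
    write_vcf(rows, genome, out_path, seed=seed)
    return out_path


def synth_random_variants(
    ts: TranscriptSet,
    genome: GenomeSequence,
    n: int,
    seed: int = 0,
    decoy_fraction: float = 0.12,
) -> list[Variant]:
    """Random genome-consistent variants across all classes and strands.

    Most anchors land inside CDS; ``decoy_fraction`` of anchors are jittered
    off the CDS to produce splice-region and intronic decoys. Returned
    variants are raw (not yet left-normalized).
    """
    rng = random.Random(seed)
    tms = sorted(ts, key=lambda t: t.transcript_id)
    out: list[Variant] = []
    classes = ["snv", "snv", "ins", "del", "delins"]
    while len(out) < n:
        tm = rng.choice(tms)
        contig = genome.contigs[tm.contig]
        cds_pos = rng.randint(1, tm.cds_len)
        gpos = tm.region_positions()[cds_pos - 1]
        if rng.random() < decoy_fraction:
            gpos = max(1, min(len(contig) - 10, gpos + rng.randint(-5, 5)))
        vclass = rng.choice(classes)
        gref = contig[gpos - 1]
        if vclass == "snv":
            galt = rng.choice([b for b in "ACGT" if b != gref])
            v = Variant(tm.contig, gpos, gref, galt)
        elif vclass == "ins":
            length = rng.randint(1, 6)
            ins = "".join(rng.choice("ACGT") for _ in range(length))
            if rng.random() < 0.25 and length >= 3:
                stop = rng.choice(_STOPS)
                at = rng.randint(0, length - 3)
                ins = ins[:at] + stop + ins[at + 3 :]
            v = Variant(tm.contig, gpos, gref, gref + ins)
        elif vclass == "del":
            k = rng.randint(1, 6)
            if gpos + k > len(contig):
                continue
            v = Variant(tm.contig, gpos, contig[gpos - 1 : gpos + k], gref)
        else:
            rl = rng.randint(1, 4)
            ref = contig[gpos - 1 : gpos - 1 + rl]
            if len(ref) < rl:
                continue
            alt = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 5)))
            if alt == ref:
                continue
            v = Variant(tm.contig, gpos, ref, alt)
        if "N" in v.ref or "N" in v.alt:
            continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# boundary-scan fixtures
# ---------------------------------------------------------------------------


def tac_cds(n_codons: int, stop: str = "TAA") -> str:
    """ATG + TAC repeats + stop: every internal codon admits a stop-gain SNV
    (TAC -> TAA/TAG at its third base) and the reference is stop-free in all
    frames across codon boundaries."""
    return "ATG" + "TAC" * (n_codons - 2) + stop


def penultimate_scan_set(
    first_widths: tuple[int, ...] = (90, 91, 92), n_codons: int = 60
) -> tuple[GenomeSequence, TranscriptSet, dict[str, int]]:
    """Two-coding-exon transcripts whose penultimate boundary sits at every
    codon phase, so pooled stop-gain SNVs sample every junction distance."""
    designs = []
    boundaries = {}
    for i, a in enumerate(first_widths):
        cds = tac_cds(n_codons)
        tid = f"PEN{a}"
        strand = "-" if i == 1 else "+"
        designs.append(
            TranscriptDesign(
                transcript_id=tid,
                strand=strand,
                exon_lengths=[12 + a, (len(cds) - a) + 30],
                intron_lengths=[60],
                utr5_len=12,
                utr3_len=30,
                cds_seq=cds,
                contig=f"penctg{i + 1}",
            )
        )
        boundaries[tid] = a
    genome, ts, _parts = make_fixture(designs, seed=11)
    return genome, ts, boundaries


def exon_width_scan_set(
    widths: tuple[int, ...] = (400, 405, 406, 407, 408, 409, 414),
) -> tuple[GenomeSequence, TranscriptSet, dict[str, int]]:
    """Three-coding-exon transcripts whose middle (all-coding) exon width is
    swept across the 407 bp threshold."""
    designs = []
    info = {}
    for i, w in enumerate(widths):
        first_coding, last_coding = 240, 90
        total = first_coding + w + last_coding
        last_coding += (3 - total % 3) % 3
        cds = tac_cds((first_coding + w + last_coding) // 3)
        tid = f"EXW{w}"
        strand = "-" if i % 2 else "+"
        designs.append(
            TranscriptDesign(
                transcript_id=tid,
                strand=strand,
                exon_lengths=[9 + first_coding, w, last_coding + 30],
                intron_lengths=[50, 50],
                utr5_len=9,
                utr3_len=30,
                cds_seq=cds,
                contig=f"exwctg{i + 1}",
            )
        )
        info[tid] = w
    genome, ts, _parts = make_fixture(designs, seed=13)
    return genome, ts, info


def stop_gain_snv(
    tm: TranscriptModel, genome: GenomeSequence, codon: int, to: str = "TAA"
) -> Variant:
    """The genomic SNV that turns TAC codon ``codon`` (1-based) into a stop.

    Only valid on transcripts built with :func:`tac_cds`.
    """
    cds_pos = 3 * codon  # third base of the codon
    gpos = tm.region_positions()[cds_pos - 1]
    gref = genome.contigs[tm.contig][gpos - 1]
    base = {"TAA": "A", "TAG": "G"}[to]
    galt = base if tm.strand == "+" else _ORC_COMP[base]
    if gref == galt:
        raise InfeasibleDesignError(f"codon {codon} of {tm.transcript_id} is not TAC")
    return Variant(tm.contig, gpos, gref, galt)
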