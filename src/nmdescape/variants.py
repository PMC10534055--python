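"""VCF reading, variant left-normalization, and annotated VCF writing.

Variants are held as normalized, biallelic records. Multiallelic VCF records
are split into one :class:`Variant` per alternate allele; symbolic alleles,
breakends, spanning deletions (``*``) and alleles containing N are skipped
and counted. Annotation results are written back into the INFO column under
the ``AENMD`` key, one ``transcript|flags`` entry per annotated transcript.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pysam

from .rules import RuleResults
from .transcripts import GenomeSequence

log = logging.getLogger(__name__)

AENMD_INFO_LINE = (
    '##INFO=<ID=AENMD,Number=.,Type=String,Description='
    '"transcript_id|is_ptc|last_exon|penultimate|css_proximal|exon407|single_exon">'
)

_ALLOWED = set("ACGT")


@dataclass(frozen=True)
class Variant:
    """One biallelic chrom/pos/ref/alt record (1-based pos of first ref base)."""

    contig: str
    pos: int
    ref: str
    alt: str
    source_id: str = ""

    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"


def variant_class(v: Variant) -> str:
    """Classify a *normalized* variant: snv / ins / del / delins."""
    lr, la = len(v.ref), len(v.alt)
    if lr == 1 and la == 1:
        return "snv"
    if lr == 1 and la > 1:
        return "ins" if v.alt[0] == v.ref[0] else "delins"
    if lr > 1 and la == 1:
        return "del"
    return "delins"


@dataclass
class ReadStats:
    records: int = 0
    variants: int = 0
    multiallelic_records: int = 0
    skipped_symbolic: int = 0
    skipped_star: int = 0
    skipped_n: int = 0
    skipped_malformed: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def read_variants(
    vcf_path: str | Path,
    stats: ReadStats | None = None,
    with_allele_info: bool = False,
) -> Iterator:
    """Stream Variants from a VCF (v4.x, plain or gzip/bgzip).

    Multiallelic records are split per alt. With ``with_allele_info=True``
    yields ``(Variant, allele_index, n_alts)`` tuples instead of bare
    Variants (allele_index is 1-based).
    """
    stats = stats if stats is not None else ReadStats()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            stats.records += 1
            alts = rec.alts or ()
            if len(alts) > 1:
                stats.multiallelic_records += 1
            ref = (rec.ref or "").upper()
            for k, alt in enumerate(alts, start=1):
                alt = (alt or "").upper()
                if alt.startswith("<") or "[" in alt or "]" in alt:
                    stats.skipped_symbolic += 1
                    continue
                if alt == "*":
                    stats.skipped_star += 1
                    continue
                if not ref or not alt or not (set(ref) <= _ALLOWED) or not (
                    set(alt) <= _ALLOWED
                ):
                    stats.skipped_n += 1
                    continue
                v = Variant(
                    contig=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    source_id=f"{rec.chrom}:{rec.pos}:{ref}:{alt}",
                )
                stats.variants += 1
                yield (v, k, len(alts)) if with_allele_info else v


class RefMismatchError(ValueError):
    """REF allele does not match the genome at the stated position."""


def left_normalize(v: Variant, genome: GenomeSequence) -> Variant:
    """Left-align and make parsimonious one biallelic variant.

    The classic normalization loop: repeatedly truncate a shared trailing
    base; when either allele becomes empty, extend both one base leftward
    from the genome; finally trim shared leading bases while both alleles
    have length >= 2. Idempotent, and the implied edit to the genome string
    is unchanged.
    """
    contig = genome.contigs.get(v.contig)
    if contig is None:
        if not genome.ensure_alias(v.contig):
            raise KeyError(f"contig {v.contig!r} absent from genome")
        contig = genome.contigs[v.contig]
    ref, alt, pos = v.ref.upper(), v.alt.upper(), v.pos
    if contig[pos - 1 : pos - 1 + len(ref)] != ref:
        raise RefMismatchError(
            f"{v.contig}:{v.pos} REF {v.ref!r} does not match genome"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if not ref or not alt:
            if pos <= 1:
                raise ValueError(
                    f"normalization underflows contig start at {v.contig}:{v.pos}"
                )
            pos -= 1
            b = contig[pos - 1]
            ref, alt = b + ref, b + alt
            continue
        break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(v.contig, pos, ref, alt, v.source_id)


# ---------------------------------------------------------------------------
# AENMD entry formatting
# ---------------------------------------------------------------------------


def format_rule_entry(label: str, rr: RuleResults) -> str:
    """``transcript|P|L|U|C|E|S`` with 0/1 flags (is_ptc, last exon,
    penultimate, CSS-proximal, 407-plus, single exon)."""
    flags = (
        rr.is_ptc,
        rr.last_exon,
        rr.penultimate,
        rr.css_proximal,
        rr.exon407,
        rr.single_exon,
    )
    return label + "|" + "|".join("1" if f else "0" for f in flags)


def parse_rule_entry(entry: str) -> tuple[str, RuleResults]:
    parts = entry.split("|")
    label, bits = parts[0], [p == "1" for p in parts[1:]]
    if len(bits) != 6:
        raise ValueError(f"malformed AENMD entry: {entry!r}")
    rr = RuleResults(
        is_ptc=bits[0],
        last_exon=bits[1],
        penultimate=bits[2],
        css_proximal=bits[3],
        exon407=bits[4],
        single_exon=bits[5],
        escape_any=any(bits[1:]),
    )
    return label, rr


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":  # gzip/bgzip
        return gzip.open(path, "rt")
    return open(path, "rt")


def write_annotated_vcf(
    vcf_in: str | Path,
    annotations: Mapping[str, Sequence[str]],
    out_path: str | Path,
) -> None:
    """Copy ``vcf_in`` to ``out_path`` adding AENMD INFO entries.

    ``annotations`` maps per-alt source ids (``CHROM:POS:REF:ALT`` of the
    *original* record) to preformatted entry strings (see
    :func:`format_rule_entry`). Input records are preserved byte-for-byte;
    records without annotations pass through unmodified. The AENMD header
    line is inserted before #CHROM.
    """
    out_path = Path(out_path)
    with _open_text(vcf_in) as src, open(out_path, "w") as dst:
        for line in src:
            line = line.rstrip("\n")
            if line.startswith("##"):
                dst.write(line + "\n")
                continue
            if line.startswith("#CHROM"):
                dst.write(AENMD_INFO_LINE + "\n")
                dst.write(line + "\n")
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                dst.write(line + "\n")
                continue
            chrom, pos, _id, ref, alt_field = fields[0], fields[1], fields[2], fields[3], fields[4]
            entries: list[str] = []
            for alt in alt_field.split(","):
                key = f"{chrom}:{pos}:{ref.upper()}:{alt.upper()}"
                entries.extend(annotations.get(key, ()))
            if entries:
                info = fields[7]
                tag = "AENMD=" + ",".join(entries)
                fields[7] = tag if info in (".", "") else info + ";" + tag
            dst.write("\t".join(fields) + "\n")
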