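"""Genome access, transcript models, and spliced-CDS coordinate arithmetic.

All genomic coordinates are 1-based and closed (the GTF/VCF convention).
Spliced-CDS coordinates are 1-based with position 1 being the first base of
the start codon; they extend past the coding sequence into the 3'UTR so that
frameshift-induced stop codons downstream of the canonical stop can still be
located on the transcript.

Transcript models are loaded from GTF or GFF3, then filtered the way
high-confidence protein-coding transcript sets are usually built: protein
coding biotype, transcript support level (TSL) 1 (or missing TSL for
intronless transcripts), coding length divisible by three, and standard
chromosomes only.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import gffutils
import pyfaidx
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: chr1-22, X, Y, M plus their un-prefixed aliases (MT for mitochondria).
STANDARD_CHROMS: frozenset[str] = frozenset(
    [str(i) for i in range(1, 23)]
    + ["X", "Y", "M", "MT"]
    + [f"chr{i}" for i in range(1, 23)]
    + ["chrX", "chrY", "chrM", "chrMT"]
)


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def normalize_contig(name: str) -> str:
    """Strip a leading ``chr`` so VCF and GTF contig naming styles compare equal."""
    return name[3:] if name.startswith("chr") else name


@dataclass
class GenomeSequence:
    """In-memory genome: contig name -> upper-case nucleotide string."""

    contigs: dict[str, str]

    def fetch(self, contig: str, start: int, end: int) -> str:
        """1-based closed substring of a contig."""
        return self.contigs[contig][start - 1 : end]

    def base(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos - 1]

    def ensure_alias(self, name: str) -> bool:
        """Make ``name`` resolvable if a chr/no-chr alias of it is present.

        Returns True when the name now resolves. The alias shares the same
        underlying string (no copy).
        """
        if name in self.contigs:
            return True
        want = normalize_contig(name)
        for existing in list(self.contigs):
            if normalize_contig(existing) == want:
                self.contigs[name] = self.contigs[existing]
                log.warning("contig %r matched via chr-alias of %r", name, existing)
                return True
        return False


def load_genome(fasta_path: str | Path) -> GenomeSequence:
    """Load a FASTA file into memory.

    Contig names are taken from the header up to the first whitespace;
    sequence is upper-cased and characters outside {A,C,G,T,N} become N.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    fa = pyfaidx.Fasta(
        str(fasta_path), as_raw=True, sequence_always_upper=True, rebuild=True
    )
    contigs: dict[str, str] = {}
    for name in fa.keys():
        seq = str(fa[name][:])
        contigs[name] = "".join(c if c in "ACGTN" else "N" for c in seq)
    fa.close()
    if not contigs:
        raise ValueError(f"empty FASTA: {fasta_path}")
    return GenomeSequence(contigs)


@dataclass
class TranscriptModel:
    """One transcript: exon/CDS structure in transcript (5'->3') order.

    ``exons`` and ``cds_intervals`` are lists of 1-based closed genomic
    ``(start, end)`` tuples, ordered 5'->3' in transcript orientation (i.e.
    descending genomic coordinate on the minus strand). ``cds_intervals``
    include the canonical stop codon.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: Literal["+", "-"]
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    tsl: int | None = None
    biotype: str = "protein_coding"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- basic structure ---------------------------------------------------
    @property
    def cds_len(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_single_exon(self) -> bool:
        return len(self.exons) == 1

    @property
    def n_coding_exons(self) -> int:
        return len(self.cds_intervals)

    @property
    def last_cds_exon_start_cds(self) -> int:
        """Spliced-CDS position of the first coding base of the last coding exon."""
        s, e = self.cds_intervals[-1]
        return self.cds_len - (e - s + 1) + 1

    @property
    def penultimate_junction_cds(self) -> int:
        """Spliced-CDS position of the 3'-most coding base of the penultimate
        coding exon (0 when there is at most one coding exon)."""
        return self.last_cds_exon_start_cds - 1

    # -- spliced walks (cached) --------------------------------------------
    def spliced_positions(self) -> list[int]:
        """Genomic position of every exonic base, in transcript order."""
        cached = self._cache.get("spliced")
        if cached is None:
            out: list[int] = []
            for s, e in self.exons:
                rng = range(s, e + 1) if self.strand == "+" else range(e, s - 1, -1)
                out.extend(rng)
            cached = self._cache["spliced"] = out
        return cached

    def _cds_offset(self) -> int:
        """Index into spliced_positions() of CDS position 1; validates that the
        CDS is a contiguous block of the spliced transcript."""
        cached = self._cache.get("cds_offset")
        if cached is None:
            spliced = self.spliced_positions()
            cds_set: set[int] = set()
            for s, e in self.cds_intervals:
                cds_set.update(range(s, e + 1))
            if len(cds_set) != self.cds_len:
                raise ValueError(f"{self.transcript_id}: overlapping CDS intervals")
            off = next(
                (i for i, p in enumerate(spliced) if p in cds_set), None
            )
            if off is None:
                raise ValueError(f"{self.transcript_id}: CDS outside exons")
            block = spliced[off : off + self.cds_len]
            if set(block) != cds_set:
                raise ValueError(
                    f"{self.transcript_id}: CDS not contiguous in spliced transcript"
                )
            cached = self._cache["cds_offset"] = off
        return cached

    def region_positions(self) -> list[int]:
        """Genomic positions of the spliced CDS + 3'UTR, transcript order."""
        cached = self._cache.get("region_pos")
        if cached is None:
            cached = self._cache["region_pos"] = self.spliced_positions()[
                self._cds_offset() :
            ]
        return cached

    def region_seq(self, genome: GenomeSequence) -> str:
        """Reference CDS + 3'UTR nucleotide string (transcript orientation)."""
        cached = self._cache.get("region_seq")
        if cached is None:
            contig = genome.contigs[self.contig]
            if self.strand == "+":
                seq = "".join(contig[p - 1] for p in self.region_positions())
            else:
                seq = "".join(
                    complement(contig[p - 1]) for p in self.region_positions()
                )
            cached = self._cache["region_seq"] = seq
        return cached

    def g2c_map(self) -> dict[int, int]:
        cached = self._cache.get("g2c")
        if cached is None:
            pos = self.region_positions()[: self.cds_len]
            cached = self._cache["g2c"] = {p: i + 1 for i, p in enumerate(pos)}
        return cached


def coding_sequence(tm: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced coding sequence (start codon through canonical stop)."""
    if tm.contig not in genome.contigs and not genome.ensure_alias(tm.contig):
        raise KeyError(f"contig {tm.contig!r} absent from genome")
    return tm.region_seq(genome)[: tm.cds_len]


def coordinate_map(
    tm: TranscriptModel, pos: int, direction: Literal["g2c", "c2g"]
) -> int | None:
    """Convert between genomic and spliced-CDS coordinates.

    ``g2c`` returns None for genomic positions outside the CDS intervals;
    ``c2g`` raises for positions outside [1, CDS length].
    """
    if direction == "g2c":
        return tm.g2c_map().get(pos)
    if direction == "c2g":
        if not 1 <= pos <= tm.cds_len:
            raise ValueError(f"CDS position {pos} outside [1, {tm.cds_len}]")
        return tm.region_positions()[pos - 1]
    raise ValueError(f"unknown direction {direction!r}")


def exon_of_cds_pos(tm: TranscriptModel, cds_pos: int) -> tuple[int, int]:
    """(exon ordinal, exon genomic width) for a spliced-CDS position.

    The ordinal is 1-based in transcript orientation and counts all exons,
    including pure-UTR ones. Width is the full annotated exon width (UTR
    included).
    """
    if not 1 <= cds_pos <= tm.cds_len:
        raise ValueError(f"CDS position {cds_pos} outside [1, {tm.cds_len}]")
    return exon_of_region_pos(tm, cds_pos)


def exon_of_region_pos(tm: TranscriptModel, region_pos: int) -> tuple[int, int]:
    """Like :func:`exon_of_cds_pos` but also accepts 3'UTR positions."""
    positions = tm.region_positions()
    if not 1 <= region_pos <= len(positions):
        raise ValueError(f"region position {region_pos} outside transcript")
    gpos = positions[region_pos - 1]
    for ordinal, (s, e) in enumerate(tm.exons, start=1):
        if s <= gpos <= e:
            return ordinal, e - s + 1
    raise ValueError(f"{tm.transcript_id}: position {gpos} outside exons")


# ---------------------------------------------------------------------------
# transcript sets
# ---------------------------------------------------------------------------


@dataclass
class TranscriptSet:
    """A collection of transcripts with a per-contig interval index over CDS spans."""

    transcripts: dict[str, TranscriptModel]
    load_report: dict[str, int] = field(default_factory=dict)
    filter_report: dict[str, int] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] | None = field(
        default=None, repr=False, compare=False
    )

    def __iter__(self):
        return iter(self.transcripts.values())

    def __len__(self) -> int:
        return len(self.transcripts)

    def _build_trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for tm in self.transcripts.values():
            if not tm.cds_intervals:
                continue
            lo = min(s for s, _ in tm.cds_intervals)
            hi = max(e for _, e in tm.cds_intervals)
            trees.setdefault(normalize_contig(tm.contig), IntervalTree()).addi(
                lo, hi + 1, tm.transcript_id
            )
        return trees

    def overlapping(self, contig: str, start: int, end: int) -> list[TranscriptModel]:
        """Transcripts whose CDS span overlaps [start, end] (1-based closed).

        Deterministic: results sorted by transcript id.
        """
        if self._trees is None:
            self._trees = self._build_trees()
        tree = self._trees.get(normalize_contig(contig))
        if tree is None:
            return []
        hits = sorted({iv.data for iv in tree.overlap(start, end + 1)})
        return [self.transcripts[tid] for tid in hits]

    def fingerprint(self) -> str:
        """Stable hash of transcript IDs and CDS spans (for index validation)."""
        h = hashlib.sha256()
        for tid in sorted(self.transcripts):
            tm = self.transcripts[tid]
            h.update(tid.encode())
            h.update(tm.contig.encode())
            h.update(tm.strand.encode())
            for s, e in tm.cds_intervals:
                h.update(f":{s}-{e}".encode())
            h.update(b";")
        return h.hexdigest()


@dataclass(frozen=True)
class FilterCriteria:
    """Transcript-set filters for a high-confidence coding transcript set.

    Defaults: protein-coding biotype, TSL 1 (missing TSL tolerated for
    single-exon transcripts), CDS length divisible by three, standard
    chromosomes.
    """

    require_biotype: frozenset[str] = frozenset({"protein_coding"})
    max_tsl: int = 1
    allow_missing_tsl_single_exon: bool = True
    require_cds_mod3: bool = True
    contig_allowlist: frozenset[str] | Literal["all"] = STANDARD_CHROMS


def filter_transcript_set(ts: TranscriptSet, crit: FilterCriteria) -> TranscriptSet:
    """Apply :class:`FilterCriteria`; removal counts land in ``filter_report``."""
    kept: dict[str, TranscriptModel] = {}
    counts = {"biotype": 0, "tsl": 0, "cds_mod3": 0, "contig": 0}
    for tid, tm in ts.transcripts.items():
        if crit.contig_allowlist != "all" and tm.contig not in crit.contig_allowlist:
            counts["contig"] += 1
            continue
        if crit.require_biotype and tm.biotype not in crit.require_biotype:
            counts["biotype"] += 1
            continue
        if tm.tsl is None:
            if not (crit.allow_missing_tsl_single_exon and tm.is_single_exon):
                counts["tsl"] += 1
                continue
        elif tm.tsl > crit.max_tsl:
            counts["tsl"] += 1
            continue
        if crit.require_cds_mod3 and tm.cds_len % 3 != 0:
            counts["cds_mod3"] += 1
            continue
        kept[tid] = tm
    for name, n in counts.items():
        if n:
            log.info("filter removed %d transcripts (%s)", n, name)
    return TranscriptSet(kept, load_report=dict(ts.load_report), filter_report=counts)


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Coalesce overlapping or directly adjacent intervals (genomic order)."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _feature_transcript_id(feat) -> str | None:
    attrs = feat.attributes
    if "transcript_id" in attrs:
        return attrs["transcript_id"][0]
    if "Parent" in attrs:
        parent = attrs["Parent"][0]
        return parent.split(":", 1)[1] if parent.startswith("transcript:") else parent
    return None


def _parse_tsl(raw: str | None) -> int | None:
    if raw is None:
        return None
    token = raw.strip().split()[0] if raw.strip() else ""
    try:
        return int(token)
    except ValueError:
        return None  # "NA" and friends


def load_transcript_models(
    annotation_path: str | Path, dialect: Literal["gtf", "gff3", "auto"] = "auto"
) -> TranscriptSet:
    """Load transcript models from a GTF or GFF3 file (plain or gzipped).

    Exons and CDS features are grouped per transcript and ordered 5'->3' in
    transcript orientation. Separate ``stop_codon`` features (the GENCODE GTF
    dialect excludes the stop codon from CDS) are merged into the CDS so the
    coding sequence includes its terminal codon. Transcripts with CDS but no
    exons, or with CDS outside every exon, are skipped and counted.
    """
    db = gffutils.create_db(
        str(annotation_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}

    def rec(tid: str) -> dict:
        return per_tx.setdefault(
            tid,
            {
                "exons": [],
                "cds": [],
                "stop": [],
                "contig": None,
                "strand": None,
                "gene": "",
                "tsl": None,
                "biotype": None,
            },
        )

    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype in ("transcript", "mrna"):
            tid = feat.attributes.get("transcript_id", feat.attributes.get("ID", [""]))[0]
            tid = tid.split(":", 1)[1] if tid.startswith("transcript:") else tid
            if not tid:
                continue
            r = rec(tid)
            r["tsl"] = _parse_tsl(
                (feat.attributes.get("transcript_support_level") or [None])[0]
            )
            for key in ("transcript_biotype", "transcript_type", "biotype"):
                if key in feat.attributes:
                    r["biotype"] = feat.attributes[key][0]
                    break
            r["gene"] = (feat.attributes.get("gene_id") or [""])[0]
            continue
        if ftype not in ("exon", "cds", "stop_codon"):
            continue
        tid = _feature_transcript_id(feat)
        if tid is None:
            continue
        r = rec(tid)
        r["contig"] = feat.seqid
        r["strand"] = feat.strand
        if not r["gene"]:
            r["gene"] = (feat.attributes.get("gene_id") or [""])[0]
        if r["biotype"] is None:
            for key in ("transcript_biotype", "transcript_type", "biotype"):
                if key in feat.attributes:
                    r["biotype"] = feat.attributes[key][0]
                    break
        if r["tsl"] is None and "transcript_support_level" in feat.attributes:
            r["tsl"] = _parse_tsl(feat.attributes["transcript_support_level"][0])
        iv = (feat.start, feat.end)
        {"exon": r["exons"], "cds": r["cds"], "stop_codon": r["stop"]}[ftype].append(iv)

    transcripts: dict[str, TranscriptModel] = {}
    report = {"no_cds": 0, "no_exons": 0, "cds_outside_exons": 0, "bad_strand": 0}
    for tid, r in per_tx.items():
        if not r["cds"]:
            report["no_cds"] += 1
            continue
        if not r["exons"]:
            log.warning("transcript %s has CDS but no exons; skipped", tid)
            report["no_exons"] += 1
            continue
        if r["strand"] not in ("+", "-"):
            report["bad_strand"] += 1
            continue
        exons = _merge_intervals(r["exons"])
        cds = _merge_intervals(r["cds"] + r["stop"])
        if not all(
            any(es <= s and e <= ee for es, ee in exons) for s, e in cds
        ):
            log.warning("transcript %s has CDS outside exons; skipped", tid)
            report["cds_outside_exons"] += 1
            continue
        if r["strand"] == "-":
            exons = exons[::-1]
            cds = cds[::-1]
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=r["gene"],
            contig=r["contig"],
            strand=r["strand"],
            exons=exons,
            cds_intervals=cds,
            tsl=r["tsl"],
            biotype=r["biotype"] if r["biotype"] is not None else "protein_coding",
        )
    for name, n in report.items():
        if n:
            log.info("annotation load skipped %d transcripts (%s)", n, name)
    return TranscriptSet(transcripts, load_report=report)
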