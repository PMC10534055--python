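# Methods

## Model

NMD surveillance is modelled positionally: whether a transcript carrying a
premature termination codon (PTC) is degraded depends on where translation
terminates relative to the transcript's intron–exon structure, not on the
variant that caused it. The annotator therefore works in two stages:

1. **Locate the 5′-most novel stop.** For each normalized variant and each
   overlapping transcript, the mutant coding sequence is reconstructed
   explicitly: the spliced reference CDS *plus the 3′UTR* is extracted in
   transcript orientation (alleles reverse-complemented on the minus
   strand), the REF span is replaced by ALT, and the result is scanned
   codon-by-codon from the start codon. Extending the scan through the
   3′UTR is what lets frameshifts whose novel stop lies past the canonical
   stop be annotated. Because the mutant string itself is scanned, both the
   size and the content of inserted sequence matter: an insertion carrying
   an in-frame TAA terminates at the insertion, a same-length sense
   insertion does not.
2. **Apply the escape rules** to that stop's location (next section).

### Coordinates

Genomic coordinates are 1-based closed (GTF/VCF convention). Spliced-CDS
coordinates are 1-based with position 1 = first base of the start codon and
run through the 3′UTR. Mutant (alt) positions map back to reference
positions by a three-piece alignment: identity upstream of the variant,
clamp-to-anchor inside the replaced/inserted span, shift by −(len ALT −
len REF) downstream. The anchor is the transcript-orientation 5′-most
affected base.

### What counts as premature

The first stop found is reported unless termination is not actually
premature: for frame-preserving variants (indel length ≡ 0 mod 3) a first
stop at or past the shifted canonical stop position is either the canonical
stop itself (possibly swapped for another stop codon, or restored by the
alt allele) or a stop-loss readthrough stop — neither is a PTC, and
stop-loss consequence calling is out of scope. Under a frameshift every
stop reached is novel, including ones in the 3′UTR.

## The five rules

* **last exon** — reference position of the PTC's first base ≥ first coding
  base of the last coding exon. "Last coding exon" is the exon holding the
  3′-most coding base; when an annotated stop codon is split across the
  final junction this is deliberately the downstream exon, because a PTC
  upstream of that junction still has an exon-junction complex deposited
  after it. Frameshift PTCs in 3′UTR sequence count as downstream and
  return true.
* **penultimate exon** (`d_pen`, default 50 bp) — distance measured along
  the spliced CDS from the boundary (3′-most coding base of the penultimate
  coding exon) to the PTC nucleotide closest to, and not past, that
  boundary. A PTC codon straddling the junction anchors at its
  boundary-proximal base; a short penultimate exon lets PTCs in earlier
  exons qualify. "Within d bp" is read inclusively (≤ d).
* **CSS-proximal** (`d_css`, default 150 bp) — the PTC's first base lies
  within the first `d_css` bases of the **mutant** CDS. Mutant coordinates
  are used because the PTC may sit inside inserted sequence that has no
  reference position; the frame is configurable in principle but mutant is
  the default and only shipped behavior. Inclusive boundary.
* **407-bp exon** — the full annotated genomic width of the exon containing
  the PTC (UTR portions included) is strictly greater than 407 bp. Full
  width rather than coding-only width is used because the rule is stated in
  terms of the exon's span; the threshold is a parameter.
* **single exon** — the transcript has exactly one exon.

`escape_any` is the disjunction of the flags over the enabled-rule subset;
individual flags are always reported as computed, so restricting the subset
changes only the disjunction. All five flags plus `is_ptc` are emitted per
transcript into the `AENMD` INFO field as `0`/`1` columns.

## Variant handling

* **Left-normalization** uses the classic algorithm: repeatedly truncate a
  shared trailing base, extending both alleles one genome base leftward
  whenever one becomes empty; finally trim shared leading bases while both
  alleles keep length ≥ 2. It is idempotent and preserves the edit. The
  test suite checks it against an independent oracle that enumerates every
  VCF representation of the edit inside a ±30 bp window and picks the
  minimal-position, minimal-length parsimonious one.
* **Splice exclusion**: variants whose REF span crosses an exon–intron
  boundary or touches the intronic splice margin at an internal junction
  are not analyzed. The margin defaults to the 2 canonical donor/acceptor
  bases (`--splice-margin`); exonic bases adjacent to a junction are *not*
  excluded. Coding status requires the whole REF span inside one CDS
  interval, so the margin never bites for coding spans.
* **Multiallelic records** are split per ALT; symbolic alleles, breakends,
  spanning deletions (`*`) and alleles containing N are skipped and
  counted. Annotations are written back onto the original records (keyed by
  `CHROM:POS:REF:ALT` of the raw per-alt record) so the output preserves
  input records byte-for-byte; entries from multiallelic records tag the
  transcript with `#k` (1-based allele index).

## Transcript set

GTF and GFF3 are both read (gffutils); separate GENCODE-style `stop_codon`
features are merged into the CDS so the coding sequence includes its
terminal codon. Default filters reproduce a high-confidence coding set:
protein-coding biotype, TSL ≤ 1 with missing TSL tolerated only for
intronless transcripts, CDS length divisible by 3, and a standard-chromosome
allowlist (chr1–22, X, Y, M, with chr/no-chr aliasing applied when matching
VCF and genome contig names). Filtered-out transcripts are counted, not
errors, so arbitrary public GTFs load.

## The SNV index

All stop-gain SNVs of a transcript set are pre-enumerated — for every CDS
position, each of the three alternative bases is constructed and scanned
exactly like any other variant — and stored in a character trie keyed by
`contig:zero-padded-position:REF>ALT` (padding width derived from contig
length so lexicographic order is genomic order). The serialized form is a
sorted flat file carrying a fingerprint (hash of transcript IDs + CDS
spans); loading against a different transcript set fails fast. Lookup is
used only for SNVs; non-SNVs are always constructed explicitly. Annotation
with and without the index is identical by construction and verified
byte-for-byte in the tests.

## Synthetic data and oracles

The generator emits multi-exon protein-coding transcripts with valid CDS
(ATG start, terminal stop, length ≡ 0 mod 3, no internal in-frame stop —
bodies are drawn from the 61 sense codons), UTRs, GT…AG introns, and both
strands; defaults are 20 transcripts, 1–5 exons of 80–320 bp, introns of
40–120 bp, an even strand mix, and one forced intronless transcript plus
one forced >407 bp exon so every rule is reachable. Transcripts whose stop
codon straddles the last junction arise naturally and are kept — real
annotations contain them. Everything is written as plain FASTA + GENCODE
dialect GTF (seed recorded in the headers), and variant placement searches
genomic candidates until the *oracle* confirms the requested rule profile.

Two independent oracles back the equivalence tests and share no code with
the annotator: a literal-string re-annotation (rebuild the whole mutant
spliced transcript base by base, translate with Biopython, re-derive exon
membership by cumulative exon walking, apply the rule definitions directly)
and the exhaustive normalization search described above.

What passing against this generator does and does not show: it covers the
full combinatorics of variant classes, strands, junction-spanning codons,
frameshift read-through into UTRs and inserted-stop content on compact
transcripts; it does not model realistic base composition, overlapping
genes, shared exons between isoforms, very long exons/introns, or
population allele frequencies, so performance claims at biobank scale are
out of scope.

## Problem sizes and numerics

The default verification sizes — chosen to exercise every code path while
keeping a full run interactive — are: ≥ 5000 random variant–transcript
pairs for oracle agreement, every coding SNV of the fixture set (tens of
thousands) for index equivalence, ≥ 1000 denormalized indels for
normalization, and exhaustive stop-gain scans over engineered transcripts
for the rule boundaries. Because an in-frame stop always starts on a codon
boundary, single-transcript scans sample junction distances at 3 bp steps;
the boundary fixtures therefore sweep the penultimate boundary across all
three codon phases, giving 1 bp resolution for the 50 bp rule, and the
exon-size fixture sweeps exon widths in 1 bp steps around 407. CSS
distances are intrinsically codon-granular (the largest flagged stop start
is 148, the smallest unflagged is 151 under the inclusive ≤ 150 default);
the reported boundary is the smallest unflagged position minus one.

Determinism: a single seeded generator stream per fixture; the CLI is
deterministic for fixed inputs (rerun output is byte-identical).

## Known limitations

* No splice-disruption prediction: a variant destroying a splice site is
  excluded, not reinterpreted.
* No NMD efficacy scores — boolean per-rule flags only.
* The scan stops at the annotated transcript 3′ end; a frameshift with no
  stop before the transcript end yields no call rather than a readthrough
  prediction.
* Genotype columns are passed through untouched; structural variants and
  phasing are out of scope.
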