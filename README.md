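# nmdescape

Annotate premature-termination-codon (PTC) variants with predicted escape
from nonsense-mediated mRNA decay (NMD) — a library plus a VCF-in/VCF-out
command-line tool.

## The problem

A variant that introduces a premature stop codon usually destroys its
transcript: NMD recognizes termination upstream of the last exon–exon
junction and degrades the mRNA, making the allele a loss-of-function allele.
But PTCs in particular transcript locations *escape* NMD; the truncated
protein is then produced and can act dominant-negatively or gain function.
Distinguishing the two outcomes matters for interpreting clinical variants,
and it has to work for **every** PTC-generating variant class — not just
stop-gain SNVs but also insertions, deletions and delins, including
frameshifts whose novel stop appears far downstream of the variant, and
insertions that carry a stop codon *inside the inserted sequence*.

`nmdescape` reconstructs the mutant coding sequence of every
variant–transcript pair explicitly, locates the 5′-most novel stop codon,
and evaluates five established escape rules:

| rule | predicted escape when | parameter |
|---|---|---|
| last exon | the PTC lies in the last coding exon | — |
| penultimate exon | the PTC lies ≤ *d*<sub>pen</sub> bp upstream of the penultimate exon's 3′ boundary (spliced distance) | *d*<sub>pen</sub> = 50 |
| CSS-proximal | the PTC starts ≤ *d*<sub>css</sub> bp after the coding start site (mutant coordinates) | *d*<sub>css</sub> = 150 |
| 407-bp exon | the PTC's exon spans > 407 bp | 407 |
| single exon | the transcript is intronless | — |

A pair matching **any** enabled rule is predicted to escape; all five flags
are reported individually so users can restrict attention to, say, the
exon-junction-complex rules only.

## Worked example

The package ships a synthetic-fixture generator, so a complete run needs no
external data:

```sh
python - <<'EOF'
from nmdescape.synthetic import FixtureSpec, synth_genome_and_annotation, synth_variants
from nmdescape.transcripts import load_genome, load_transcript_models, \
    filter_transcript_set, FilterCriteria
fa, gtf = synth_genome_and_annotation(FixtureSpec(seed=3), "demo")
g = load_genome(fa)
ts = filter_transcript_set(load_transcript_models(gtf),
                           FilterCriteria(contig_allowlist="all"))
synth_variants(ts, g, [
    ("TX001", "single_exon", "snv"), ("TX002", "splice", "del"),
    ("TX002", "exon407", "snv"),     ("TX002", "penultimate", "snv"),
    ("TX002", "last_exon", "snv"),   ("TX003", "penultimate", "delins"),
    ("TX003", "none", "snv"),        ("TX003", "css_proximal", "ins"),
    ("TX004", "sensitive", "snv"),   ("TX004", "last_exon", "del"),
], "demo/variants.vcf", seed=4)
EOF

nmdescape annotate --fasta demo/genome.fa --gtf demo/annotation.gtf \
    --in demo/variants.vcf --out demo/out.vcf --contigs all
```

The output VCF carries one `AENMD` INFO entry per annotated transcript, with
the format `transcript|is_ptc|last_exon|penultimate|css_proximal|exon407|single_exon`:

```text
ctg1  309   TX001_single_exon_snv     G     A     .  .  AENMD=TX001|1|1|0|1|0|1
ctg1  932   TX002_splice_del          GCGT  G     .  .  .
ctg1  986   TX002_exon407_snv         C     T     .  .  AENMD=TX002|1|0|0|0|1|0
ctg1  1427  TX002_penultimate_snv     A     T     .  .  AENMD=TX002|1|0|1|0|1|0
ctg1  1493  TX002_last_exon_snv       G     T     .  .  AENMD=TX002|1|1|0|0|0|0
ctg1  2281  TX003_penultimate_delins  GG    TAA   .  .  AENMD=TX003|1|0|1|0|0|0
ctg1  2524  TX003_none_snv            C     A     .  .  .
ctg1  2809  TX003_css_proximal_ins    G     GTTA  .  .  AENMD=TX003|1|0|0|1|0|0
ctg1  3481  TX004_sensitive_snv       C     T     .  .  AENMD=TX004|1|0|0|0|0|0
ctg1  4101  TX004_last_exon_del       TG    T     .  .  AENMD=TX004|1|1|0|0|0|0
```

Reading the flags: the stop-gain in the intronless TX001 escapes by the
single-exon (and last-exon, CSS-proximal) rules; the splice-spanning
deletion is excluded from analysis; the synonymous SNV on TX003 creates no
PTC and passes through unannotated; `TX004_sensitive_snv` is a PTC that
matches no rule — predicted NMD-sensitive. A machine-readable summary lands
next to the output (`demo/out.vcf.summary`), e.g.

```text
pairs_coding=9
pairs_escape_any=7
pairs_ptc=8
pairs_rule_css_proximal=2
pairs_rule_exon407=2
pairs_rule_last_exon=3
pairs_rule_penultimate=2
pairs_rule_single_exon=1
pairs_splice_excluded=1
variants_annotated=8
```

For repeated runs over the same transcript set, pre-compute the stop-gain
SNV index once (a trie over `contig:pos:REF>ALT` keys); annotation output
with and without the index is byte-identical:

```sh
nmdescape build-index --fasta demo/genome.fa --gtf demo/annotation.gtf \
    --index demo/ptc.idx --contigs all
nmdescape annotate ... --index demo/ptc.idx
```

Real annotations work the same way: pass a genome FASTA and a
GENCODE/ENSEMBL GTF (or GFF3); the default transcript filters keep
protein-coding transcripts on standard chromosomes with transcript support
level 1 (or missing TSL for intronless transcripts) and CDS length
divisible by three.

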