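# Methods

## Coordinate model

All coordinates are GTF-native: 1-based, fully closed intervals, length
`end − start + 1`. The in-memory hierarchy (annotation → gene →
transcript → feature segment) is reconstructed purely from the
`gene_id`/`transcript_id` attributes of feature lines, so dialects
without explicit `gene`/`transcript` rows (UCSC-exported RefSeq) load
identically to Ensembl-style files. Unknown column-3 feature types map to
an `other` kind but keep their original string, so any GTF round-trips
feature-for-feature. Chromosome aliasing is a pure relabelling applied at
parse time; alt-contig dropping matches a configurable name pattern
(default `_alt|_random`) because alt-scaffold naming varies between
assemblies. Genes asserted on several chromosomes are kept and flagged as
*split* rather than rejected: the curation stage needs to see them to
apply the larger-piece rule.

The stop codon is **not** part of the 3'UTR. `three_prime_utr` segments
are consumed as written; the optional `derive_utr3_from_cds` helper (for
dialects that omit UTR rows) computes exon ∖ (CDS ∪ stop) strictly 3' of
the stop codon, and is off by default in the audit so that the counts
reflect what the file actually declares — the audit's purpose is to
measure annotation completeness, not to repair it. A transcript without a
stop codon has no derivable UTR boundary and is flagged, not guessed.

## Completeness audit

A gene is *coding* iff any transcript carries ≥1 CDS segment; biotype
labels are not required, which keeps the audit dialect-independent. A
gene *has* a stop codon or 3'UTR iff any of its transcripts does
(gene-level collapse over unique gene IDs, so alternatively spliced
multi-exon UTRs are not double-counted). Aggregates are exactly
reproducible from the emitted per-gene rows; a per-transcript table is
also emitted for finer inspection.

## Terminal-exon anchoring and length classes

Per gene, the representative transcript maximises total 3'UTR length,
with ties broken by lexicographically smallest transcript ID — a
deterministic stand-in for an arbitrary pick, as is the
smallest-ID survivor when terminal exons with identical coordinates are
collapsed. The anchor is the 5' boundary of the 3'-most UTR-containing
exon (start on `+`, end on `-`): annotations disagree about how far a
UTR extends but rarely about the splice site where the terminal exon
begins, which makes exact anchor equality a high-precision join that
avoids many-to-many ambiguity. When two entries in the other annotation
share an anchor, the one with the longest UTR is paired and the row is
flagged ambiguous.

The length-class threshold τ = 50 nt ("longer" means a difference
strictly greater than τ) absorbs trivial end-trimming differences;
classification of a third annotation is against max(len_A, len_B), so
"longer in the merge" means longer than *either* source.

## Transcript matching

Intron chains (ordered splice-junction pairs in genomic coordinates)
define structural equivalence. Class priority when several query
transcripts overlap one reference transcript: `=` > `c` > `j` > `o` >
`x` > `u`, ties broken by larger exonic overlap then smaller transcript
ID. Two multi-exon transcripts are `=` iff chains are identical
(terminal-exon outer boundaries free). Two single-exon transcripts are
`=` iff their overlap covers ≥ 0.8 of **both** exons; the fraction is
applied to both deliberately — if it were applied only to the shorter,
any exon nested inside a longer one would classify `=` and single-exon
containment (`c`) would be unreachable. A single exon wholly inside one
reference exon is `c`; a multi-exon query whose chain is a contiguous
sub-chain of the reference is `c`. Unstranded (`.`) features are compared
against both strands and can never be `=`. The 0.8 fraction is
configurable; it is an explicit, testable stand-in for the matching
tool-chain defaults commonly used for this comparison.

Missing-gene confirmation implements a deliberate asymmetry: a single
same-strand overlap anywhere on any transcript rescues a gene, so the
confirmed-missing list contains only genes with no structural footprint
at all in the query — the coordinate equivalent of re-searching the query
for any matching gene ID before declaring a gene absent.

## Curation of a merged annotation

* **Fusion transcripts**: flagged iff exons overlap exons of ≥2 distinct
  same-strand reference genes, each by ≥ `min_overlap_bp` (default 30 nt
  — roughly half a short exon; the threshold only needs to separate
  genuine exon sharing from a few bases of slop, and is configurable).
  Reference genes representing the same locus in two source annotations
  (same symbol) count once. Removal is idempotent: a second pass flags
  nothing.
* **Small RNAs**: gene-level removal by biotype
  (rRNA/snRNA/snoRNA/sRNA/miscRNA); miRNA is never removed, whatever the
  configured set, since miRNA genes are legitimate quantification targets.
  An annotation with no biotype labels is returned unchanged with a
  warning.
* **Nomenclature**: Ensembl symbol first, RefSeq symbol second, the
  locus's own XLOC-style ID last. Conflicts — one merged gene matching
  references with different symbols, or one symbol landing on several
  merged loci — are reported, not auto-resolved: symbol conflicts in real
  curation are resolved partly by judgment, so the tool's default is a
  faithful report.
* **Add-back**: confirmed-missing reference genes are copied verbatim (no
  exon re-fitting), tagged with their provenance. For split genes only
  the piece with the larger **total exonic span** is added (exonic span,
  not transcript span, because a stray single-exon fragment can still
  have a long genomic footprint); a piece carrying the 3'UTR wins exact
  ties. A gene whose exons collide with an existing curated gene on the
  same strand is skipped with a report, preventing the add-back from
  re-creating removed fusions. Genes removed as structural small RNAs are
  excluded from the add-back candidate lists — otherwise the pipeline
  would re-import exactly what it just removed, since those genes remain
  "missing" relative to the source annotation that still carries them.
* **LL IDs**: assigned in (chromosome, gene start, gene ID) order —
  deterministic across runs — and written into every GTF line's
  attributes so expression matrices quantified against the GTF join the
  gene-information table on a stable key.

## Novel-locus triage

Redundancy against the reference annotations is decided first (`=`/`c`
on the same strand), because a locus that re-describes an existing gene
should be removed even if it has protein evidence. Retention then
requires protein homology at exact/high/moderate confidence ("low" fails
— it is indistinguishable from spurious hits), or structural overlap with
a published lincRNA (`=`, `c`, `j` or `o`), or more than one exon
(splicing is itself evidence of a real transcript). Confidence tiers are
consumed as given in the evidence table; the package does not run
homology searches.

## Synthetic study conditions

The generator lays genes sequentially (intergenic gaps 500–2000 nt,
1–10 exons of 50–2000 nt, introns 60–2000 nt, 3'UTRs 100–1200 nt) across
four 60 Mb chromosomes by default, and plants every discrepancy class
with bookkeeping sufficient to predict all module outputs exactly. Default
proportions reflect the completeness gap typical of a large Ensembl-style
annotation versus a RefSeq-style one: 18% vs 6% of coding genes without
any 3'UTR, 6% vs 1% without stop codons, structural small RNAs in only
the former. Planted 3'UTR deltas are log-uniform on [60, 5000] nt —
strictly above the 50 nt threshold — with separate within-threshold
controls (1–50 nt) that must classify "same"; UTR-length discrepancies
between real annotations span a few tens of nt to multi-kb, hence the
log scale. Rescue decoys overlap their target gene by 10 nt (enough to
rescue, below the 30 nt fusion threshold). A single seeded random stream
drives everything; identical seeds give byte-identical GTFs.

What the fixtures do **not** emulate: nucleotide sequence (coordinates
only), overlapping gene nests and antisense gene pairs beyond the planted
cases, multi-isoform genes (one transcript per generated gene except at
merged loci), soft intron-boundary wobble, and chromosome-scale gene
density. Passing the oracle suite therefore demonstrates that the
algorithms implement their stated rules exactly, not that real-annotation
edge cases (e.g. gffcompare's full class-code vocabulary on deeply nested
loci) are all reproduced.

## Numerical and degenerate-input choices

Interval trees store closed GTF intervals as half-open `[start, end+1)`.
Empty annotations audit to all-zero reports and serialise to empty files.
All tie-breaks (representative transcripts, collapsed duplicates, best
match, LL order) resolve by lexicographic ID so outputs are reproducible
bit-for-bit, independent of input order and of the `--threads` setting
(computation is single-threaded; the flag exists for interface
compatibility and is echoed into the run manifest). The acceptance script
runs the default study at 500 matched genes — large enough that every
planted class occurs at realistic multiplicity, small enough to complete
in seconds.

## Known limitations

Anchor matching is exact by design: annotations that shift a terminal
splice site by even 1 nt will not match (the tested conditions plant no
such wobble). Only the six class codes listed are implemented, not the
full gffcompare vocabulary (i, e, p, s, y, r), and `.tracking`/`.loci`
outputs are out of scope. GFF3 input, sequence handling and
assembly validation are out of scope; evidence tables are consumed, never
produced.
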