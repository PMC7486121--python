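# annoforge

Audit, compare and curate transcriptome annotations.

Two GTF annotations of the same genome assembly — say an Ensembl release
and a RefSeq build for zebrafish GRCz11 — routinely disagree in ways that
matter for RNA-seq: a large fraction of coding genes may lack any
transcript with an annotated 3'UTR or stop codon, matched genes may carry
3'UTRs differing by kilobases, and each annotation contains thousands of
genes the other lacks. Because oligo-dT-primed bulk libraries and droplet
scRNA-seq concentrate reads at transcript 3' ends, a truncated or missing
3'UTR model silently drops those reads from quantification, and the same
dataset can yield visibly different differential-expression calls under
different annotations. annoforge is a toolkit for measuring those
discrepancies and for mechanising the curation of a merged, improved
annotation. It is aimed at genome-annotation engineers and RNA-seq
bioinformaticians who need the comparison to be exact, deterministic and
reproducible.

## What it computes

**Completeness audit.** For an annotation with gene set $G$, the audit
reports $|G|$, the coding subset $G_{CDS} = \{g : g$ has a CDS segment$\}$,
and the counts of coding genes with no `stop_codon` and no
`three_prime_utr` feature on *any* transcript (gene-level collapse over
unique gene IDs, driven purely by GTF column 3).

**Reference gene set via terminal-3'UTR-exon anchoring.** For each gene
the representative transcript is the one maximising the 3'UTR length
$u(t) = \sum_{s \in \mathrm{3'UTR}(t)} (\mathrm{end}_s - \mathrm{start}_s + 1)$.
Its terminal UTR-bearing exon is anchored at its 5' boundary (exon start
on `+`, exon end on `-`) — a splice boundary that is stable across
annotations even when the annotated UTR extends different distances.
Genes are matched across annotations by exact anchor equality, and the
matched pair is classified by

$$\mathrm{class}(u_A, u_B) = \begin{cases}
\text{longer\_A} & u_A - u_B > \tau \\
\text{longer\_B} & u_B - u_A > \tau \\
\text{same} & |u_A - u_B| \le \tau
\end{cases}, \qquad \tau = 50\ \mathrm{nt}.$$

A third annotation (e.g. a merged build) is then judged against
$\max(u_A, u_B)$ with the same threshold.

**Transcript matching and missing genes.** Transcripts are compared by
intron chain — the ordered splice-junction list — with gffcompare-style
class codes `=` (identical chain; terminal exon boundaries free), `c`
(contained sub-chain), `j` (shared junction), `o` (same-strand exonic
overlap), `x` (antisense overlap only), `u` (none). A reference gene is
*confirmed missing* from a query annotation only when every one of its
transcripts classifies `x` or `u`; any same-strand overlap rescues it.

**Curation.** On a merged annotation: flag and remove fusion transcripts
(exons bridging ≥2 same-strand reference genes, each overlap ≥30 bp),
drop structural small RNAs (rRNA/snRNA/snoRNA/sRNA/miscRNA — never
miRNA), assign nomenclature by priority (Ensembl symbol → RefSeq symbol →
XLOC id) with conflict reporting, add confirmed-missing reference genes
back verbatim (for split genes, the piece with the larger exonic span and
the 3'UTR wins), and assign stable `LL1, LL2, …` gene IDs in positional
order, emitting a one-row-per-gene information table.

**Novel-locus triage.** An XLOC locus is *redundant* if structurally
matched/contained in a reference transcript; otherwise it is retained iff
it has an exact/high/moderate protein-homology hit, or structural overlap
with a published lincRNA, or more than one exon — else dropped.

A seeded fixture generator produces paired annotations with all of these
discrepancies planted and recorded in a manifest that predicts every
module's exact output, serving as an end-to-end oracle.

## Worked example

```sh
annoforge simulate --seed 7 --n-genes 80 --outdir fx/
annoforge audit --gtf fx/annA.gtf --out fx/audit.tsv
```

prints

```
# annotation	annA
All Genes	116
annotated CDS	98
CDS, missing annotated stop codon	5
CDS, missing annotated 3' UTR	14
```

i.e. of 116 genes, 98 are coding, and 14 of those (≈14%) have no
transcript with an annotated 3'UTR — genes whose expression a 3'-biased
library will undercount. Comparing the pair and folding in the merge:

```sh
annoforge refset --gtf-a fx/annA.gtf --gtf-b fx/annB.gtf --gtf-c fx/merged.gtf --out fx/refset.tsv
```

```
reference genes	71
same	55
longer_A	10
longer_B	6
```

71 genes anchor-match between the two annotations; 55 have equivalent
3'UTRs (within 50 nt) while 10 and 6 are longer in A or B respectively —
the genes where the choice of annotation changes read capture. The full
curation pipeline (`annoforge curate`) then reports the fusion
transcripts removed, genes added back and the final curated gene count,
and `annoforge classify-novel` partitions the XLOC loci into
retain/drop/redundant.

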