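"""Coordinate data model and GTF input/output.

The in-memory hierarchy is ``GenomeAnnotation`` -> ``GeneModel`` ->
``TranscriptModel`` -> ``FeatureSegment``, reconstructed purely from the
``gene_id``/``transcript_id`` attributes of GTF feature lines, so that
annotations whose dialect lacks explicit ``gene``/``transcript`` lines
(e.g. UCSC-exported RefSeq) load identically to Ensembl-style files.

Coordinates follow the GTF convention throughout: 1-based, fully closed
intervals, so a segment of length L spans ``end - start + 1 = L`` bases.
The stop codon is *not* counted as part of the 3'UTR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

__all__ = [
    "Interval",
    "FeatureSegment",
    "TranscriptModel",
    "GeneModel",
    "GenomeAnnotation",
    "GtfParseError",
    "UtrUnderivableError",
    "read_gtf",
    "write_gtf",
    "utr3_length",
    "derive_utr3_from_cds",
    "read_alias_table",
    "DEFAULT_ALT_PATTERN",
]

#: Chromosome names matching this pattern are treated as alternate/patch
#: contigs when ``drop_alt`` is requested.  Configurable because naming of
#: alt scaffolds varies between assemblies.
DEFAULT_ALT_PATTERN = r"_alt|_random"

SEGMENT_KINDS = ("exon", "CDS", "stop_codon", "five_prime_utr", "three_prime_utr", "other")

# column-3 values normalised into the internal kind vocabulary
_KIND_MAP = {
    "exon": "exon",
    "CDS": "CDS",
    "stop_codon": "stop_codon",
    "five_prime_utr": "five_prime_utr",
    "three_prime_utr": "three_prime_utr",
    "5UTR": "five_prime_utr",
    "3UTR": "three_prime_utr",
}


class GtfParseError(ValueError):
    """A GTF line could not be interpreted; carries the 1-based line number."""


class UtrUnderivableError(ValueError):
    """A 3'UTR cannot be derived because the transcript lacks a stop codon."""


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based, closed genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "Interval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class FeatureSegment:
    """One GTF feature line belonging to a transcript.

    ``kind`` is the normalised feature class; ``raw_kind`` preserves the
    original column-3 string so unknown feature types round-trip verbatim.
    """

    interval: Interval
    kind: str
    raw_kind: str = ""
    source: str = "annoforge"
    frame: str = "."
    attrs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.raw_kind:
            object.__setattr__(self, "raw_kind", self.kind)

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class TranscriptModel:
    """A transcript: an ordered bag of feature segments on one chrom/strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    segments: list[FeatureSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments.sort(key=lambda s: (s.interval.start, s.interval.end, s.kind))

    def add_segment(self, seg: FeatureSegment) -> None:
        if seg.interval.chrom != self.chrom:
            raise ValueError(
                f"segment chrom {seg.interval.chrom} != transcript chrom {self.chrom} "
                f"({self.transcript_id})"
            )
        self.segments.append(seg)
        self.segments.sort(key=lambda s: (s.interval.start, s.interval.end, s.kind))

    def segments_of(self, kind: str) -> list[FeatureSegment]:
        return [s for s in self.segments if s.kind == kind]

    @property
    def exons(self) -> list[FeatureSegment]:
        """Exon segments in genomic (left-to-right) order."""
        return self.segments_of("exon")

    @property
    def span(self) -> Interval:
        return Interval(
            self.chrom,
            min(s.interval.start for s in self.segments),
            max(s.interval.end for s in self.segments),
            self.strand,
        )

    def has(self, kind: str) -> bool:
        return any(s.kind == kind for s in self.segments)

    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing a gene identifier.

    Transcripts asserted on multiple chromosomes are retained (the gene is
    then *split*); downstream curation decides which piece to keep.
    """

    gene_id: str
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    symbol: str | None = None
    name: str | None = None
    biotype: str | None = None
    #: stable curated identifier (LL1, LL2, ...) once assigned
    ll_id: str | None = None
    #: provenance/confidence note set during curation (e.g. added_back_*)
    match_note: str | None = None

    @property
    def chroms(self) -> list[str]:
        return sorted({t.chrom for t in self.transcripts.values()})

    @property
    def is_split(self) -> bool:
        return len(self.chroms) > 1

    @property
    def chrom(self) -> str:
        return self.chroms[0]

    @property
    def strand(self) -> str:
        strands = {t.strand for t in self.transcripts.values()}
        return strands.pop() if len(strands) == 1 else "."

    def span_on(self, chrom: str) -> Interval | None:
        txs = [t for t in self.transcripts.values() if t.chrom == chrom]
        if not txs:
            return None
        return Interval(
            chrom,
            min(t.span.start for t in txs),
            max(t.span.end for t in txs),
            self.strand,
        )


class GenomeAnnotation:
    """A labelled, chromosome-indexed collection of gene models."""

    def __init__(self, label: str, genes: Mapping[str, GeneModel] | None = None):
        self.label = label
        self.genes: dict[str, GeneModel] = dict(genes or {})
        self._exon_index: dict[tuple[str, str], IntervalTree] | None = None
        self._validate()

    def _validate(self) -> None:
        seen_tx: dict[str, str] = {}
        for gid, gene in self.genes.items():
            if gene.gene_id != gid:
                raise ValueError(f"gene map key {gid} != gene_id {gene.gene_id}")
            for tid in gene.transcripts:
                if tid in seen_tx:
                    raise ValueError(
                        f"transcript_id {tid} appears in genes {seen_tx[tid]} and {gid}"
                    )
                seen_tx[tid] = gid

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gene in self.genes.values():
            yield from gene.transcripts.values()

    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def add_gene(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        self._exon_index = None

    def remove_gene(self, gene_id: str) -> GeneModel:
        self._exon_index = None
        return self.genes.pop(gene_id)

    def split_genes(self) -> list[str]:
        """Gene IDs asserted on more than one chromosome."""
        return sorted(g.gene_id for g in self.genes.values() if g.is_split)

    # -- interval index -----------------------------------------------------
    def exon_index(self) -> dict[tuple[str, str], IntervalTree]:
        """Per-(chrom, strand) interval tree over exons.

        Tree payloads are ``(gene_id, transcript_id)``.  intervaltree uses
        half-open coordinates, so closed GTF intervals are stored as
        ``[start, end + 1)``.
        """
        if self._exon_index is None:
            idx: dict[tuple[str, str], IntervalTree] = {}
            for gene in self.genes.values():
                for tx in gene.transcripts.values():
                    key = (tx.chrom, tx.strand)
                    tree = idx.setdefault(key, IntervalTree())
                    for ex in tx.exons:
                        tree.addi(
                            ex.interval.start,
                            ex.interval.end + 1,
                            (gene.gene_id, tx.transcript_id),
                        )
            self._exon_index = idx
        return self._exon_index

    def invalidate_index(self) -> None:
        self._exon_index = None

    def copy(self, label: str | None = None) -> "GenomeAnnotation":
        genes = {
            gid: GeneModel(
                gene_id=g.gene_id,
                transcripts={
                    tid: TranscriptModel(
                        transcript_id=t.transcript_id,
                        gene_id=t.gene_id,
                        chrom=t.chrom,
                        strand=t.strand,
                        segments=list(t.segments),
                    )
                    for tid, t in g.transcripts.items()
                },
                symbol=g.symbol,
                name=g.name,
                biotype=g.biotype,
                ll_id=g.ll_id,
                match_note=g.match_note,
            )
            for gid, g in self.genes.items()
        }
        return GenomeAnnotation(label or self.label, genes)


# ---------------------------------------------------------------------------
# GTF reading
# ---------------------------------------------------------------------------

def read_alias_table(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV mapping source chromosome names to targets."""
    aliases: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"alias table line is not 2 columns: {line!r}")
            aliases[parts[0]] = parts[1]
    return aliases


def _first(attrs, key: str) -> str | None:
    vals = attrs.get(key)
    return vals[0] if vals else None


def read_gtf(
    path: str | Path,
    label: str,
    alias_table: Mapping[str, str] | None = None,
    drop_alt: bool = False,
    alt_pattern: str = DEFAULT_ALT_PATTERN,
    strict_chroms: bool = False,
) -> GenomeAnnotation:
    """Parse a GTF file into a :class:`GenomeAnnotation`.

    Parameters
    ----------
    alias_table
        Optional chromosome rename map applied to every feature (pure
        relabelling; feature counts are unchanged).
    drop_alt
        Exclude features on chromosomes whose (aliased) name matches
        ``alt_pattern``.
    strict_chroms
        When an alias table is given and strict mode is on, chromosomes
        absent from the table raise instead of passing through unchanged.
    """
    alias_table = dict(alias_table or {})
    alt_re = re.compile(alt_pattern)
    genes: dict[str, GeneModel] = {}
    tx_owner: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {line.count(chr(9)) + 1}"
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # pragma: no cover - defensive
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc

            chrom = feat.seqid
            if chrom in alias_table:
                chrom = alias_table[chrom]
            elif alias_table and strict_chroms:
                raise GtfParseError(
                    f"{path}:{lineno}: chromosome {chrom!r} has no alias and "
                    "strict mode is on"
                )
            if drop_alt and alt_re.search(chrom):
                continue

            gene_id = _first(feat.attributes, "gene_id")
            if gene_id is None:
                raise GtfParseError(f"{path}:{lineno}: feature lacks gene_id")
            symbol = _first(feat.attributes, "gene_name")
            gname = _first(feat.attributes, "gene_description") or _first(
                feat.attributes, "description"
            )
            biotype = _first(feat.attributes, "gene_biotype") or _first(
                feat.attributes, "gene_type"
            )

            gene = genes.get(gene_id)
            if gene is None:
                gene = GeneModel(gene_id=gene_id)
                genes[gene_id] = gene
            if symbol and gene.symbol is None:
                gene.symbol = symbol
            if gname and gene.name is None:
                gene.name = gname
            if biotype and gene.biotype is None:
                gene.biotype = biotype

            if feat.featuretype == "gene":
                continue

            tx_id = _first(feat.attributes, "transcript_id")
            if tx_id is None:
                raise GtfParseError(
                    f"{path}:{lineno}: non-gene feature lacks transcript_id"
                )
            if feat.featuretype == "transcript":
                # hierarchy line: ensure the transcript exists, no segment
                _get_tx(gene, tx_owner, tx_id, gene_id, chrom, feat.strand, path, lineno)
                continue

            kind = _KIND_MAP.get(feat.featuretype, "other")
            extra = tuple(
                (k, feat.attributes[k][0])
                for k in feat.attributes
                if k
                not in (
                    "gene_id",
                    "transcript_id",
                    "gene_name",
                    "gene_biotype",
                    "gene_type",
                    "gene_description",
                    "description",
                )
            )
            seg = FeatureSegment(
                interval=Interval(chrom, feat.start, feat.end, feat.strand),
                kind=kind,
                raw_kind=feat.featuretype,
                source=feat.source,
                frame=feat.frame,
                attrs=extra,
            )
            tx = _get_tx(gene, tx_owner, tx_id, gene_id, chrom, feat.strand, path, lineno)
            if tx.chrom != chrom:
                # split transcript pieces are modelled as per-chromosome
                # transcripts suffixed with the chromosome name
                alt_id = f"{tx_id}__{chrom}"
                tx = _get_tx(gene, tx_owner, alt_id, gene_id, chrom, feat.strand, path, lineno)
            tx.add_segment(seg)

    return GenomeAnnotation(label, genes)


def _get_tx(gene, tx_owner, tx_id, gene_id, chrom, strand, path, lineno) -> TranscriptModel:
    owner = tx_owner.get(tx_id)
    if owner is not None and owner != gene_id:
        raise GtfParseError(
            f"{path}:{lineno}: transcript {tx_id} assigned to genes {owner} and {gene_id}"
        )
    tx_owner[tx_id] = gene_id
    tx = gene.transcripts.get(tx_id)
    if tx is None:
        tx = TranscriptModel(
            transcript_id=tx_id, gene_id=gene_id, chrom=chrom, strand=strand
        )
        gene.transcripts[tx_id] = tx
    return tx


# ---------------------------------------------------------------------------
# GTF writing
# ---------------------------------------------------------------------------

def _format_attrs(gene: GeneModel, tx: TranscriptModel, seg: FeatureSegment) -> str:
    parts = [f'gene_id "{tx.gene_id}"', f'transcript_id "{tx.transcript_id}"']
    if gene.symbol:
        parts.append(f'gene_name "{gene.symbol}"')
    if gene.biotype:
        parts.append(f'gene_biotype "{gene.biotype}"')
    if gene.name:
        parts.append(f'gene_description "{gene.name}"')
    for key, val in sorted(seg.attrs):
        parts.append(f'{key} "{val}"')
    return "; ".join(parts) + ";"


def write_gtf(ann: GenomeAnnotation, path: str | Path) -> None:
    """Serialise an annotation to GTF.

    Output is deterministically ordered (chrom, start, end, feature kind,
    transcript_id) with attribute order gene_id, transcript_id, gene
    metadata, then remaining keys sorted, so identical annotations yield
    byte-identical files.
    """
    rows = []
    for gene in ann.genes.values():
        for tx in gene.transcripts.values():
            for seg in tx.segments:
                rows.append((seg.interval.chrom, seg.interval.start, seg.interval.end,
                             seg.raw_kind, tx.transcript_id, gene, tx, seg))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3], r[4]))
    with open(path, "w") as fh:
        for chrom, start, end, raw_kind, _tid, gene, tx, seg in rows:
            fh.write(
                "\t".join(
                    (
                        chrom,
                        seg.source,
                        raw_kind,
                        str(start),
                        str(end),
                        ".",
                        seg.interval.strand,
                        seg.frame,
                        _format_attrs(gene, tx, seg),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# 3'UTR arithmetic
# ---------------------------------------------------------------------------

def utr3_length(t: TranscriptModel) -> int:
    """Total annotated 3'UTR length of a transcript in nucleotides.

    The sum of ``three_prime_utr`` segment lengths; 0 when the transcript
    carries none.  Purely segment-based: invariant under segment order and
    strand.
    """
    return sum(s.length for s in t.segments_of("three_prime_utr"))


def derive_utr3_from_cds(t: TranscriptModel) -> TranscriptModel:
    """Derive 3'UTR segments for GTF dialects that omit explicit UTR lines.

    The 3'UTR is the exonic sequence strictly 3' of the stop codon
    (exclusive of the stop codon itself).  Returns a new transcript with
    ``three_prime_utr`` segments appended; idempotent when the transcript
    already carries them.

    Raises
    ------
    UtrUnderivableError
        If the transcript has no stop codon: the 3' boundary of the CDS is
        then unknown and the transcript is left for the caller to flag.
    """
    if t.has("three_prime_utr"):
        return t
    stops = t.segments_of("stop_codon")
    if not stops:
        raise UtrUnderivableError(
            f"transcript {t.transcript_id} has no stop_codon; 3'UTR underivable"
        )
    if t.strand == "+":
        utr_from = max(s.interval.end for s in stops) + 1
    else:
        utr_to = min(s.interval.start for s in stops) - 1

    new_segs = list(t.segments)
    for ex in t.exons:
        if t.strand == "+":
            lo, hi = max(ex.interval.start, utr_from), ex.interval.end
        else:
            lo, hi = ex.interval.start, min(ex.interval.end, utr_to)
        if lo <= hi:
            new_segs.append(
                FeatureSegment(
                    interval=Interval(t.chrom, lo, hi, t.strand),
                    kind="three_prime_utr",
                    raw_kind="three_prime_utr",
                    source=ex.source,
                )
            )
    return replace_segments(t, new_segs)


def replace_segments(t: TranscriptModel, segments: list[FeatureSegment]) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        chrom=t.chrom,
        strand=t.strand,
        segments=segments,
    )
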