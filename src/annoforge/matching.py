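"""Coordinate-based transcript matching and missing-gene detection.

Transcripts are compared by structure, not identifier: the ordered list of
splice junctions (the *intron chain*) defines equivalence.  Two multi-exon
transcripts with identical chains are a full match even when their
terminal exon boundaries differ — UTR-length disagreements must not break
gene matching.  Each reference transcript is assigned its best same-locus
query class, using single-character codes compatible with gffcompare
output:

    =  FULL              identical intron chain (or reciprocal single-exon
                         overlap at/above the configured fraction)
    c  CONTAINED         query chain is a contiguous sub-chain of the
                         reference (or a single exon inside a reference exon)
    j  JUNCTION_OVERLAP  at least one shared splice junction
    o  EXONIC_OVERLAP    same-strand exonic overlap, no shared junction
    x  ANTISENSE         exonic overlap only on the opposite strand
    u  NONE              no exonic overlap at the locus

A reference gene is *confirmed missing* from the query only when every one
of its transcripts classifies as antisense-only or no-overlap; any
same-strand overlap anywhere rescues the gene (the gene-ID re-search step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .model import GenomeAnnotation, TranscriptModel

__all__ = [
    "MatchClass",
    "IntronChain",
    "MatchReport",
    "intron_chain",
    "classify_pair",
    "match_annotations",
    "confirm_missing_genes",
    "intersect_gene_sets",
    "DEFAULT_SINGLE_EXON_FRACTION",
]

#: Minimum reciprocal overlap (as a fraction of the shorter transcript) for
#: two single-exon transcripts to count as a full match.
DEFAULT_SINGLE_EXON_FRACTION = 0.8


class MatchClass(Enum):
    FULL = "="
    CONTAINED = "c"
    JUNCTION_OVERLAP = "j"
    EXONIC_OVERLAP = "o"
    ANTISENSE = "x"
    NONE = "u"


#: higher = better; used to pick the best query class per reference transcript
_PRIORITY = {
    MatchClass.FULL: 5,
    MatchClass.CONTAINED: 4,
    MatchClass.JUNCTION_OVERLAP: 3,
    MatchClass.EXONIC_OVERLAP: 2,
    MatchClass.ANTISENSE: 1,
    MatchClass.NONE: 0,
}

#: classes that rescue a gene from the missing list (same-strand overlap)
RESCUING = {
    MatchClass.FULL,
    MatchClass.CONTAINED,
    MatchClass.JUNCTION_OVERLAP,
    MatchClass.EXONIC_OVERLAP,
}


@dataclass(frozen=True)
class IntronChain:
    chrom: str
    strand: str
    junctions: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        flat = [p for j in self.junctions for p in j]
        if flat != sorted(flat) or len(set(flat)) != len(flat):
            raise ValueError("junctions must be strictly increasing")


def intron_chain(t: TranscriptModel) -> IntronChain:
    """The transcript's splice junctions: (donor, acceptor) genomic pairs.

    Junction i is (end of exon i, start of exon i+1) in genomic order;
    single-exon transcripts have an empty chain.
    """
    exons = t.exons
    junctions = tuple(
        (exons[i].interval.end, exons[i + 1].interval.start)
        for i in range(len(exons) - 1)
    )
    return IntronChain(t.chrom, t.strand, junctions)


def _exonic_overlap_bp(q: TranscriptModel, r: TranscriptModel) -> int:
    total = 0
    for qe in q.exons:
        for re_ in r.exons:
            total += qe.interval.overlap_bp(re_.interval)
    return total


def _is_subchain(small: tuple, big: tuple) -> bool:
    n, m = len(small), len(big)
    if n == 0 or n > m:
        return False
    return any(big[i : i + n] == small for i in range(m - n + 1))


def classify_pair(
    q: TranscriptModel,
    r: TranscriptModel,
    single_exon_fraction: float = DEFAULT_SINGLE_EXON_FRACTION,
) -> MatchClass:
    """Structural class of query transcript ``q`` against reference ``r``."""
    if q.chrom != r.chrom:
        return MatchClass.NONE
    overlap = _exonic_overlap_bp(q, r)
    # strand "." is compared against both strands but can never be FULL
    strands_known = q.strand in "+-" and r.strand in "+-"
    same_strand = (not strands_known) or q.strand == r.strand
    if not same_strand:
        return MatchClass.ANTISENSE if overlap > 0 else MatchClass.NONE

    qc, rc = intron_chain(q).junctions, intron_chain(r).junctions
    if qc and rc and qc == rc and q.strand == r.strand and strands_known:
        return MatchClass.FULL
    if not qc and not rc and overlap > 0 and strands_known and q.strand == r.strand:
        # reciprocal: the overlap must cover the fraction of BOTH exons,
        # otherwise a short exon inside a long one would outrank containment
        longer = max(q.exonic_length(), r.exonic_length())
        if overlap >= single_exon_fraction * longer:
            return MatchClass.FULL
    if qc and rc and len(qc) < len(rc) and _is_subchain(qc, rc):
        return MatchClass.CONTAINED
    if not qc:
        qe = q.exons[0].interval
        for re_ in r.exons:
            if re_.interval.start <= qe.start and qe.end <= re_.interval.end:
                return MatchClass.CONTAINED
    shared = set(qc) & set(rc)
    if shared:
        return MatchClass.JUNCTION_OVERLAP
    if overlap > 0:
        return MatchClass.EXONIC_OVERLAP
    return MatchClass.NONE


@dataclass
class MatchReport:
    """Best query class per reference transcript, with gene-level rollup."""

    query_label: str
    reference_label: str
    per_transcript: dict[str, tuple[str | None, MatchClass]] = field(default_factory=dict)
    tx_gene: dict[str, str] = field(default_factory=dict)
    missing_gene_list: list[str] = field(default_factory=list)
    matched_gene_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def classes_for_gene(self, gene_id: str) -> list[MatchClass]:
        return [
            cls
            for tid, (_, cls) in self.per_transcript.items()
            if self.tx_gene[tid] == gene_id
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (tid, self.tx_gene[tid], qid or "", cls.value)
            for tid, (qid, cls) in sorted(self.per_transcript.items())
        ]
        return pd.DataFrame(
            rows, columns=["ref_transcript_id", "ref_gene_id", "query_transcript_id", "class_code"]
        )


def match_annotations(
    query: GenomeAnnotation,
    reference: GenomeAnnotation,
    single_exon_fraction: float = DEFAULT_SINGLE_EXON_FRACTION,
) -> MatchReport:
    """Classify every reference transcript against its best query match.

    Candidates are query transcripts whose exons overlap the reference
    transcript's span on either strand (found via the exon interval
    index).  Ties on class are broken by larger exonic overlap, then by
    smaller query transcript_id, so output is deterministic.
    """
    qidx = query.exon_index()
    report = MatchReport(query_label=query.label, reference_label=reference.label)

    for gene in reference.genes.values():
        for tx in gene.transcripts.values():
            span = tx.span
            cand: set[tuple[str, str]] = set()
            for strand in ("+", "-", "."):
                tree = qidx.get((tx.chrom, strand))
                if tree is not None:
                    for hit in tree.overlap(span.start, span.end + 1):
                        cand.add(hit.data)
            best: tuple[int, int, str] | None = None  # (priority, overlap, qtid)
            best_pair: tuple[str | None, MatchClass] = (None, MatchClass.NONE)
            for qgid, qtid in sorted(cand, key=lambda p: p[1]):
                qtx = query.genes[qgid].transcripts[qtid]
                cls = classify_pair(qtx, tx, single_exon_fraction)
                ov = _exonic_overlap_bp(qtx, tx)
                key = (_PRIORITY[cls], ov, qtid)
                if best is None or (key[0], key[1]) > (best[0], best[1]):
                    best = key
                    best_pair = (qtid, cls)
            report.per_transcript[tx.transcript_id] = best_pair
            report.tx_gene[tx.transcript_id] = gene.gene_id

    # gene-level rollup
    for gene in reference.genes.values():
        best_cls = MatchClass.NONE
        best_q: str | None = None
        for tx in gene.transcripts.values():
            qid, cls = report.per_transcript[tx.transcript_id]
            if _PRIORITY[cls] > _PRIORITY[best_cls]:
                best_cls, best_q = cls, qid
        if best_cls in RESCUING and best_q is not None:
            qgid = _owner_gene(query, best_q)
            note = "transcript_match" if best_cls is MatchClass.FULL else "coordinate_overlap"
            report.matched_gene_pairs[gene.gene_id] = (qgid, note)
    report.missing_gene_list = confirm_missing_genes(report, reference)
    return report


def _owner_gene(ann: GenomeAnnotation, transcript_id: str) -> str:
    for gene in ann.genes.values():
        if transcript_id in gene.transcripts:
            return gene.gene_id
    raise KeyError(transcript_id)


def confirm_missing_genes(
    report: MatchReport, reference: GenomeAnnotation
) -> list[str]:
    """Reference genes with no same-strand query overlap on any transcript."""
    missing = []
    for gene in reference.genes.values():
        classes = [
            report.per_transcript[tid][1]
            for tid in gene.transcripts
            if tid in report.per_transcript
        ]
        if classes and all(c in (MatchClass.ANTISENSE, MatchClass.NONE) for c in classes):
            missing.append(gene.gene_id)
    return sorted(missing)


def intersect_gene_sets(
    set_a: list[str],
    set_b: list[str],
    crosswalk_a: dict[str, str] | None = None,
    crosswalk_b: dict[str, str] | None = None,
) -> dict:
    """Intersect two gene-ID lists through a shared-ID crosswalk.

    Each annotation's IDs are mapped to a common namespace (e.g. NCBI
    gene IDs); unmapped IDs are excluded from the partition but counted.
    Duplicate crosswalk targets are reported as ambiguities.
    """
    def _map(ids: list[str], xw: dict[str, str] | None):
        if xw is None:
            return set(ids), 0, []
        mapped: dict[str, list[str]] = {}
        unmapped = 0
        for i in ids:
            tgt = xw.get(i)
            if tgt is None:
                unmapped += 1
            else:
                mapped.setdefault(tgt, []).append(i)
        dupes = sorted(t for t, srcs in mapped.items() if len(srcs) > 1)
        return set(mapped), unmapped, dupes

    ma, ua, da = _map(list(set_a), crosswalk_a)
    mb, ub, db = _map(list(set_b), crosswalk_b)
    return {
        "a_only": sorted(ma - mb),
        "b_only": sorted(mb - ma),
        "both": sorted(ma & mb),
        "unmapped_a": ua,
        "unmapped_b": ub,
        "ambiguous_a": da,
        "ambiguous_b": db,
    }
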