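"""Matched reference gene set and cross-annotation 3'UTR length comparison.

Two annotations of the same assembly rarely share gene identifiers, but a
gene's terminal 3'UTR exon starts at the same splice boundary in both: the
5' boundary of the 3'-most UTR-bearing exon (the exon start on the plus
strand, the exon end on the minus strand) is stable even when the
annotated UTR extends different distances downstream.  Matching on that
anchor links one representative transcript per gene across annotations
without relying on nomenclature.

Relative 3'UTR length is classified with a slack threshold: "longer"
means a difference of more than ``threshold`` nucleotides (default 50),
so trivial end-trimming differences count as "same".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import GeneModel, GenomeAnnotation, Interval, TranscriptModel, utr3_length

__all__ = [
    "TerminalUtrExon",
    "ReferenceGeneSetRow",
    "representative_transcript",
    "terminal_utr_exon",
    "collapse_terminal_exons",
    "build_reference_set",
    "classify_relative_length",
    "incorporate_annotation",
    "refset_to_frame",
]

SAME, LONGER_A, LONGER_B = "same", "longer_A", "longer_B"
LONGER_C, SHORTER_C = "longer_C", "shorter_C"


@dataclass(frozen=True)
class TerminalUtrExon:
    """The 3'-most exon of a transcript that contains 3'UTR sequence."""

    transcript_id: str
    gene_id: str
    interval: Interval
    utr3_len: int

    @property
    def anchor(self) -> int:
        """The 5' boundary of the terminal exon: the cross-annotation key."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.interval.chrom, self.interval.strand, self.anchor)


@dataclass
class ReferenceGeneSetRow:
    gene_key: str
    rep_transcript_A: str
    rep_transcript_B: str
    utr3_len_A: int
    utr3_len_B: int
    class_AB: str
    ambiguous_B: bool = False
    rep_transcript_C: str | None = None
    utr3_len_C: int | None = None
    class_C: str | None = None


def representative_transcript(g: GeneModel) -> TranscriptModel | None:
    """The single transcript representing a gene for UTR comparison.

    The transcript with the longest 3'UTR; ties broken by lexicographically
    smallest transcript_id.  ``None`` when no transcript has any annotated
    3'UTR (the gene is then excluded from the reference set).
    """
    best: TranscriptModel | None = None
    best_len = 0
    for tid in sorted(g.transcripts):
        ln = utr3_length(g.transcripts[tid])
        if ln > best_len:
            best, best_len = g.transcripts[tid], ln
    return best


def terminal_utr_exon(t: TranscriptModel) -> TerminalUtrExon | None:
    """Extract the transcript's terminal 3'UTR-containing exon, if any."""
    utr = t.segments_of("three_prime_utr")
    if not utr:
        return None
    candidates = [
        e
        for e in t.exons
        if any(e.interval.overlap_bp(u.interval) > 0 for u in utr)
    ]
    if not candidates:
        # UTR declared without a covering exon (degenerate dialect):
        # fall back to the 3'-most UTR segment itself
        candidates = utr
    ex = candidates[-1] if t.strand == "+" else candidates[0]
    return TerminalUtrExon(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        interval=ex.interval,
        utr3_len=utr3_length(t),
    )


def collapse_terminal_exons(exons: list[TerminalUtrExon]) -> list[TerminalUtrExon]:
    """Merge entries with identical coordinates into one.

    The surviving transcript_id is the lexicographically smallest among the
    duplicates — a deterministic rule standing in for an arbitrary pick.
    """
    by_coord: dict[Interval, TerminalUtrExon] = {}
    for e in exons:
        cur = by_coord.get(e.interval)
        if cur is None or e.transcript_id < cur.transcript_id:
            by_coord[e.interval] = e
    return sorted(
        by_coord.values(),
        key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end,
                       e.interval.strand, e.transcript_id),
    )


def classify_relative_length(len_a: int, len_b: int, threshold: int = 50) -> str:
    """Classify the relative 3'UTR length of two matched transcripts.

    "longer" means a length difference strictly greater than ``threshold``
    nucleotides; anything within +/- threshold is "same".
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    if len_a < 0 or len_b < 0:
        raise ValueError("UTR lengths must be non-negative")
    if len_a - len_b > threshold:
        return LONGER_A
    if len_b - len_a > threshold:
        return LONGER_B
    return SAME


def _terminal_exon_map(
    ann: GenomeAnnotation,
) -> tuple[dict[tuple[str, str, int], TerminalUtrExon], set[tuple[str, str, int]]]:
    """Anchor -> terminal-exon lookup over all UTR-bearing transcripts.

    Terminal exons are first collapsed on identical coordinates; when
    distinct entries still share an anchor (a many-to-one collision), the
    one with the longest 3'UTR wins and the anchor is flagged ambiguous.
    """
    exons = []
    for tx in ann.transcripts():
        te = terminal_utr_exon(tx)
        if te is not None:
            exons.append(te)
    collapsed = collapse_terminal_exons(exons)
    out: dict[tuple[str, str, int], TerminalUtrExon] = {}
    ambiguous: set[tuple[str, str, int]] = set()
    for e in collapsed:
        cur = out.get(e.key)
        if cur is None:
            out[e.key] = e
        else:
            ambiguous.add(e.key)
            if e.utr3_len > cur.utr3_len or (
                e.utr3_len == cur.utr3_len and e.transcript_id < cur.transcript_id
            ):
                out[e.key] = e
    return out, ambiguous


def build_reference_set(
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    threshold: int = 50,
) -> list[ReferenceGeneSetRow]:
    """Build the matched reference gene set of two annotations.

    ``ann_a`` drives the construction: each of its genes contributes its
    representative (longest-3'UTR) transcript, whose terminal-UTR-exon
    anchor is looked up among ``ann_b``'s collapsed terminal exons.  A
    match requires identical (chrom, strand, anchor); unmatched genes are
    excluded.  One row per matched gene, keyed by the ``ann_a`` gene_id.
    """
    b_map, b_ambiguous = _terminal_exon_map(ann_b)
    rows: list[ReferenceGeneSetRow] = []
    for gid in sorted(ann_a.genes):
        rep = representative_transcript(ann_a.genes[gid])
        if rep is None:
            continue
        te = terminal_utr_exon(rep)
        if te is None:
            continue
        hit = b_map.get(te.key)
        if hit is None:
            continue
        len_a, len_b = te.utr3_len, hit.utr3_len
        rows.append(
            ReferenceGeneSetRow(
                gene_key=gid,
                rep_transcript_A=rep.transcript_id,
                rep_transcript_B=hit.transcript_id,
                utr3_len_A=len_a,
                utr3_len_B=len_b,
                class_AB=classify_relative_length(len_a, len_b, threshold),
                ambiguous_B=te.key in b_ambiguous,
            )
        )
    return rows


def incorporate_annotation(
    refset: list[ReferenceGeneSetRow],
    ann_c: GenomeAnnotation,
    ann_a: GenomeAnnotation,
    threshold: int = 50,
) -> list[ReferenceGeneSetRow]:
    """Attach a third annotation to an existing reference set (in place).

    ``ann_c`` transcripts are matched by the same terminal-exon anchor as
    the driver gene's representative transcript.  The third-annotation
    class is judged against the better of the two original annotations:
    longer_C iff ``len_C - max(len_A, len_B) > threshold``, shorter_C for
    the symmetric case, else same.  Rows without a C match keep
    ``class_C = None``.
    """
    c_map, _ = _terminal_exon_map(ann_c)
    for row in refset:
        rep = ann_a.genes[row.gene_key].transcripts[row.rep_transcript_A]
        te = terminal_utr_exon(rep)
        hit = c_map.get(te.key) if te is not None else None
        if hit is None:
            continue
        row.rep_transcript_C = hit.transcript_id
        row.utr3_len_C = hit.utr3_len
        base = max(row.utr3_len_A, row.utr3_len_B)
        cls = classify_relative_length(hit.utr3_len, base, threshold)
        row.class_C = {LONGER_A: LONGER_C, LONGER_B: SHORTER_C, SAME: SAME}[cls]
    return refset


def refset_to_frame(refset: list[ReferenceGeneSetRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_key": [r.gene_key for r in refset],
            "rep_transcript_A": [r.rep_transcript_A for r in refset],
            "rep_transcript_B": [r.rep_transcript_B for r in refset],
            "utr3_len_A": [r.utr3_len_A for r in refset],
            "utr3_len_B": [r.utr3_len_B for r in refset],
            "class_AB": [r.class_AB for r in refset],
            "ambiguous_B": [r.ambiguous_B for r in refset],
            "rep_transcript_C": [r.rep_transcript_C for r in refset],
            "utr3_len_C": [r.utr3_len_C for r in refset],
            "class_C": [r.class_C for r in refset],
        }
    )
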