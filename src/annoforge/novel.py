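"""Triage of novel (XLOC) loci for retention in a curated annotation.

Assembly merging labels loci that match no known gene with arbitrary
``XLOC`` identifiers.  These are a mix of genuinely novel genes,
unannotated paralogs, lincRNAs, pseudogenes, and single-exon assembly
noise.  A locus is retained when any of three criteria holds:

1. protein homology — an exact, high- or moderate-confidence blastx-style
   hit against a zebrafish or human protein (``low`` does not count);
2. structural match or overlap with a previously published lincRNA model;
3. more than one exon in at least one of its transcripts.

Independently, a locus whose transcripts fully match or are contained in
reference-annotation transcripts on the same strand is *redundant* — it
re-describes a gene the annotation already has — and is removed
regardless of the criteria above.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .matching import DEFAULT_SINGLE_EXON_FRACTION, MatchClass, classify_pair
from .model import GenomeAnnotation

__all__ = ["EvidenceRow", "XlocDecision", "classify_xloc", "RETAIN", "DROP", "REDUNDANT"]

RETAIN, DROP, REDUNDANT = "retain", "drop", "redundant"

PASSING_CONFIDENCE = {"exact", "high", "moderate"}
LINCRNA_MATCH_CLASSES = {
    MatchClass.FULL,
    MatchClass.CONTAINED,
    MatchClass.JUNCTION_OVERLAP,
    MatchClass.EXONIC_OVERLAP,
}
REDUNDANT_CLASSES = {MatchClass.FULL, MatchClass.CONTAINED}


@dataclass(frozen=True)
class EvidenceRow:
    """Per-locus protein-homology evidence, consumed as given."""

    xloc_id: str
    protein_hit_confidence: str = "none"  # exact | high | moderate | low | none
    species_hit: str = "none"  # zebrafish | human | both | none


@dataclass(frozen=True)
class XlocDecision:
    xloc_id: str
    decision: str
    reason: str


def _best_class_against(
    ann: GenomeAnnotation, gene_id: str, other: GenomeAnnotation
) -> MatchClass:
    """Best structural class of any transcript of ``gene_id`` vs ``other``."""
    from .matching import _PRIORITY

    best = MatchClass.NONE
    oidx = other.exon_index()
    for tx in ann.genes[gene_id].transcripts.values():
        span = tx.span
        cand: set[tuple[str, str]] = set()
        for strand in ("+", "-", "."):
            tree = oidx.get((tx.chrom, strand))
            if tree is not None:
                for hit in tree.overlap(span.start, span.end + 1):
                    cand.add(hit.data)
        for ogid, otid in sorted(cand):
            otx = other.genes[ogid].transcripts[otid]
            # query = the XLOC transcript, reference = the known model
            cls = classify_pair(tx, otx, DEFAULT_SINGLE_EXON_FRACTION)
            if _PRIORITY[cls] > _PRIORITY[best]:
                best = cls
    return best


def classify_xloc(
    ann: GenomeAnnotation,
    evidence: list[EvidenceRow] | pd.DataFrame | None,
    lincrnas: GenomeAnnotation | None,
    refs: list[GenomeAnnotation],
    xloc_prefix: str = "XLOC",
) -> list[XlocDecision]:
    """Classify every XLOC gene as retain, drop, or redundant.

    The three decisions partition the XLOC genes.  Redundancy against the
    reference annotations is checked first; only non-redundant loci are
    then tested against the retention criteria.
    """
    ev_map: dict[str, EvidenceRow] = {}
    if evidence is not None:
        if isinstance(evidence, pd.DataFrame):
            evidence = [
                EvidenceRow(
                    xloc_id=r.xloc_id,
                    protein_hit_confidence=r.protein_hit_confidence,
                    species_hit=getattr(r, "species_hit", "none"),
                )
                for r in evidence.itertuples(index=False)
            ]
        for row in evidence:
            ev_map[row.xloc_id] = row

    xloc_ids = sorted(g for g in ann.genes if g.startswith(xloc_prefix))
    unknown_ev = sorted(set(ev_map) - set(xloc_ids))

    decisions: list[XlocDecision] = []
    for gid in xloc_ids:
        ref_best = MatchClass.NONE
        for ref in refs:
            cls = _best_class_against(ann, gid, ref)
            if cls in REDUNDANT_CLASSES:
                ref_best = cls
                break
        if ref_best in REDUNDANT_CLASSES:
            decisions.append(
                XlocDecision(gid, REDUNDANT, f"{ref_best.value} match to reference transcript")
            )
            continue

        ev = ev_map.get(gid)
        if ev is not None and ev.protein_hit_confidence in PASSING_CONFIDENCE:
            decisions.append(
                XlocDecision(gid, RETAIN, f"protein hit ({ev.protein_hit_confidence})")
            )
            continue
        if lincrnas is not None:
            linc_cls = _best_class_against(ann, gid, lincrnas)
            if linc_cls in LINCRNA_MATCH_CLASSES:
                decisions.append(
                    XlocDecision(gid, RETAIN, f"lincRNA structural match ({linc_cls.value})")
                )
                continue
        max_exons = max(
            len(t.exons) for t in ann.genes[gid].transcripts.values()
        )
        if max_exons > 1:
            decisions.append(XlocDecision(gid, RETAIN, f"multi-exon ({max_exons} exons)"))
            continue
        decisions.append(XlocDecision(gid, DROP, "single exon, no supporting evidence"))

    if unknown_ev:
        import warnings

        warnings.warn(
            f"evidence rows for unknown XLOC ids: {', '.join(unknown_ev[:5])}"
            + ("..." if len(unknown_ev) > 5 else ""),
            stacklevel=2,
        )
    return decisions
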