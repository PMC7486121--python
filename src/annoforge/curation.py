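"""Curation of a merged annotation: fusion removal, nomenclature,
missing-gene add-back, stable gene IDs and the gene-information table.

Assembly-derived merges (e.g. Cufflinks/Cuffmerge output combined with two
reference annotations) carry characteristic artifacts: *fusion
transcripts* whose exons bridge two adjacent same-strand genes, small
structural RNAs inherited from only one source annotation, conflicting
gene symbols, and genes present in one reference but absent from the
merge.  The operations here mechanise that cleanup and finish by assigning
every gene a stable arbitrary identifier (``LL1``, ``LL2``, ...) in
deterministic positional order, linking the GTF to a one-row-per-gene
information table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .matching import MatchReport
from .model import GeneModel, GenomeAnnotation

__all__ = [
    "FusionFlag",
    "GeneInfoRecord",
    "CurationLog",
    "detect_fusion_transcripts",
    "remove_transcripts",
    "remove_small_rna",
    "assign_nomenclature",
    "add_back_missing",
    "assign_ll_ids",
    "build_gene_info",
    "DEFAULT_FUSION_MIN_OVERLAP",
    "SMALL_RNA_BIOTYPES",
]

#: minimum exonic overlap with each bridged reference gene for a transcript
#: to be called a fusion
DEFAULT_FUSION_MIN_OVERLAP = 30

#: structural small-RNA biotypes removed by default; miRNA is never removed
SMALL_RNA_BIOTYPES = frozenset({"rRNA", "snRNA", "snoRNA", "sRNA", "miscRNA"})


@dataclass(frozen=True)
class FusionFlag:
    transcript_id: str
    gene_id: str
    overlapped_gene_ids: tuple[str, ...]
    overlap_bp: tuple[int, ...]


@dataclass
class GeneInfoRecord:
    ll_id: str
    gene_id: str
    ensembl_gene_id: str | None = None
    ncbi_id: str | None = None
    zfin_id: str | None = None
    symbol: str | None = None
    name: str | None = None
    match_note: str = "novel_xloc"


@dataclass
class CurationLog:
    """Per-run bookkeeping so the conservation equation is checkable:
    |curated| = |merged| - |removed| + |added back|."""

    removed_transcripts: list[str] = field(default_factory=list)
    removed_genes: list[str] = field(default_factory=list)
    added_genes: list[str] = field(default_factory=list)
    skipped_addbacks: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def detect_fusion_transcripts(
    merged: GenomeAnnotation,
    refs: list[GenomeAnnotation],
    min_overlap_bp: int = DEFAULT_FUSION_MIN_OVERLAP,
) -> list[FusionFlag]:
    """Flag transcripts whose exons bridge two or more reference genes.

    A transcript is a fusion candidate iff its exons overlap exons of at
    least two distinct reference genes on the same strand, each by at
    least ``min_overlap_bp``.  Reference genes that represent the same
    locus in different annotations (same symbol, or same gene_id) are
    counted once, so a transcript covering one gene annotated by both
    references is not a fusion.
    """
    flags: list[FusionFlag] = []
    indexes = [r.exon_index() for r in refs]
    for gene in merged.genes.values():
        for tx in gene.transcripts.values():
            overlaps: dict[str, int] = {}  # locus key -> summed overlap bp
            display: dict[str, str] = {}
            for ref, idx in zip(refs, indexes):
                tree = idx.get((tx.chrom, tx.strand))
                if tree is None:
                    continue
                for ex in tx.exons:
                    for hit in tree.overlap(ex.interval.start, ex.interval.end + 1):
                        rgid, rtid = hit.data
                        rgene = ref.genes[rgid]
                        key = rgene.symbol or rgid
                        ov = min(ex.interval.end, hit.end - 1) - max(ex.interval.start, hit.begin) + 1
                        if ov > 0:
                            overlaps[key] = overlaps.get(key, 0) + ov
                            display.setdefault(key, rgid)
            hit_keys = sorted(k for k, v in overlaps.items() if v >= min_overlap_bp)
            if len(hit_keys) >= 2:
                flags.append(
                    FusionFlag(
                        transcript_id=tx.transcript_id,
                        gene_id=gene.gene_id,
                        overlapped_gene_ids=tuple(display[k] for k in hit_keys),
                        overlap_bp=tuple(overlaps[k] for k in hit_keys),
                    )
                )
    flags.sort(key=lambda f: f.transcript_id)
    return flags


def remove_transcripts(
    ann: GenomeAnnotation, ids: list[str], log: CurationLog | None = None
) -> GenomeAnnotation:
    """Drop transcripts by ID; genes emptied by the removal are dropped too."""
    log = log if log is not None else CurationLog()
    wanted = set(ids)
    known = {t.transcript_id for t in ann.transcripts()}
    unknown = sorted(wanted - known)
    if unknown:
        raise KeyError(f"unknown transcript ids: {', '.join(unknown)}")
    out = ann.copy()
    for gid in list(out.genes):
        gene = out.genes[gid]
        for tid in list(gene.transcripts):
            if tid in wanted:
                del gene.transcripts[tid]
                log.removed_transcripts.append(tid)
        if not gene.transcripts:
            del out.genes[gid]
            log.removed_genes.append(gid)
    out.invalidate_index()
    return out


def remove_small_rna(
    ann: GenomeAnnotation,
    biotypes: frozenset[str] | set[str] = SMALL_RNA_BIOTYPES,
    log: CurationLog | None = None,
) -> GenomeAnnotation:
    """Remove structural small-RNA genes by biotype; miRNA is always kept."""
    log = log if log is not None else CurationLog()
    doomed = {b for b in biotypes if b != "miRNA"}
    out = ann.copy()
    any_biotype = any(g.biotype for g in out.genes.values())
    if not any_biotype:
        log.warnings.append("annotation carries no biotype labels; nothing removed")
        return out
    for gid in list(out.genes):
        g = out.genes[gid]
        if g.biotype in doomed and g.biotype != "miRNA":
            del out.genes[gid]
            log.removed_genes.append(gid)
    out.invalidate_index()
    return out


@dataclass
class SymbolConflict:
    kind: str  # "multi_reference" | "multi_locus"
    detail: str


def assign_nomenclature(
    merged: GenomeAnnotation,
    ens: GenomeAnnotation,
    refseq: GenomeAnnotation,
    report_ens: MatchReport,
    report_refseq: MatchReport,
) -> tuple[GenomeAnnotation, list[SymbolConflict]]:
    """Assign gene symbols/names to a merged annotation by match priority.

    Priority: symbol of the matched Ensembl gene, else of the matched
    RefSeq gene, else the gene keeps (or is given) an ``XLOC_`` style
    identifier as its symbol.  ``report_ens``/``report_refseq`` must come
    from ``match_annotations(query=merged, reference=...)`` so that
    matched_gene_pairs maps reference gene -> merged gene.

    Conflicts are recorded, not auto-resolved: (a) one merged gene matched
    to reference genes carrying different symbols, (b) one symbol landing
    on more than one merged locus.
    """
    out = merged.copy()
    conflicts: list[SymbolConflict] = []
    # invert: merged gene -> list of (priority, ref symbol, ref name, ref gid)
    cand: dict[str, list[tuple[int, str, str | None, str]]] = {}
    for prio, (ref, rep) in enumerate([(ens, report_ens), (refseq, report_refseq)]):
        for ref_gid, (merged_gid, _note) in rep.matched_gene_pairs.items():
            rg = ref.genes[ref_gid]
            if rg.symbol:
                cand.setdefault(merged_gid, []).append((prio, rg.symbol, rg.name, ref_gid))

    symbol_owners: dict[str, list[str]] = {}
    for gid in sorted(out.genes):
        options = sorted(cand.get(gid, []))
        if not options:
            if out.genes[gid].symbol is None:
                out.genes[gid].symbol = gid
            symbol_owners.setdefault(out.genes[gid].symbol, []).append(gid)
            continue
        symbols = {s for _, s, _, _ in options}
        if len(symbols) > 1:
            conflicts.append(
                SymbolConflict(
                    kind="multi_reference",
                    detail=f"{gid} matches references with symbols {sorted(symbols)}",
                )
            )
        prio, symbol, name, _ref = options[0]
        out.genes[gid].symbol = symbol
        if name:
            out.genes[gid].name = name
        symbol_owners.setdefault(symbol, []).append(gid)

    for symbol, owners in sorted(symbol_owners.items()):
        if len(owners) > 1:
            conflicts.append(
                SymbolConflict(
                    kind="multi_locus",
                    detail=f"symbol {symbol} assigned to loci {owners}",
                )
            )
    return out, conflicts


def _exonic_span_on(gene: GeneModel, chrom: str) -> int:
    return sum(
        t.exonic_length() for t in gene.transcripts.values() if t.chrom == chrom
    )


def _has_utr_on(gene: GeneModel, chrom: str) -> bool:
    return any(
        t.has("three_prime_utr")
        for t in gene.transcripts.values()
        if t.chrom == chrom
    )


def add_back_missing(
    curated: GenomeAnnotation,
    missing_by_ref: dict[str, list[str]],
    refs: dict[str, GenomeAnnotation],
    log: CurationLog | None = None,
) -> GenomeAnnotation:
    """Copy confirmed-missing reference genes into the curated annotation.

    Transcript models are copied verbatim (no exon re-fitting) and the
    gene is tagged ``added_back_<ref label>``.  For genes split across
    chromosomes only the piece with the larger total exonic span is added;
    the piece carrying a 3'UTR wins ties.  A gene whose exons collide with
    an existing curated gene on the same strand is skipped (adding it
    would re-create the fusion situation the earlier pass removed).
    """
    log = log if log is not None else CurationLog()
    out = curated.copy()
    for ref_label in sorted(missing_by_ref):
        ref = refs[ref_label]
        for gid in sorted(missing_by_ref[ref_label]):
            gene = ref.genes[gid]
            keep_chrom = None
            if gene.is_split:
                keep_chrom = max(
                    gene.chroms,
                    key=lambda c: (_exonic_span_on(gene, c), _has_utr_on(gene, c), c),
                )
                # 3'UTR breaks exact exonic-span ties
                best_span = _exonic_span_on(gene, keep_chrom)
                tied = [c for c in gene.chroms if _exonic_span_on(gene, c) == best_span]
                if len(tied) > 1:
                    with_utr = [c for c in tied if _has_utr_on(gene, c)]
                    keep_chrom = min(with_utr) if with_utr else min(tied)

            new_gid = f"{gid}"
            if new_gid in out.genes:
                log.skipped_addbacks.append((gid, "gene_id already present"))
                continue
            txs = {
                tid: t
                for tid, t in gene.transcripts.items()
                if keep_chrom is None or t.chrom == keep_chrom
            }
            if _collides(out, txs):
                log.skipped_addbacks.append((gid, "coordinate collision on same strand"))
                continue
            new_gene = GeneModel(
                gene_id=new_gid,
                transcripts={tid: _copy_tx(t) for tid, t in txs.items()},
                symbol=gene.symbol,
                name=gene.name,
                biotype=gene.biotype,
                match_note=f"added_back_{ref_label}",
            )
            out.add_gene(new_gene)
            log.added_genes.append(new_gid)
    out.invalidate_index()
    return out


def _copy_tx(t):
    from .model import TranscriptModel

    return TranscriptModel(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        chrom=t.chrom,
        strand=t.strand,
        segments=list(t.segments),
    )


def _collides(ann: GenomeAnnotation, txs) -> bool:
    idx = ann.exon_index()
    for t in txs.values():
        tree = idx.get((t.chrom, t.strand))
        if tree is None:
            continue
        for ex in t.exons:
            if tree.overlap(ex.interval.start, ex.interval.end + 1):
                return True
    return False


def assign_ll_ids(ann: GenomeAnnotation) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Assign stable arbitrary gene IDs LL1, LL2, ... in positional order.

    Sort key is (chrom, gene start, gene_id), so the numbering is
    deterministic across runs and re-runs on identical input produce an
    identical table.  The ll_id is also written into every GTF line's
    attributes via the segment attribute map.
    """
    out = ann.copy()
    order = sorted(
        out.genes.values(),
        key=lambda g: (g.chrom, g.span_on(g.chrom).start, g.gene_id),
    )
    rows = []
    for i, gene in enumerate(order, start=1):
        ll = f"LL{i}"
        gene.ll_id = ll
        for tx in gene.transcripts.values():
            tx.segments = [
                _with_attr(seg, "ll_id", ll) for seg in tx.segments
            ]
        span = gene.span_on(gene.chrom)
        rows.append((ll, gene.gene_id, gene.symbol or "", gene.chrom, span.start, span.end))
    table = pd.DataFrame(
        rows, columns=["ll_id", "gene_id", "symbol", "chrom", "start", "end"]
    )
    return out, table


def _with_attr(seg, key, value):
    from dataclasses import replace

    attrs = tuple(kv for kv in seg.attrs if kv[0] != key) + ((key, value),)
    return replace(seg, attrs=attrs)


def build_gene_info(
    ann: GenomeAnnotation,
    crosswalks: dict[str, dict[str, str]] | None = None,
    report_ens: MatchReport | None = None,
    report_refseq: MatchReport | None = None,
) -> pd.DataFrame:
    """One information record per curated gene (requires LL IDs assigned).

    ``crosswalks`` maps namespace -> {curated or reference gene_id ->
    external ID} for "ensembl", "ncbi", "zfin".  The match note records
    how confidently each external link was made: a full intron-chain
    match, a coordinate overlap, an add-back provenance tag, or novel
    XLOC status.
    """
    crosswalks = crosswalks or {}
    # invert match reports: merged gene -> (ref gene, note)
    links: dict[str, dict[str, tuple[str, str]]] = {"ensembl": {}, "refseq": {}}
    for ns, rep in (("ensembl", report_ens), ("refseq", report_refseq)):
        if rep is None:
            continue
        for ref_gid, (merged_gid, note) in rep.matched_gene_pairs.items():
            prev = links[ns].get(merged_gid)
            if prev is None or (note == "transcript_match" and prev[1] != "transcript_match"):
                links[ns][merged_gid] = (ref_gid, note)

    rows = []
    for gene in ann.genes.values():
        ll = getattr(gene, "ll_id", None)
        if ll is None:
            raise ValueError("assign_ll_ids must run before build_gene_info")
        ens_link = links["ensembl"].get(gene.gene_id)
        ref_link = links["refseq"].get(gene.gene_id)
        note = getattr(gene, "match_note", None)
        if note is None:
            if ens_link and ens_link[1] == "transcript_match":
                note = "full_transcript_match"
            elif ref_link and ref_link[1] == "transcript_match":
                note = "full_transcript_match"
            elif ens_link or ref_link:
                note = "gene_coordinate_overlap"
            elif gene.gene_id.startswith("XLOC"):
                note = "novel_xloc"
            else:
                note = "unlinked"
        ens_id = ens_link[0] if ens_link else None
        ncbi = None
        zfin = None
        for key in (gene.gene_id, ref_link[0] if ref_link else None, ens_id):
            if key is None:
                continue
            ncbi = ncbi or crosswalks.get("ncbi", {}).get(key)
            zfin = zfin or crosswalks.get("zfin", {}).get(key)
            ens_id = ens_id or crosswalks.get("ensembl", {}).get(key)
        rows.append(
            (
                ll,
                gene.gene_id,
                ens_id or "",
                ncbi or "",
                zfin or "",
                gene.symbol or "",
                gene.name or "",
                note,
            )
        )
    rows.sort(key=lambda r: int(r[0][2:]))
    return pd.DataFrame(
        rows,
        columns=[
            "ll_id",
            "gene_id",
            "ensembl_gene_id",
            "ncbi_id",
            "zfin_id",
            "symbol",
            "name",
            "match_note",
        ],
    )
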