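"""Synthetic paired annotations with planted, manifest-recorded discrepancies.

The generator emulates the discrepancy classes found when comparing two
independently produced annotations of one genome assembly, plus the
artifacts of an assembly-derived merge of the two:

* coding genes lacking 3'UTR or stop-codon features in one annotation;
* genes whose 3'UTR is longer in one annotation (deltas drawn log-uniform
  in [60, 5000] nt, i.e. strictly above the 50 nt "same" threshold) and
  within-threshold controls (deltas 1..50 nt);
* genes entirely absent from one annotation, a subset of them partially
  overlapped by an unrelated transcript in the other (rescuing them from
  the confirmed-missing list);
* fusion transcripts bridging two adjacent same-strand genes in the merge;
* duplicated gene symbols;
* structural small-RNA genes (present in only one annotation) and miRNAs;
* novel XLOC loci of every triage class, with matching evidence tables and
  a companion lincRNA annotation;
* genes split across chromosomes and genes dropped by the merge (add-back
  material).

Every planted item is recorded in a :class:`FixtureManifest` whose
predictions are derived from the planting bookkeeping alone — never by
running the analysis modules — so the manifest is an independent oracle
for the whole toolkit.  Identical seeds yield identical annotations.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .model import FeatureSegment, GeneModel, GenomeAnnotation, Interval, TranscriptModel
from .novel import EvidenceRow

__all__ = ["FixtureConfig", "FixtureManifest", "FixtureSet", "generate"]


class FixtureConfigError(ValueError):
    pass


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic annotation pair.

    Default proportions mirror the completeness gap between a large
    Ensembl-style annotation (A: ~18% of coding genes without any 3'UTR,
    ~6% without a stop codon, small structural RNAs included) and a
    RefSeq-style one (B: ~6% and ~1%, no small RNAs), at desk scale.
    """

    n_genes: int = 100
    seed: int = 0
    chrom_sizes: dict[str, int] | None = None  # None -> four 60 Mb chromosomes
    alt_chrom: str = "chr1_alt"
    n_alt_genes: int = 0

    frac_missing_utr3_A: float = 0.18
    frac_missing_utr3_B: float = 0.06
    frac_missing_stop_A: float = 0.06
    frac_missing_stop_B: float = 0.01

    n_utr_longer_A: int = 10
    n_utr_longer_B: int = 6
    n_utr_longer_merged: int = 5
    n_same_controls: int = 5
    utr_delta_range: tuple[int, int] = (60, 5000)  # log-uniform, > threshold
    threshold: int = 50

    n_missing_from_A: int = 8  # genes present only in B
    n_rescued_A: int = 2  # subset of the above overlapped by a decoy in A
    n_missing_from_B: int = 8  # genes present only in A
    n_absent_from_merged: int = 4  # B genes the merge dropped
    n_split_genes: int = 1  # B genes split across two chromosomes

    n_fusion_transcripts: int = 4
    n_duplicate_symbols: int = 2
    n_small_rna: dict[str, int] = field(
        default_factory=lambda: {"rRNA": 6, "snRNA": 3, "snoRNA": 2, "sRNA": 1, "miscRNA": 1}
    )
    n_mirna: int = 3
    n_xloc: dict[str, int] = field(
        default_factory=lambda: {
            "single_exon_no_evidence": 4,
            "multi_exon": 4,
            "evidence_backed": 3,
            "lincRNA_matched": 2,
            "redundant": 2,
        }
    )

    def validate(self) -> None:
        for name in ("frac_missing_utr3_A", "frac_missing_utr3_B",
                     "frac_missing_stop_A", "frac_missing_stop_B"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureConfigError(f"{name}={v} not in [0, 1]")
        n_roles = (
            round(self.frac_missing_utr3_A * self.n_genes)
            + round(self.frac_missing_utr3_B * self.n_genes)
            + self.n_utr_longer_A
            + self.n_utr_longer_B
            + self.n_utr_longer_merged
            + self.n_same_controls
            + round(self.frac_missing_stop_A * self.n_genes)
            + round(self.frac_missing_stop_B * self.n_genes)
            + 2 * self.n_duplicate_symbols
        )
        if n_roles > self.n_genes:
            raise FixtureConfigError(
                f"planted roles ({n_roles}) exceed n_genes ({self.n_genes})"
            )
        if self.n_rescued_A > self.n_missing_from_A:
            raise FixtureConfigError("n_rescued_A exceeds n_missing_from_A")
        if self.n_alt_genes > self.n_genes:
            raise FixtureConfigError("n_alt_genes exceeds n_genes")
        if self.n_split_genes and self._chroms() and len(self._chroms()) < 2:
            raise FixtureConfigError("split genes need at least two chromosomes")

    def _chroms(self) -> dict[str, int]:
        if self.chrom_sizes is not None:
            return dict(self.chrom_sizes)
        return {f"chr{i}": 60_000_000 for i in range(1, 5)}


@dataclass
class FixtureManifest:
    """Planted ground truth plus the exact outputs every module must produce."""

    config: dict
    categories: dict[str, list[str]] = field(default_factory=dict)
    audit_expected: dict[str, dict[str, int]] = field(default_factory=dict)
    refset_expected: dict = field(default_factory=dict)
    missing_expected: dict[str, list[str]] = field(default_factory=dict)
    fusion_transcripts: list[str] = field(default_factory=list)
    xloc_expected: dict[str, str] = field(default_factory=dict)
    split_gene_kept_chrom: dict[str, str] = field(default_factory=dict)
    duplicate_symbols: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class FixtureSet:
    ann_a: GenomeAnnotation
    ann_b: GenomeAnnotation
    merged: GenomeAnnotation
    lincrnas: GenomeAnnotation
    evidence: list[EvidenceRow]
    manifest: FixtureManifest


# ---------------------------------------------------------------------------
# coordinate construction helpers
# ---------------------------------------------------------------------------

class _Layout:
    """Sequential allocator over an ordered chromosome table."""

    def __init__(self, chrom_sizes: dict[str, int], gap: tuple[int, int], rng: random.Random):
        self.table = list(chrom_sizes.items())
        self.idx = 0
        self.cursor = 1
        self.gap = gap
        self.rng = rng

    @property
    def chrom(self) -> str:
        return self.table[self.idx][0]

    def alloc(self, width: int, chrom: str | None = None) -> tuple[str, int]:
        if chrom is not None:
            # dedicated contig (e.g. alt scaffold): track a side cursor
            if not hasattr(self, "_side"):
                self._side: dict[str, int] = {}
            start = self._side.get(chrom, 1)
            self._side[chrom] = start + width + self.rng.randint(*self.gap)
            return chrom, start
        while self.cursor + width > self.table[self.idx][1]:
            self.idx += 1
            self.cursor = 1
            if self.idx >= len(self.table):
                raise FixtureConfigError(
                    "chromosomes too small for the requested number of genes"
                )
        start = self.cursor
        self.cursor = start + width + self.rng.randint(*self.gap)
        return self.table[self.idx][0], start

    def next_chrom_of(self, chrom: str) -> str:
        names = [c for c, _ in self.table]
        return names[(names.index(chrom) + 1) % len(names)]


@dataclass
class _GeneSpec:
    """Strand-aware blueprint from which A/B/merged variants are stamped."""

    chrom: str
    start: int
    strand: str
    exon_lens: list[int]
    intron_lens: list[int]
    u5: int
    utr3: int
    coding: bool = True

    def width(self, ext: int = 0) -> int:
        return sum(self.exon_lens) + sum(self.intron_lens) + ext


def _draw_spec(rng: random.Random, coding: bool = True, min_exons: int = 1,
               max_exons: int = 10, min_last_exon_pad: int = 20,
               long_terminal: bool = False, strand: str | None = None) -> _GeneSpec:
    k = rng.randint(min_exons, max_exons)
    utr3 = rng.randint(100, 1200) if coding else 0
    u5 = rng.randint(0, 80) if coding else 0
    exon_lens = [rng.randint(50, 2000) for _ in range(k)]
    intron_lens = [rng.randint(60, 2000) for _ in range(k - 1)]
    strand = strand or rng.choice("+-")
    if coding:
        pad = rng.randint(min_last_exon_pad, 500)
        terminal = utr3 + 3 + pad
        if long_terminal:
            terminal = max(terminal, 1200)
        first_min = u5 + 20 if k > 1 else u5 + 20 + 3 + utr3
        if strand == "+":
            exon_lens[-1] = terminal if k > 1 else max(first_min, terminal + u5 + 20)
            exon_lens[0] = max(exon_lens[0], first_min) if k > 1 else exon_lens[-1]
        else:
            exon_lens[0] = terminal if k > 1 else max(first_min, terminal + u5 + 20)
            exon_lens[-1] = max(exon_lens[-1], first_min) if k > 1 else exon_lens[0]
    return _GeneSpec("", 0, strand, exon_lens, intron_lens, u5, utr3, coding)


def _stamp_transcript(
    spec: _GeneSpec,
    tx_id: str,
    gene_id: str,
    missing_utr: bool = False,
    missing_stop: bool = False,
    ext: int = 0,
) -> TranscriptModel:
    """Materialise a transcript from a spec at its laid-out position.

    ``ext`` lengthens the annotated 3'UTR (and the terminal exon) by that
    many nucleotides on the transcript's 3' side; on the minus strand the
    terminal exon is the genomically first one, so the extension grows
    leftwards into space the layout reserved.
    """
    chrom, strand = spec.chrom, spec.strand
    exon_iv: list[tuple[int, int]] = []
    pos = spec.start
    for i, ln in enumerate(spec.exon_lens):
        exon_iv.append((pos, pos + ln - 1))
        pos += ln
        if i < len(spec.intron_lens):
            pos += spec.intron_lens[i]
    if ext:
        if strand == "+":
            s, e = exon_iv[-1]
            exon_iv[-1] = (s, e + ext)
        else:
            s, e = exon_iv[0]
            exon_iv[0] = (s - ext, e)

    segs: list[FeatureSegment] = [
        FeatureSegment(Interval(chrom, s, e, strand), "exon") for s, e in exon_iv
    ]
    if spec.coding:
        utr3 = spec.utr3 + ext
        u5 = spec.u5
        if strand == "+":
            first, last = exon_iv[0], exon_iv[-1]
            if u5:
                segs.append(FeatureSegment(
                    Interval(chrom, first[0], first[0] + u5 - 1, strand), "five_prime_utr"))
            cds_end = last[1] - utr3 - 3
            segs.append(FeatureSegment(
                Interval(chrom, first[0] + u5, exon_iv[0][1] if len(exon_iv) > 1 else cds_end,
                         strand), "CDS"))
            for s, e in exon_iv[1:-1]:
                segs.append(FeatureSegment(Interval(chrom, s, e, strand), "CDS"))
            if len(exon_iv) > 1:
                segs.append(FeatureSegment(
                    Interval(chrom, last[0], cds_end, strand), "CDS"))
            if not missing_stop:
                segs.append(FeatureSegment(
                    Interval(chrom, cds_end + 1, cds_end + 3, strand), "stop_codon"))
            if not missing_utr and utr3 > 0:
                segs.append(FeatureSegment(
                    Interval(chrom, last[1] - utr3 + 1, last[1], strand), "three_prime_utr"))
        else:
            # minus strand: genomic mirror — 3' features at low coordinates
            first, last = exon_iv[0], exon_iv[-1]
            if u5:
                segs.append(FeatureSegment(
                    Interval(chrom, last[1] - u5 + 1, last[1], strand), "five_prime_utr"))
            cds_start = first[0] + utr3 + 3
            if len(exon_iv) > 1:
                segs.append(FeatureSegment(
                    Interval(chrom, cds_start, first[1], strand), "CDS"))
                for s, e in exon_iv[1:-1]:
                    segs.append(FeatureSegment(Interval(chrom, s, e, strand), "CDS"))
                segs.append(FeatureSegment(
                    Interval(chrom, last[0], last[1] - u5, strand), "CDS"))
            else:
                segs.append(FeatureSegment(
                    Interval(chrom, cds_start, last[1] - u5, strand), "CDS"))
            if not missing_stop:
                segs.append(FeatureSegment(
                    Interval(chrom, cds_start - 3, cds_start - 1, strand), "stop_codon"))
            if not missing_utr and utr3 > 0:
                segs.append(FeatureSegment(
                    Interval(chrom, first[0], first[0] + utr3 - 1, strand), "three_prime_utr"))
    return TranscriptModel(tx_id, gene_id, chrom, strand, segs)


def _make_gene(gene_id, tx, symbol=None, biotype="protein_coding", name=None):
    return GeneModel(
        gene_id=gene_id,
        transcripts={tx.transcript_id: tx},
        symbol=symbol,
        biotype=biotype,
        name=name,
    )


def _log_uniform(rng: random.Random, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate(config: FixtureConfig) -> FixtureSet:
    """Generate the paired annotations, merge, lincRNAs, evidence and manifest."""
    config.validate()
    rng = random.Random(config.seed)
    layout = _Layout(config._chroms(), gap=(500, 2000), rng=rng)

    A = GenomeAnnotation("A")
    B = GenomeAnnotation("B")
    M = GenomeAnnotation("merged")
    L = GenomeAnnotation("lincRNA")
    evidence: list[EvidenceRow] = []
    man = FixtureManifest(config=_config_dict(config))
    cat = man.categories

    n = config.n_genes
    n_mu_a = round(config.frac_missing_utr3_A * n)
    n_mu_b = round(config.frac_missing_utr3_B * n)
    n_ms_a = round(config.frac_missing_stop_A * n)
    n_ms_b = round(config.frac_missing_stop_B * n)

    # role assignment over the n matched base genes (disjoint slices of a
    # seeded shuffle, so every prediction is pure bookkeeping)
    order = list(range(n))
    rng.shuffle(order)
    roles: dict[int, str] = {}
    cursor = 0

    def take(count: int, role: str) -> list[int]:
        nonlocal cursor
        chosen = order[cursor : cursor + count]
        cursor += count
        for i in chosen:
            roles[i] = role
        return chosen

    idx_mu_a = take(n_mu_a, "missing_utr3_A")
    idx_mu_b = take(n_mu_b, "missing_utr3_B")
    idx_la = take(config.n_utr_longer_A, "longer_A")
    idx_lb = take(config.n_utr_longer_B, "longer_B")
    idx_lm = take(config.n_utr_longer_merged, "longer_merged")
    idx_ctrl = take(config.n_same_controls, "same_control")
    idx_ms_a = take(n_ms_a, "missing_stop_A")
    idx_ms_b = take(n_ms_b, "missing_stop_B")
    dup_pairs = [
        (order[cursor + 2 * i], order[cursor + 2 * i + 1])
        for i in range(config.n_duplicate_symbols)
    ]
    take(2 * config.n_duplicate_symbols, "duplicate_symbol")

    alt_set = set(range(n - config.n_alt_genes, n))  # by gene index, not shuffle

    dup_symbol_of = {b: a for a, b in dup_pairs}

    # ---- matched base genes ------------------------------------------------
    for i in range(n):
        role = roles.get(i, "plain")
        force_multi = role == "longer_merged"
        spec = _draw_spec(rng, min_exons=2 if force_multi else 1)
        ext_a = ext_b = ext_m = 0
        if role == "longer_A":
            ext_a = _log_uniform(rng, *config.utr_delta_range)
        elif role == "longer_B":
            ext_b = _log_uniform(rng, *config.utr_delta_range)
        elif role == "longer_merged":
            ext_m = _log_uniform(rng, *config.utr_delta_range)
        elif role == "same_control":
            ext_a = rng.randint(1, config.threshold)
        reserve = max(ext_a, ext_b, ext_m)
        chrom_override = config.alt_chrom if i in alt_set else None
        spec.chrom, spec.start = layout.alloc(spec.width(reserve), chrom=chrom_override)
        if spec.strand == "-":
            spec.start += reserve  # extension grows leftwards into the reserve
        gid_a, gid_b, gid_m = f"GA{i:05d}", f"GB{i:05d}", f"MG{i:05d}"
        symbol = f"gene{dup_symbol_of[i] if i in dup_symbol_of else i}"
        tx_a = _stamp_transcript(spec, f"TA{i:05d}", gid_a,
                                 missing_utr=role == "missing_utr3_A",
                                 missing_stop=role == "missing_stop_A", ext=ext_a)
        tx_b = _stamp_transcript(spec, f"TB{i:05d}", gid_b,
                                 missing_utr=role == "missing_utr3_B",
                                 missing_stop=role == "missing_stop_B", ext=ext_b)
        A.add_gene(_make_gene(gid_a, tx_a, symbol=symbol))
        B.add_gene(_make_gene(gid_b, tx_b, symbol=symbol))
        # merged locus: union of both models (A copy may carry the merge-only
        # UTR extension)
        tx_ma = _stamp_transcript(spec, f"TA{i:05d}", gid_m,
                                  missing_utr=role == "missing_utr3_A",
                                  missing_stop=role == "missing_stop_A",
                                  ext=ext_a or ext_m)
        tx_mb = _stamp_transcript(spec, f"TB{i:05d}", gid_m,
                                  missing_utr=role == "missing_utr3_B",
                                  missing_stop=role == "missing_stop_B", ext=ext_b)
        gene_m = GeneModel(gene_id=gid_m,
                           transcripts={t.transcript_id: t for t in (tx_ma, tx_mb)},
                           biotype="protein_coding")
        M.add_gene(gene_m)
        cat.setdefault(role, []).append(gid_a)
    cat["alt_contig"] = [f"GA{i:05d}" for i in sorted(alt_set)]
    man.duplicate_symbols = [f"gene{a}" for a, _ in dup_pairs]

    # ---- redundant-XLOC host genes (long terminal exon in both refs) ------
    host_ids = []
    xloc_expected = man.xloc_expected
    xn = dict(config.n_xloc)
    for j in range(xn.get("redundant", 0)):
        spec = _draw_spec(rng, min_exons=1, max_exons=4, long_terminal=True)
        spec.chrom, spec.start = layout.alloc(spec.width())
        gid_a, gid_b, gid_m = f"GAH{j:04d}", f"GBH{j:04d}", f"MGH{j:04d}"
        symbol = f"hostgene{j}"
        tx_a = _stamp_transcript(spec, f"TAH{j:04d}", gid_a)
        tx_b = _stamp_transcript(spec, f"TBH{j:04d}", gid_b)
        A.add_gene(_make_gene(gid_a, tx_a, symbol=symbol))
        B.add_gene(_make_gene(gid_b, tx_b, symbol=symbol))
        tx_ma = _stamp_transcript(spec, f"TAH{j:04d}", gid_m)
        tx_mb = _stamp_transcript(spec, f"TBH{j:04d}", gid_m)
        M.add_gene(GeneModel(gene_id=gid_m,
                             transcripts={t.transcript_id: t for t in (tx_ma, tx_mb)},
                             biotype="protein_coding"))
        host_ids.append(gid_a)
        # the redundant XLOC: a short exon inside the host's terminal exon
        term = tx_a.exons[-1] if spec.strand == "+" else tx_a.exons[0]
        xlen = min(200, term.length // 3)
        xs = term.interval.start + (term.length - xlen) // 2
        xid = f"XLOC_R{j:06d}"
        xtx = TranscriptModel(f"TX_R{j:06d}", xid, spec.chrom, spec.strand,
                              [FeatureSegment(Interval(spec.chrom, xs, xs + xlen - 1,
                                                       spec.strand), "exon")])
        M.add_gene(_make_gene(xid, xtx, symbol=xid, biotype=None))
        xloc_expected[xid] = "redundant"
    cat["xloc_host"] = host_ids

    # ---- fusion units: two adjacent same-strand genes + bridging transcript
    fusion_gene_ids = []
    for j in range(config.n_fusion_transcripts):
        strand = rng.choice("+-")
        s1 = _draw_spec(rng, min_exons=1, max_exons=5, strand=strand)
        s2 = _draw_spec(rng, min_exons=1, max_exons=5, strand=strand)
        gap = rng.randint(200, 400)
        chrom, start = layout.alloc(s1.width() + gap + s2.width())
        s1.chrom, s1.start = chrom, start
        s2.chrom, s2.start = chrom, start + s1.width() + gap
        ids = []
        for k, spec in enumerate((s1, s2)):
            gid_a, gid_b, gid_m = (f"GAF{j:03d}_{k}", f"GBF{j:03d}_{k}", f"MGF{j:03d}_{k}")
            symbol = f"fusgene{j}_{k}"
            tx_a = _stamp_transcript(spec, f"TAF{j:03d}_{k}", gid_a)
            tx_b = _stamp_transcript(spec, f"TBF{j:03d}_{k}", gid_b)
            A.add_gene(_make_gene(gid_a, tx_a, symbol=symbol))
            B.add_gene(_make_gene(gid_b, tx_b, symbol=symbol))
            M.add_gene(GeneModel(
                gene_id=gid_m,
                transcripts={
                    f"TAF{j:03d}_{k}": _stamp_transcript(spec, f"TAF{j:03d}_{k}", gid_m),
                    f"TBF{j:03d}_{k}": _stamp_transcript(spec, f"TBF{j:03d}_{k}", gid_m),
                },
                biotype="protein_coding"))
            ids.append(gid_a)
        # bridging transcript: genomically-last exon of gene 1 + first of gene 2
        e1 = _stamp_transcript(s1, "tmp", "tmp").exons[-1].interval
        e2 = _stamp_transcript(s2, "tmp", "tmp").exons[0].interval
        fid, ftx_id = f"FUSG{j:04d}", f"TFUS{j:04d}"
        ftx = TranscriptModel(ftx_id, fid, chrom, strand, [
            FeatureSegment(Interval(chrom, e1.start, e1.end, strand), "exon"),
            FeatureSegment(Interval(chrom, e2.start, e2.end, strand), "exon"),
        ])
        M.add_gene(_make_gene(fid, ftx, symbol=None, biotype=None))
        man.fusion_transcripts.append(ftx_id)
        fusion_gene_ids.extend(ids)
    cat["fusion_flank"] = fusion_gene_ids

    # ---- genes present only in B (missing from A); some rescued by decoys -
    missing_a_confirmed, rescued = [], []
    for j in range(config.n_missing_from_A):
        spec = _draw_spec(rng)
        spec.chrom, spec.start = layout.alloc(spec.width() + 200)
        spec.start += 150  # leading pad for a decoy to stick out into
        gid_b, gid_m = f"GBM{j:04d}", f"MGmA{j:04d}"
        tx_b = _stamp_transcript(spec, f"TBM{j:04d}", gid_b)
        B.add_gene(_make_gene(gid_b, tx_b, symbol=f"bonly{j}"))
        M.add_gene(_make_gene(gid_m, _stamp_transcript(spec, f"TBM{j:04d}", gid_m),
                              biotype="protein_coding"))
        if j < config.n_rescued_A:
            # decoy in A: 10 bp same-strand overlap with the gene's leftmost exon
            first_ex = tx_b.exons[0].interval
            dgid = f"DEC{j:04d}"
            dtx = TranscriptModel(f"TDEC{j:04d}", dgid, spec.chrom, spec.strand, [
                FeatureSegment(Interval(spec.chrom, first_ex.start - 90,
                                        first_ex.start + 9, spec.strand), "exon")])
            A.add_gene(_make_gene(dgid, dtx, symbol=f"decoy{j}", biotype=None))
            M.add_gene(_make_gene(f"MGdec{j:04d}",
                                  TranscriptModel(f"TDEC{j:04d}", f"MGdec{j:04d}",
                                                  spec.chrom, spec.strand,
                                                  list(dtx.segments)),
                                  biotype=None))
            rescued.append(gid_b)
        else:
            missing_a_confirmed.append(gid_b)
    cat["missing_from_A"] = missing_a_confirmed + rescued
    cat["rescued_from_A"] = rescued
    cat["decoys"] = [f"DEC{j:04d}" for j in range(config.n_rescued_A)]

    # ---- genes present only in A (missing from B) --------------------------
    missing_b = []
    for j in range(config.n_missing_from_B):
        spec = _draw_spec(rng)
        spec.chrom, spec.start = layout.alloc(spec.width())
        gid_a, gid_m = f"GAM{j:04d}", f"MGmB{j:04d}"
        A.add_gene(_make_gene(gid_a, _stamp_transcript(spec, f"TAM{j:04d}", gid_a),
                              symbol=f"aonly{j}"))
        M.add_gene(_make_gene(gid_m, _stamp_transcript(spec, f"TAM{j:04d}", gid_m),
                              biotype="protein_coding"))
        missing_b.append(gid_a)
    cat["missing_from_B"] = missing_b

    # ---- B genes dropped by the merge (add-back material) ------------------
    absent_merged = []
    for j in range(config.n_absent_from_merged):
        spec = _draw_spec(rng)
        spec.chrom, spec.start = layout.alloc(spec.width())
        gid_b = f"GBD{j:04d}"
        B.add_gene(_make_gene(gid_b, _stamp_transcript(spec, f"TBD{j:04d}", gid_b),
                              symbol=f"dropped{j}"))
        absent_merged.append(gid_b)
    cat["absent_from_merged"] = absent_merged

    # ---- split genes: large UTR-bearing piece + stray single exon ----------
    split_ids = []
    for j in range(config.n_split_genes):
        spec = _draw_spec(rng, min_exons=3)
        spec.chrom, spec.start = layout.alloc(spec.width())
        gid = f"GBS{j:04d}"
        tx1 = _stamp_transcript(spec, f"TBS{j:04d}a", gid)
        # stray single-exon piece on a dedicated unplaced contig
        stray_chrom, os_ = layout.alloc(100, chrom="chrUn")
        tx2 = TranscriptModel(f"TBS{j:04d}b", gid, stray_chrom, spec.strand, [
            FeatureSegment(Interval(stray_chrom, os_, os_ + 99, spec.strand), "exon")])
        B.add_gene(GeneModel(gene_id=gid,
                             transcripts={t.transcript_id: t for t in (tx1, tx2)},
                             symbol=f"split{j}", biotype="protein_coding"))
        split_ids.append(gid)
        man.split_gene_kept_chrom[gid] = spec.chrom
    cat["split_genes"] = split_ids

    # ---- small RNAs and miRNAs (annotation A only, copied into the merge) --
    small_ids, mirna_ids = [], []
    for biotype in sorted(config.n_small_rna):
        for j in range(config.n_small_rna[biotype]):
            spec = _draw_spec(rng, coding=False, max_exons=1)
            spec.chrom, spec.start = layout.alloc(spec.width())
            gid = f"GAS_{biotype}{j:03d}"
            tx = _stamp_transcript(spec, f"TAS_{biotype}{j:03d}", gid)
            A.add_gene(_make_gene(gid, tx, symbol=f"{biotype.lower()}{j}", biotype=biotype))
            mgid = f"MGS_{biotype}{j:03d}"
            M.add_gene(_make_gene(
                mgid, TranscriptModel(tx.transcript_id, mgid, tx.chrom, tx.strand,
                                      list(tx.segments)),
                symbol=f"{biotype.lower()}{j}", biotype=biotype))
            small_ids.append(mgid)
    for j in range(config.n_mirna):
        spec = _draw_spec(rng, coding=False, max_exons=1)
        spec.chrom, spec.start = layout.alloc(spec.width())
        gid = f"GAmir{j:03d}"
        tx = _stamp_transcript(spec, f"TAmir{j:03d}", gid)
        A.add_gene(_make_gene(gid, tx, symbol=f"mir{j}", biotype="miRNA"))
        mgid = f"MGmir{j:03d}"
        M.add_gene(_make_gene(
            mgid, TranscriptModel(tx.transcript_id, mgid, tx.chrom, tx.strand,
                                  list(tx.segments)),
            symbol=f"mir{j}", biotype="miRNA"))
        mirna_ids.append(mgid)
    cat["small_rna_merged"] = small_ids
    cat["mirna_merged"] = mirna_ids

    # ---- novel XLOC loci ----------------------------------------------------
    conf_cycle = ["exact", "high", "moderate"]
    for j in range(xn.get("single_exon_no_evidence", 0)):
        spec = _draw_spec(rng, coding=False, max_exons=1)
        spec.chrom, spec.start = layout.alloc(spec.width())
        xid = f"XLOC_S{j:06d}"
        M.add_gene(_make_gene(xid, _stamp_transcript(spec, f"TX_S{j:06d}", xid),
                              symbol=xid, biotype=None))
        if j % 2 == 0:
            evidence.append(EvidenceRow(xid, "low", "zebrafish"))
        xloc_expected[xid] = "drop"
    for j in range(xn.get("multi_exon", 0)):
        spec = _draw_spec(rng, coding=False, min_exons=2, max_exons=4)
        spec.chrom, spec.start = layout.alloc(spec.width())
        xid = f"XLOC_M{j:06d}"
        M.add_gene(_make_gene(xid, _stamp_transcript(spec, f"TX_M{j:06d}", xid),
                              symbol=xid, biotype=None))
        xloc_expected[xid] = "retain"
    for j in range(xn.get("evidence_backed", 0)):
        spec = _draw_spec(rng, coding=False, max_exons=1)
        spec.chrom, spec.start = layout.alloc(spec.width())
        xid = f"XLOC_E{j:06d}"
        M.add_gene(_make_gene(xid, _stamp_transcript(spec, f"TX_E{j:06d}", xid),
                              symbol=xid, biotype=None))
        evidence.append(EvidenceRow(xid, conf_cycle[j % 3],
                                    "human" if j % 2 else "zebrafish"))
        xloc_expected[xid] = "retain"
    for j in range(xn.get("lincRNA_matched", 0)):
        spec = _draw_spec(rng, coding=False, max_exons=1)
        spec.chrom, spec.start = layout.alloc(spec.width())
        xid = f"XLOC_L{j:06d}"
        xtx = _stamp_transcript(spec, f"TX_L{j:06d}", xid)
        M.add_gene(_make_gene(xid, xtx, symbol=xid, biotype=None))
        lid = f"LINC{j:04d}"
        L.add_gene(_make_gene(
            lid, TranscriptModel(f"TLINC{j:04d}", lid, xtx.chrom, xtx.strand,
                                 list(xtx.segments)),
            symbol=lid, biotype="lincRNA"))
        xloc_expected[xid] = "retain"

    # ---- manifest predictions (bookkeeping only) ----------------------------
    n_host = xn.get("redundant", 0)
    n_flank = 2 * config.n_fusion_transcripts
    n_small_total = sum(config.n_small_rna.values())
    a_total = (n + n_host + n_flank + config.n_missing_from_B
               + config.n_rescued_A + n_small_total + config.n_mirna)
    b_total = (n + n_host + n_flank + config.n_missing_from_A
               + config.n_absent_from_merged + config.n_split_genes)
    man.audit_expected = {
        "A": {
            "n_genes_total": a_total,
            "n_genes_cds": n + n_host + n_flank + config.n_missing_from_B,
            "n_cds_missing_stop": n_ms_a,
            "n_cds_missing_utr3": n_mu_a,
        },
        "B": {
            "n_genes_total": b_total,
            "n_genes_cds": b_total,
            "n_cds_missing_stop": n_ms_b,
            "n_cds_missing_utr3": n_mu_b,
        },
    }
    n_rows = (n - n_mu_a - n_mu_b) + n_host + n_flank
    man.refset_expected = {
        "n_rows": n_rows,
        "n_longer_A": config.n_utr_longer_A,
        "n_longer_B": config.n_utr_longer_B,
        "n_same": n_rows - config.n_utr_longer_A - config.n_utr_longer_B,
        "longer_A_ids": [f"GA{i:05d}" for i in sorted(idx_la)],
        "longer_B_ids": [f"GA{i:05d}" for i in sorted(idx_lb)],
        "n_longer_C": config.n_utr_longer_merged,
        "longer_C_ids": [f"GA{i:05d}" for i in sorted(idx_lm)],
    }
    man.missing_expected = {
        "query_A_ref_B": sorted(missing_a_confirmed + absent_merged + split_ids),
        "query_B_ref_A": sorted(
            missing_b
            + [g.gene_id for g in A.genes.values() if g.biotype
               and (g.biotype in config.n_small_rna or g.biotype == "miRNA")]
        ),
        "query_merged_ref_B": sorted(absent_merged + split_ids),
        "query_merged_ref_A": [],
    }
    man.counts = {
        "merged_genes": len(M),
        "fusion_transcripts": config.n_fusion_transcripts,
        "small_rna_removed": n_small_total,
        "added_back": config.n_absent_from_merged + config.n_split_genes,
        "curated_genes": (len(M) - config.n_fusion_transcripts - n_small_total
                          + config.n_absent_from_merged + config.n_split_genes),
        "n_multi_locus_symbol_conflicts": config.n_duplicate_symbols,
    }
    # record gene-id lists of the role slices for exact per-gene checks
    for role, idxs in (
        ("missing_utr3_A", idx_mu_a), ("missing_utr3_B", idx_mu_b),
        ("missing_stop_A", idx_ms_a), ("missing_stop_B", idx_ms_b),
        ("same_control", idx_ctrl),
    ):
        cat[role] = [f"GA{i:05d}" for i in sorted(idxs)]

    return FixtureSet(A, B, M, L, evidence, man)


def _config_dict(config: FixtureConfig) -> dict:
    d = asdict(config)
    d["utr_delta_range"] = list(d["utr_delta_range"])
    return d
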