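"""Shared builders for hand-constructed annotation objects."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from annoforge.model import (
    FeatureSegment,
    GeneModel,
    GenomeAnnotation,
    Interval,
    TranscriptModel,
)


def make_tx(
    tx_id: str,
    gene_id: str,
    chrom: str,
    strand: str,
    exons,
    cds=None,
    stop=None,
    utr3=None,
    utr5=None,
) -> TranscriptModel:
    """Build a transcript from (start, end) tuples per feature kind."""
    segs = []

    def add(kind, ivs):
        for s, e in ivs or []:
            segs.append(FeatureSegment(Interval(chrom, s, e, strand), kind))

    add("exon", exons)
    add("CDS", cds)
    add("stop_codon", stop)
    add("three_prime_utr", utr3)
    add("five_prime_utr", utr5)
    return TranscriptModel(tx_id, gene_id, chrom, strand, segs)


def make_gene(gene_id, *txs, symbol=None, biotype="protein_coding") -> GeneModel:
    return GeneModel(
        gene_id=gene_id,
        transcripts={t.transcript_id: t for t in txs},
        symbol=symbol,
        biotype=biotype,
    )


def make_ann(label, *genes) -> GenomeAnnotation:
    return GenomeAnnotation(label, {g.gene_id: g for g in genes})


@pytest.fixture(scope="session")
def default_fixture():
    """One generated fixture set shared by read-only tests."""
    from annoforge.fixtures import FixtureConfig, generate

    return generate(FixtureConfig(n_genes=120, seed=11, n_alt_genes=5))
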