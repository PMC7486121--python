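"""Fusion removal, nomenclature, add-back, LL IDs and the gene-info table."""

import pytest

from annoforge.curation import (
    CurationLog,
    add_back_missing,
    assign_ll_ids,
    assign_nomenclature,
    build_gene_info,
    detect_fusion_transcripts,
    remove_small_rna,
    remove_transcripts,
)
from annoforge.matching import match_annotations
from annoforge.model import read_gtf, write_gtf

from conftest import make_ann, make_gene, make_tx


def _two_ref_genes(strand_b="+"):
    ga = make_gene("ga", make_tx("ta", "ga", "chr1", "+", [(1000, 1500)]),
                   symbol="alpha")
    gb = make_gene("gb", make_tx("tb", "gb", "chr1", strand_b, [(3000, 3500)]),
                   symbol="beta")
    return make_ann("ref", ga, gb)


class TestFusionDetection:
    def test_same_strand_bridge_flagged(self):
        ref = _two_ref_genes()
        merged = make_ann(
            "m",
            make_gene("mf", make_tx("tf", "mf", "chr1", "+",
                                    [(1100, 1400), (3100, 3400)])),
        )
        (flag,) = detect_fusion_transcripts(merged, [ref], min_overlap_bp=30)
        assert flag.transcript_id == "tf"
        assert set(flag.overlapped_gene_ids) == {"ga", "gb"}
        assert all(bp == 301 for bp in flag.overlap_bp)

    def test_opposite_strand_gene_not_counted(self):
        ref = _two_ref_genes(strand_b="-")
        merged = make_ann(
            "m",
            make_gene("mf", make_tx("tf", "mf", "chr1", "+",
                                    [(1100, 1400), (3100, 3400)])),
        )
        assert detect_fusion_transcripts(merged, [ref]) == []

    def test_same_locus_in_two_references_counts_once(self):
        # both references annotate the same gene (same symbol): not a fusion
        ref1 = make_ann("r1", make_gene(
            "e1", make_tx("et", "e1", "chr1", "+", [(1000, 2000)]), symbol="alpha"))
        ref2 = make_ann("r2", make_gene(
            "n1", make_tx("nt", "n1", "chr1", "+", [(1000, 2000)]), symbol="alpha"))
        merged = make_ann("m", make_gene(
            "mg", make_tx("mt", "mg", "chr1", "+", [(1000, 2000)])))
        assert detect_fusion_transcripts(merged, [ref1, ref2]) == []

    def test_below_min_overlap_not_flagged(self):
        ref = _two_ref_genes()
        merged = make_ann(
            "m",
            make_gene("mf", make_tx("tf", "mf", "chr1", "+",
                                    [(1481, 1500), (3000, 3400)])),  # 20 bp on ga
        )
        assert detect_fusion_transcripts(merged, [ref], min_overlap_bp=30) == []

    def test_fixture_flags_match_manifest_and_idempotence(self, default_fixture):
        fx = default_fixture
        refs = [fx.ann_a, fx.ann_b]
        flags = detect_fusion_transcripts(fx.merged, refs)
        assert sorted(f.transcript_id for f in flags) == sorted(fx.manifest.fusion_transcripts)
        cleaned = remove_transcripts(fx.merged, [f.transcript_id for f in flags])
        assert detect_fusion_transcripts(cleaned, refs) == []


class TestRemoveTranscripts:
    def test_removing_only_transcript_removes_gene(self):
        ann = make_ann("x", make_gene("g", make_tx("t", "g", "chr1", "+", [(1, 100)])))
        log = CurationLog()
        out = remove_transcripts(ann, ["t"], log)
        assert len(out) == 0 and log.removed_genes == ["g"]

    def test_partial_removal_keeps_gene(self):
        g = make_gene("g", *(make_tx(f"t{i}", "g", "chr1", "+", [(1, 100)][:1])
                             for i in range(3)))
        out = remove_transcripts(make_ann("x", g), ["t0"])
        assert len(out.genes["g"].transcripts) == 2

    def test_unknown_id_raises(self):
        ann = make_ann("x", make_gene("g", make_tx("t", "g", "chr1", "+", [(1, 100)])))
        with pytest.raises(KeyError, match="nope"):
            remove_transcripts(ann, ["nope"])


class TestRemoveSmallRna:
    def test_small_rna_removed_mirna_kept(self):
        genes = [
            make_gene(f"r{i}", make_tx(f"rt{i}", f"r{i}", "chr1", "+",
                                       [(1000 * i + 1, 1000 * i + 100)]),
                      biotype="rRNA")
            for i in range(20)
        ] + [
            make_gene(f"m{i}", make_tx(f"mt{i}", f"m{i}", "chr2", "+",
                                       [(1000 * i + 1, 1000 * i + 90)]),
                      biotype="miRNA")
            for i in range(5)
        ]
        out = remove_small_rna(make_ann("x", *genes))
        assert len(out) == 5
        assert all(g.biotype == "miRNA" for g in out.genes.values())

    def test_no_biotypes_warns_and_keeps_all(self):
        ann = make_ann("x", make_gene("g", make_tx("t", "g", "chr1", "+", [(1, 100)]),
                                      biotype=None))
        log = CurationLog()
        out = remove_small_rna(ann, log=log)
        assert len(out) == 1 and log.warnings

    def test_empty_biotype_set_is_noop(self):
        ann = make_ann("x", make_gene("g", make_tx("t", "g", "chr1", "+", [(1, 100)]),
                                      biotype="rRNA"))
        assert len(remove_small_rna(ann, biotypes=set())) == 1

    def test_mirna_kept_even_if_listed(self):
        ann = make_ann("x", make_gene("g", make_tx("t", "g", "chr1", "+", [(1, 100)]),
                                      biotype="miRNA"))
        assert len(remove_small_rna(ann, biotypes={"miRNA", "rRNA"})) == 1


class TestNomenclature:
    def _setup(self):
        merged = make_ann(
            "m",
            make_gene("m1", make_tx("mt1", "m1", "chr1", "+", [(100, 200), (300, 400)])),
            make_gene("m2", make_tx("mt2", "m2", "chr1", "+", [(5000, 5200)])),
            make_gene("XLOC_1", make_tx("xt1", "XLOC_1", "chr2", "+", [(100, 300)])),
        )
        ens = make_ann("e", make_gene(
            "e1", make_tx("et1", "e1", "chr1", "+", [(100, 200), (300, 400)]),
            symbol="alpha"))
        refseq = make_ann(
            "r",
            make_gene("r1", make_tx("rt1", "r1", "chr1", "+", [(100, 200), (300, 400)]),
                      symbol="ALPHA1"),
            make_gene("r2", make_tx("rt2", "r2", "chr1", "+", [(5000, 5200)]),
                      symbol="beta"),
        )
        return merged, ens, refseq

    def test_priority_and_fallbacks(self):
        merged, ens, refseq = self._setup()
        rep_e = match_annotations(merged, ens)
        rep_r = match_annotations(merged, refseq)
        named, conflicts = assign_nomenclature(merged, ens, refseq, rep_e, rep_r)
        assert named.genes["m1"].symbol == "alpha"     # Ensembl beats RefSeq
        assert named.genes["m2"].symbol == "beta"      # RefSeq fallback
        assert named.genes["XLOC_1"].symbol == "XLOC_1"
        # m1 matched two references with different symbols
        assert any(c.kind == "multi_reference" for c in conflicts)

    def test_duplicate_symbol_conflicts_on_fixture(self, default_fixture):
        fx = default_fixture
        rep_e = match_annotations(fx.merged, fx.ann_a)
        rep_r = match_annotations(fx.merged, fx.ann_b)
        _, conflicts = assign_nomenclature(fx.merged, fx.ann_a, fx.ann_b, rep_e, rep_r)
        multi_locus = [c for c in conflicts if c.kind == "multi_locus"]
        expected = fx.manifest.counts["n_multi_locus_symbol_conflicts"]
        assert len(multi_locus) == expected
        for sym in fx.manifest.duplicate_symbols:
            assert any(f"symbol {sym} " in c.detail for c in multi_locus)


class TestAddBack:
    def test_split_gene_larger_piece_with_utr_wins(self):
        big = make_tx("tb", "sg", "chr5", "+",
                      exons=[(100 * i, 100 * i + 80) for i in range(1, 13)],
                      utr3=[(1200, 1240)])
        small = make_tx("ts", "sg", "chr7", "+", [(500, 560)])
        ref = make_ann("ref", make_gene("sg", big, small))
        out = add_back_missing(make_ann("cur"), {"ref": ["sg"]}, {"ref": ref})
        assert out.genes["sg"].chroms == ["chr5"]
        assert out.genes["sg"].match_note == "added_back_ref"

    def test_collision_with_existing_gene_skipped(self):
        cur = make_ann("cur", make_gene(
            "existing", make_tx("te", "existing", "chr1", "+", [(100, 500)])))
        ref = make_ann("ref", make_gene(
            "missing", make_tx("tm", "missing", "chr1", "+", [(300, 700)])))
        log = CurationLog()
        out = add_back_missing(cur, {"ref": ["missing"]}, {"ref": ref}, log)
        assert "missing" not in out.genes
        assert log.skipped_addbacks and log.skipped_addbacks[0][0] == "missing"

    def test_empty_list_is_noop(self):
        cur = make_ann("cur", make_gene(
            "g", make_tx("t", "g", "chr1", "+", [(1, 100)])))
        out = add_back_missing(cur, {"ref": []}, {"ref": make_ann("ref")})
        assert set(out.genes) == {"g"}


class TestLlIds:
    def test_positional_order_and_tie_rule(self):
        ann = make_ann(
            "x",
            make_gene("zz", make_tx("t1", "zz", "chr1", "+", [(100, 200)])),
            make_gene("aa", make_tx("t2", "aa", "chr1", "+", [(100, 150)])),  # tie start
            make_gene("bb", make_tx("t3", "bb", "chr2", "+", [(50, 90)])),
        )
        _, table = assign_ll_ids(ann)
        assert list(table["gene_id"]) == ["aa", "zz", "bb"]
        assert list(table["ll_id"]) == ["LL1", "LL2", "LL3"]

    def test_rerun_identical(self, default_fixture):
        _, t1 = assign_ll_ids(default_fixture.merged)
        _, t2 = assign_ll_ids(default_fixture.merged)
        assert t1.equals(t2)

    def test_ll_id_survives_gtf_round_trip(self, tmp_path):
        ann = make_ann("x", make_gene(
            "g", make_tx("t", "g", "chr1", "+", [(100, 200)])))
        with_ids, _ = assign_ll_ids(ann)
        p = tmp_path / "ll.gtf"
        write_gtf(with_ids, p)
        back = read_gtf(p, "x")
        (tx,) = back.genes["g"].transcripts.values()
        assert ("ll_id", "LL1") in tx.segments[0].attrs


def test_gene_info_table(default_fixture):
    fx = default_fixture
    rep_e = match_annotations(fx.merged, fx.ann_a)
    rep_r = match_annotations(fx.merged, fx.ann_b)
    with_ids, _ = assign_ll_ids(fx.merged)
    info = build_gene_info(
        with_ids,
        crosswalks={"ncbi": {gid: f"ncbi:{gid}" for gid in fx.ann_b.genes}},
        report_ens=rep_e,
        report_refseq=rep_r,
    )
    assert len(info) == len(fx.merged)
    assert info["ll_id"].is_unique
    by_gene = info.set_index("gene_id")
    # a plain matched gene links to its source annotations with a full match
    assert by_gene.loc["MG00000", "match_note"] == "full_transcript_match"
    assert by_gene.loc["MG00000", "ensembl_gene_id"] == "GA00000"
    # XLOC genes carry no external IDs
    xloc = info[info["gene_id"].str.startswith("XLOC")]
    assert (xloc["ensembl_gene_id"] == "").all()
    assert (xloc["match_note"] == "novel_xloc").all()


def test_curation_conservation_on_fixture(default_fixture):
    fx = default_fixture
    man = fx.manifest
    log = CurationLog()
    flags = detect_fusion_transcripts(fx.merged, [fx.ann_a, fx.ann_b])
    cur = remove_transcripts(fx.merged, [f.transcript_id for f in flags], log)
    cur = remove_small_rna(cur, log=log)
    missing = match_annotations(cur, fx.ann_b).missing_gene_list
    cur = add_back_missing(cur, {"B": missing}, {"B": fx.ann_b}, log)
    assert len(cur) == man.counts["curated_genes"]
    assert len(cur) == (man.counts["merged_genes"] - len(log.removed_genes)
                        + len(log.added_genes))
    for gid, chrom in man.split_gene_kept_chrom.items():
        assert cur.genes[gid].chroms == [chrom]
    ids1 = assign_ll_ids(cur)[1]
    ids2 = assign_ll_ids(cur.copy())[1]
    assert ids1.equals(ids2)
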