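"""Intron-chain transcript matching, class codes and missing-gene detection."""

import pytest

from annoforge.matching import (
    MatchClass,
    classify_pair,
    confirm_missing_genes,
    intersect_gene_sets,
    intron_chain,
    match_annotations,
)

from conftest import make_ann, make_gene, make_tx


def tx3(tx_id="q", gene_id="g", strand="+", chrom="chr1", shift=0, last_ext=0):
    """Three-exon transcript; shift moves all exons, last_ext lengthens exon 3."""
    exons = [(100 + shift, 200 + shift), (300 + shift, 400 + shift),
             (500 + shift, 700 + shift + last_ext)]
    return make_tx(tx_id, gene_id, chrom, strand, exons)


class TestIntronChain:
    def test_two_exons(self):
        t = make_tx("t", "g", "chr1", "+", [(1, 100), (201, 300)])
        assert intron_chain(t).junctions == ((100, 201),)

    def test_single_exon_empty(self):
        t = make_tx("t", "g", "chr1", "+", [(1, 100)])
        assert intron_chain(t).junctions == ()

    def test_five_exons_strictly_increasing(self):
        exons = [(i * 1000, i * 1000 + 100) for i in range(1, 6)]
        t = make_tx("t", "g", "chr1", "-", exons)
        j = intron_chain(t).junctions
        assert len(j) == 4
        flat = [p for pair in j for p in pair]
        assert flat == sorted(flat)


class TestClassifyPair:
    def test_identical_is_full(self):
        assert classify_pair(tx3("q"), tx3("r")) is MatchClass.FULL

    def test_terminal_exon_difference_still_full(self):
        # same intron chain, 3' terminal exon 500 nt longer in the query
        assert classify_pair(tx3("q", last_ext=500), tx3("r")) is MatchClass.FULL

    def test_contiguous_subchain_is_contained(self):
        q = make_tx("q", "g", "chr1", "+", [(300, 400), (500, 700)])
        assert classify_pair(q, tx3("r")) is MatchClass.CONTAINED

    def test_contained_is_antisymmetric(self):
        q = make_tx("q", "g", "chr1", "+", [(300, 400), (500, 700)])
        assert classify_pair(tx3("r"), q) is not MatchClass.CONTAINED

    def test_single_exon_inside_reference_exon_is_contained(self):
        q = make_tx("q", "g", "chr1", "+", [(520, 600)])
        assert classify_pair(q, tx3("r")) is MatchClass.CONTAINED

    def test_shared_junction_is_junction_overlap(self):
        q = make_tx("q", "g", "chr1", "+", [(50, 200), (300, 360), (380, 450)])
        assert classify_pair(q, tx3("r")) is MatchClass.JUNCTION_OVERLAP

    def test_exonic_overlap_without_junction(self):
        q = make_tx("q", "g", "chr1", "+", [(150, 250)])
        assert classify_pair(q, tx3("r")) is MatchClass.EXONIC_OVERLAP

    def test_antisense(self):
        q = make_tx("q", "g", "chr1", "-", [(150, 250)])
        assert classify_pair(q, tx3("r")) is MatchClass.ANTISENSE

    def test_no_overlap_and_other_chrom_are_none(self):
        assert classify_pair(tx3("q", shift=10_000), tx3("r")) is MatchClass.NONE
        assert classify_pair(tx3("q", chrom="chr2"), tx3("r")) is MatchClass.NONE

    @pytest.mark.parametrize("overlap_frac, expected", [
        (0.9, MatchClass.FULL),
        (0.5, MatchClass.EXONIC_OVERLAP),
    ])
    def test_single_exon_reciprocal_threshold(self, overlap_frac, expected):
        r = make_tx("r", "g", "chr1", "+", [(1, 1000)])
        ov = int(1000 * overlap_frac)
        q = make_tx("q", "g", "chr1", "+", [(1000 - ov + 1, 2000 - ov)])
        assert classify_pair(q, r) is expected

    def test_unstranded_never_full(self):
        q = make_tx("q", "g", "chr1", ".", [(100, 200), (300, 400), (500, 700)])
        assert classify_pair(q, tx3("r")) is not MatchClass.FULL

    def test_full_symmetric_for_multi_exon(self):
        a, b = tx3("a", last_ext=300), tx3("b")
        assert classify_pair(a, b) is classify_pair(b, a) is MatchClass.FULL


def test_self_comparison_all_full_zero_missing(default_fixture):
    ann = default_fixture.ann_a
    rep = match_annotations(ann, ann)
    assert rep.missing_gene_list == []
    assert all(cls is MatchClass.FULL for _, cls in rep.per_transcript.values())


def test_fixture_missing_genes_match_manifest(default_fixture):
    fx = default_fixture
    man = fx.manifest.missing_expected
    assert match_annotations(fx.ann_a, fx.ann_b).missing_gene_list == man["query_A_ref_B"]
    assert match_annotations(fx.ann_b, fx.ann_a).missing_gene_list == man["query_B_ref_A"]
    assert match_annotations(fx.merged, fx.ann_b).missing_gene_list == man["query_merged_ref_B"]
    assert match_annotations(fx.merged, fx.ann_a).missing_gene_list == []


def test_rescue_rule():
    # gene with one matched and one unmatched transcript is not missing
    ref = make_ann(
        "ref",
        make_gene("rg",
                  make_tx("rt1", "rg", "chr1", "+", [(100, 200), (300, 400)]),
                  make_tx("rt2", "rg", "chr1", "+", [(9000, 9100)])),
        make_gene("rg2", make_tx("rt3", "rg2", "chr1", "+", [(20_000, 20_100)])),
    )
    query = make_ann(
        "q", make_gene("qg", make_tx("qt1", "qg", "chr1", "+", [(100, 200), (300, 400)]))
    )
    rep = match_annotations(query, ref)
    assert rep.missing_gene_list == ["rg2"]
    assert confirm_missing_genes(rep, ref) == ["rg2"]


def test_missing_count_antitone_in_query_completeness(default_fixture):
    fx = default_fixture
    rep = match_annotations(fx.ann_a, fx.ann_b)
    before = list(rep.missing_gene_list)
    assert before
    # graft a copy of one missing reference gene into the query
    richer = fx.ann_a.copy("A+")
    gid = before[0]
    gene = fx.ann_b.genes[gid]
    from annoforge.model import GeneModel, TranscriptModel

    copied = GeneModel(
        gene_id="grafted",
        transcripts={
            f"graft_{tid}": TranscriptModel(f"graft_{tid}", "grafted", t.chrom,
                                            t.strand, list(t.segments))
            for tid, t in gene.transcripts.items()
        },
    )
    richer.add_gene(copied)
    after = match_annotations(richer, fx.ann_b).missing_gene_list
    assert gid not in after
    assert set(after) <= set(before)


class TestIntersectGeneSets:
    def test_identical_sets(self):
        res = intersect_gene_sets(["a", "b"], ["a", "b"])
        assert (len(res["a_only"]), len(res["b_only"]), len(res["both"])) == (0, 0, 2)

    def test_disjoint_sets(self):
        res = intersect_gene_sets(["a", "b"], ["c"])
        assert (len(res["a_only"]), len(res["b_only"]), len(res["both"])) == (2, 1, 0)

    def test_crosswalk_recovers_planted_overlap(self):
        # 40 A-IDs and 45 B-IDs sharing 30 common NCBI IDs, plus unmapped strays
        xa = {f"ensg{i}": f"ncbi{i}" for i in range(40)}
        xb = {f"refg{i}": f"ncbi{i + 10}" for i in range(45)}
        set_a = list(xa) + ["stray_a"]
        set_b = list(xb) + ["stray_b"]
        res = intersect_gene_sets(set_a, set_b, xa, xb)
        assert len(res["both"]) == 30
        assert len(res["a_only"]) == 10
        assert len(res["b_only"]) == 15
        assert res["unmapped_a"] == res["unmapped_b"] == 1

    def test_duplicate_crosswalk_targets_reported(self):
        xa = {"g1": "n1", "g2": "n1"}
        res = intersect_gene_sets(["g1", "g2"], [], xa, {})
        assert res["ambiguous_a"] == ["n1"]
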