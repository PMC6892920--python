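"""Transcript models, GTF round-trips and the discovery filter cascade."""

import math

import numpy as np
import pytest

from mslinc.annotation import (
    AnnotationCatalog,
    TranscriptModel,
    distance_to_nearest_known,
    filter_novel_lincrnas,
    mature_length,
    nearest_gene_assignment,
    parse_gtf,
    write_gtf,
)


def t(tid, exons, chrom="chr1", strand="+", biotype="candidate", gene=None):
    return TranscriptModel(tid, chrom, strand, exons, biotype, gene_id=gene or tid)


class StubScorer:
    """Fixed-probability coding-potential scorer for filter-logic tests."""

    def __init__(self, p_by_id=None, default=0.01, tau=0.5):
        self.p_by_id = p_by_id or {}
        self.default = default
        self.tau = tau

    def score(self, tid, seq):
        from mslinc.codepot import CodingPotentialResult

        p = self.p_by_id.get(tid, self.default)
        return CodingPotentialResult(
            tid, 0.0, 0.0, 0, 0.0, p, p, p < self.tau and p < self.tau
        )


class TestTranscriptModel:
    def test_mature_length_cases(self):
        assert mature_length(t("a", [(0, 1673)])) == 1673
        assert mature_length(t("b", [(0, 100), (200, 300)])) == 200

    def test_empty_exons_rejected(self):
        with pytest.raises(ValueError):
            TranscriptModel("x", "chr1", "+", [])

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            t("x", [(0, 100), (50, 150)])

    def test_tss_is_strand_aware(self):
        assert t("p", [(100, 200)], strand="+").tss == 100
        assert t("m", [(100, 200)], strand="-").tss == 199


class TestGtf:
    def test_coordinate_convention(self, tmp_path):
        path = tmp_path / "one.gtf"
        path.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        cat = parse_gtf(path)
        assert cat["t1"].exons == [(100, 200)]
        assert cat["t1"].mature_length == 100

    def test_multi_exon_grouping(self, tmp_path):
        path = tmp_path / "two.gtf"
        path.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\ttranscript_id "t1";\n'
            'chr1\tsrc\texon\t301\t350\t.\t+\t.\ttranscript_id "t1";\n'
        )
        cat = parse_gtf(path)
        assert len(cat) == 1
        assert cat["t1"].exons == [(100, 200), (300, 350)]
        assert cat["t1"].mature_length == 150

    def test_round_trip_preserves_coordinates(self, tmp_path):
        original = [
            t("a", [(100, 200), (500, 700)], strand="-", biotype="coding"),
            t("b", [(10, 60)], chrom="chr2"),
        ]
        path = tmp_path / "rt.gtf"
        write_gtf(original, path)
        back = parse_gtf(path)
        for orig in original:
            assert back[orig.id].exons == orig.exons
            assert back[orig.id].strand == orig.strand
            assert back[orig.id].biotype == orig.biotype


class TestDistance:
    def test_gap_arithmetic(self):
        cat = AnnotationCatalog([t("g", [(0, 1000)], biotype="coding")])
        assert distance_to_nearest_known(t("x", [(5000, 6000)]), cat) == 4000

    def test_overlap_is_zero(self):
        cat = AnnotationCatalog([t("g", [(0, 1000)])])
        assert distance_to_nearest_known(t("x", [(500, 1500)]), cat) == 0

    def test_empty_chromosome_is_infinite(self):
        cat = AnnotationCatalog([t("g", [(0, 1000)], chrom="chr2")])
        assert distance_to_nearest_known(t("x", [(0, 100)]), cat) == math.inf

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            knowns = [
                t(f"g{i}", [(int(s), int(s) + int(rng.integers(50, 2000)))],
                  chrom=f"chr{rng.integers(1, 3)}")
                for i, s in enumerate(rng.integers(0, 500_000, size=200))
            ]
            cat = AnnotationCatalog(knowns)
            s = int(rng.integers(0, 500_000))
            q = t("q", [(s, s + 500)], chrom=f"chr{rng.integers(1, 3)}")
            brute = min(
                (max(k.start - q.end, q.start - k.end, 0)
                 for k in knowns if k.chrom == q.chrom),
                default=math.inf,
            )
            assert distance_to_nearest_known(q, cat) == brute


class TestNearestGene:
    def test_picks_nearer_gene(self):
        cat = AnnotationCatalog([
            t("near", [(20_000, 21_000)], biotype="coding"),
            t("far", [(70_000, 71_000)], biotype="coding"),
        ])
        assert nearest_gene_assignment(t("q", [(0, 10_000)]), cat) == "near"

    def test_none_outside_window(self):
        cat = AnnotationCatalog([t("g", [(5_000_000, 5_001_000)], biotype="coding")])
        assert nearest_gene_assignment(t("q", [(0, 100)]), cat, max_dist=1_000_000) is None

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            genes = [
                t(f"g{i}", [(int(s), int(s) + 1000)], biotype="coding")
                for i, s in enumerate(rng.integers(0, 2_000_000, size=30))
            ]
            cat = AnnotationCatalog(genes)
            s = int(rng.integers(0, 2_000_000))
            q = t("q", [(s, s + 300)])
            gaps = {
                g.id: max(g.start - q.end, q.start - g.end, 0) for g in genes
            }
            in_range = {g: d for g, d in gaps.items() if d <= 1_000_000}
            expected = (
                min(in_range, key=lambda g: (in_range[g], cat[g].start, g))
                if in_range else None
            )
            assert nearest_gene_assignment(q, cat) == expected


class TestFilterCascade:
    @pytest.fixture()
    def known(self):
        return AnnotationCatalog([t("g", [(0, 10_000)], biotype="coding")])

    def test_distance_boundary_1999_rejected(self, known):
        cand = AnnotationCatalog([t("c", [(11_999, 12_500)])])
        res = filter_novel_lincrnas(cand, known, {"c": "A" * 501}, StubScorer())
        assert res.accepted == []
        assert res.audit.loc[0, "reason"] == "distance"

    def test_distance_boundary_2000_passes(self, known):
        cand = AnnotationCatalog([t("c", [(12_000, 12_500)])])
        res = filter_novel_lincrnas(cand, known, {"c": "A" * 500}, StubScorer())
        assert res.accepted == ["c"]

    def test_length_boundary_199_rejected(self, known):
        cand = AnnotationCatalog([t("c", [(20_000, 20_199)])])
        res = filter_novel_lincrnas(cand, known, {"c": "A" * 199}, StubScorer())
        assert res.audit.loc[0, "reason"] == "length"

    def test_coding_call_rejects(self, known):
        cand = AnnotationCatalog([t("c", [(20_000, 20_500)])])
        res = filter_novel_lincrnas(
            cand, known, {"c": "A" * 500}, StubScorer({"c": 0.9})
        )
        assert res.audit.loc[0, "reason"] == "coding"

    def test_missing_sequence_names_candidate(self, known):
        cand = AnnotationCatalog([t("c", [(20_000, 20_500)])])
        with pytest.raises(KeyError, match="c"):
            filter_novel_lincrnas(cand, known, {}, StubScorer())

    def test_monotone_in_thresholds(self, study, scorer):
        """Raising min_dist or min_len never grows the accepted set."""
        base = filter_novel_lincrnas(
            study.novel, study.known, study.sequences, scorer
        )
        stricter = filter_novel_lincrnas(
            study.novel, study.known, study.sequences, scorer,
            min_dist=10_000, min_len=1000,
        )
        assert set(stricter.accepted) <= set(base.accepted)

    def test_se_me_partition(self, discovery):
        accepted = set(discovery.accepted)
        se, me = set(discovery.se_lincrnas), set(discovery.me_lincrnas)
        assert se | me == accepted
        assert se & me == set()

    def test_consensus_containment(self, study, scorer):
        """Accepted set is contained in the set passing each filter alone."""
        audit = filter_novel_lincrnas(
            study.novel, study.known, study.sequences, scorer
        ).audit
        acc = audit.verdict == "accepted"
        assert (audit.loc[acc, "gap_bp"] >= 2000).all()
        assert (audit.loc[acc, "mature_len"] >= 200).all()
        assert ((audit.loc[acc, "p_A"] < 0.5) & (audit.loc[acc, "p_B"] < 0.5)).all()
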