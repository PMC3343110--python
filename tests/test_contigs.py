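import numpy as np
import pytest
from oracles import brute_force_contigs, random_hit_set

from retroarray.contigs import (
    Deletion,
    assemble_contigs,
    classify_full_length,
    cluster_recurrent_deletions,
    consensus_coverage,
    detect_deletions,
    find_ltr_flanked,
    match_probes_to_contigs,
    orf_intactness,
    probe_class_counts,
)
from retroarray.model import GenomicAlignment, Parameters, RepeatAnnotationRecord


def hit(start, end, cons_start, cons_end, strand="+", chrom="chr1",
        element="EL", cons_length=900):
    return RepeatAnnotationRecord(
        chrom, start, end, strand, element, "ERVK", "LTR",
        cons_start, cons_end, cons_length)


class TestAssembleContigs:
    def test_two_collinear_hits_merge(self):
        hits = [hit(1000, 1400, 1, 400), hit(1480, 1880, 500, 900)]
        (contig,) = assemble_contigs(hits, cons_length=900)
        assert len(contig.segments) == 2
        assert (contig.span_start, contig.span_end) == (1000, 1880)
        assert contig.coverage_fraction == pytest.approx((400 + 401) / 900)

    def test_single_hit_single_contig(self):
        (contig,) = assemble_contigs([hit(50, 450, 1, 400)], 900)
        assert len(contig.segments) == 1

    def test_strand_switch_splits(self):
        hits = [hit(1000, 1400, 1, 400), hit(1480, 1880, 500, 900, strand="-")]
        assert len(assemble_contigs(hits, 900)) == 2

    def test_gap_boundary_strictly_less_than_consensus_length(self):
        base = hit(1000, 1400, 1, 400)
        at_limit = [base, hit(1400 + 900, 1400 + 900 + 400, 500, 900)]
        below_limit = [base, hit(1400 + 899, 1400 + 899 + 400, 500, 900)]
        assert len(assemble_contigs(at_limit, 900)) == 2
        assert len(assemble_contigs(below_limit, 900)) == 1

    def test_non_collinear_hit_starts_new_contig(self):
        # second hit restarts at the consensus beginning: a new copy
        hits = [hit(1000, 1400, 500, 900), hit(1500, 1900, 1, 400)]
        assert len(assemble_contigs(hits, 900)) == 2

    def test_consensus_overlap_tolerance(self):
        base = hit(1000, 1400, 1, 400)
        slight = [base, hit(1450, 1850, 390, 790)]   # 11 nt overlap: allowed
        heavy = [base, hit(1450, 1850, 300, 700)]    # 101 nt overlap: split
        assert len(assemble_contigs(slight, 900)) == 1
        assert len(assemble_contigs(heavy, 900)) == 2

    def test_minus_strand_descending_consensus_merges(self):
        hits = [hit(1000, 1400, 500, 900, strand="-"),
                hit(1480, 1878, 1, 398, strand="-")]
        (contig,) = assemble_contigs(hits, 900)
        assert contig.strand == "-"
        assert len(contig.segments) == 2

    def test_mixed_elements_rejected(self):
        hits = [hit(0, 100, 1, 100), hit(200, 300, 1, 100, element="OTHER")]
        with pytest.raises(ValueError, match="mixed elements"):
            assemble_contigs(hits, 900)

    def test_partition_and_oracle_agreement_on_random_hit_sets(self, rng):
        """Every hit lands in exactly one contig, and the scan agrees with an
        independent re-implementation of the adjacency rules."""
        for _ in range(25):
            hits = random_hit_set(rng, int(rng.integers(1, 40)))
            contigs = assemble_contigs(hits, 1000)
            flattened = [s for c in contigs for s in c.segments]
            assert sorted(flattened, key=lambda r: r.start) == sorted(
                hits, key=lambda r: r.start)
            expected = brute_force_contigs(hits, 1000)
            assert [len(c.segments) for c in contigs] == [len(g) for g in expected]
            for contig, group in zip(contigs, expected):
                assert list(contig.segments) == group
        # one larger set
        hits = random_hit_set(rng, 200)
        contigs = assemble_contigs(hits, 1000)
        assert [list(c.segments) for c in contigs] == brute_force_contigs(hits, 1000)


class TestCoverage:
    def test_overlapping_segments_union(self):
        segs = [hit(0, 500, 1, 500, cons_length=1000),
                hit(600, 1100, 400, 900, cons_length=1000)]
        covered, fraction = consensus_coverage(segs, 1000)
        assert covered == ((1, 900),)
        assert fraction == pytest.approx(0.9)

    def test_full_length_segment_fraction_one(self):
        covered, fraction = consensus_coverage([hit(0, 900, 1, 900)], 900)
        assert fraction == 1.0

    def test_empty_segments_zero(self):
        assert consensus_coverage([], 900) == ((), 0.0)

    def test_order_independent(self, rng):
        segs = [hit(i * 500, i * 500 + 200,
                    int(s), int(s) + 199, cons_length=2000)
                for i, s in enumerate(rng.integers(1, 1800, size=6))]
        forward = consensus_coverage(segs, 2000)
        shuffled = consensus_coverage(list(reversed(segs)), 2000)
        assert forward == shuffled

    @pytest.mark.parametrize("fraction,expected", [(0.96, True), (0.95, False), (1.0, True)])
    def test_full_length_strict_boundary(self, fraction, expected):
        n = int(round(fraction * 1000))
        (contig,) = assemble_contigs([hit(0, n, 1, n, cons_length=1000)], 1000)
        assert contig.coverage_fraction == pytest.approx(fraction)
        assert classify_full_length(contig) is expected


class TestLtrFlanks:
    def contig(self):
        (c,) = assemble_contigs([hit(5000, 6000, 1, 900, cons_length=1000)], 1000)
        return c

    def ltr(self, start, end):
        return hit(start, end, 1, end - start, element="LTR_EL", cons_length=400)

    def test_flanked_within_gap(self):
        contigs = find_ltr_flanked(
            [self.contig()], [self.ltr(4610, 4960), self.ltr(6010, 6360)])
        assert contigs[0].ltr_flanked

    def test_gap_51_not_flanked(self):
        contigs = find_ltr_flanked(
            [self.contig()], [self.ltr(4599, 4949), self.ltr(6010, 6360)])
        assert not contigs[0].ltr_flanked

    def test_short_ltr_ignored(self):
        short_up = hit(4760, 4960, 1, 200, element="LTR_EL", cons_length=400)
        contigs = find_ltr_flanked(
            [self.contig()], [short_up, self.ltr(6010, 6360)])
        assert not contigs[0].ltr_flanked

    def test_one_side_only_not_flanked(self):
        contigs = find_ltr_flanked([self.contig()], [self.ltr(4610, 4960)])
        assert not contigs[0].ltr_flanked

    def test_no_ltr_hits(self):
        contigs = find_ltr_flanked([self.contig()], [])
        assert not contigs[0].ltr_flanked


class TestDeletions:
    def contig_with_coverage(self, intervals, cons_length=1000):
        segs = []
        pos = 0
        for s, e in intervals:
            length = e - s + 1
            segs.append(hit(pos, pos + length, s, e, cons_length=cons_length))
            pos += length
        (c,) = assemble_contigs(segs, cons_length)
        return c

    def test_full_coverage_no_deletions(self):
        c = self.contig_with_coverage([(1, 1000)])
        assert detect_deletions(c) == []

    def test_internal_deletion_reported(self):
        c = self.contig_with_coverage([(1, 398), (871, 1000)])
        (d,) = detect_deletions(c)
        assert (d.cons_start, d.cons_end, d.terminal) == (399, 870, False)

    def test_terminal_truncation_flagged(self):
        c = self.contig_with_coverage([(200, 1000)])
        (d,) = detect_deletions(c)
        assert (d.cons_start, d.cons_end, d.terminal) == (1, 199, True)

    def test_short_gaps_ignored(self):
        c = self.contig_with_coverage([(1, 400), (440, 1000)])  # 39 nt gap
        assert detect_deletions(c) == []

    def test_cluster_fraction_over_all_contigs(self):
        deletions = [Deletion("c1", 399, 870, False), Deletion("c4", 399, 870, False)]
        (cluster,) = cluster_recurrent_deletions(deletions, n_total_contigs=6)
        assert (cluster.cons_start, cluster.cons_end) == (399, 870)
        assert cluster.n_contigs == 2
        assert cluster.fraction == pytest.approx(1 / 3)

    def test_tolerance_boundary(self):
        near = [Deletion("c1", 399, 870, False), Deletion("c2", 399, 880, False)]
        assert len(cluster_recurrent_deletions(near, 6)) == 1
        params5 = Parameters(deletion_cluster_tolerance=5)
        assert len(cluster_recurrent_deletions(near, 6, params5)) == 2

    def test_terminal_gaps_excluded_from_clustering(self):
        deletions = [Deletion("c1", 1, 199, True), Deletion("c2", 1, 199, True)]
        assert cluster_recurrent_deletions(deletions, 6) == []

    def test_no_internal_deletions_empty(self):
        assert cluster_recurrent_deletions([], 6) == []


class TestOrf:
    def contig(self, intervals, cons_length=2000):
        return TestDeletions().contig_with_coverage(intervals, cons_length)

    def test_mostly_covered_orf_intact(self):
        c = self.contig([(1, 950), (1001, 2000)])
        assert orf_intactness(c, (1, 1000)) is True  # 950/1000 covered

    def test_fully_deleted_orf(self):
        c = self.contig([(1101, 2000)])
        assert orf_intactness(c, (1, 1000)) is False

    def test_exactly_ninety_percent_fails_strict(self):
        c = self.contig([(1, 900), (1501, 2000)])
        assert orf_intactness(c, (1, 1000)) is False

    def test_orf_outside_consensus_rejected(self):
        c = self.contig([(1, 2000)])
        with pytest.raises(ValueError):
            orf_intactness(c, (0, 100))
        with pytest.raises(ValueError):
            orf_intactness(c, (1, 3000))

    def test_monotone_in_added_coverage(self):
        partial = self.contig([(1, 895)])
        more = self.contig([(1, 895), (896, 1000)])
        assert not orf_intactness(partial, (1, 1000))
        assert orf_intactness(more, (1, 1000))


class TestProbeMatching:
    def contigs(self):
        hits = [hit(1000, 2000, 1, 900, cons_length=1000),
                hit(9000, 10000, 1, 900, cons_length=1000)]
        a, b = assemble_contigs(hits, 1000)
        return [a, b]

    def aln(self, start):
        return GenomicAlignment("chr1", start, start + 50, "+", 50, 50)

    def test_classification_matrix(self):
        contig_a, contig_b = self.contigs()
        placements = {
            "up1": [self.aln(1200)],
            "up2": [self.aln(1400), self.aln(9200)],
            "un1": [self.aln(9500)],
        }
        classes = match_probes_to_contigs(
            placements, [contig_a, contig_b], {"up1", "up2"}, {"un1"})
        by_id = {c.contig_id: c.probe_class for c in classes}
        assert by_id[contig_a.contig_id] == "only_upregulated"
        assert by_id[contig_b.contig_id] == "both"
        counts = probe_class_counts(classes)
        assert counts["only_upregulated"] == 1 and counts["both"] == 1

    def test_probe_length_padding(self):
        (contig,) = [self.contigs()[0]]
        just_outside = {"up1": [self.aln(2000)]}  # within one probe length
        far_outside = {"up1": [self.aln(2001)]}
        near = match_probes_to_contigs(just_outside, [contig], {"up1"}, set())
        far = match_probes_to_contigs(far_outside, [contig], {"up1"}, set())
        assert near[0].probe_class == "only_upregulated"
        assert far[0].probe_class == "neither"

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="both sets"):
            match_probes_to_contigs({}, [], {"p"}, {"p"})

    def test_planted_truth_classification(self, toy_dataset, toy_de, toy_genome):
        """On the simulated genome, spiked-element contigs match only the
        upregulated probes and background contigs match none."""
        from retroarray.annotate import align_probe

        params = Parameters()
        element = "simERVK-A-int"
        hits = [r for r in toy_dataset.truth.records if r.element == element]
        contigs = assemble_contigs(hits, hits[0].cons_length, params)
        up = set(toy_de.index[toy_de["call"] == "up"])
        unaffected = set(toy_de.index[toy_de["call"] == "unchanged"])
        probes = {p.probe_id: p for p in toy_dataset.probes}
        placements = {
            pid: align_probe(probes[pid], toy_genome, params.max_mismatches)
            for pid in list(up)[:20]
        }
        classes = match_probes_to_contigs(placements, contigs, up, set())
        assert all(c.probe_class in ("only_upregulated", "neither") for c in classes)
        assert any(c.probe_class == "only_upregulated" for c in classes)
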