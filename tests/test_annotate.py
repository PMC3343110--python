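import numpy as np
import pytest
from oracles import brute_force_alignments, revcomp

import retroarray.io as raio
from retroarray.annotate import (
    Genome,
    PrimerPair,
    align_probe,
    annotate_platform,
    annotation_summary,
    classify_probe,
    count_genomic_matches,
    in_silico_pcr,
    top_hit,
)
from retroarray.model import (
    GenomicAlignment,
    Parameters,
    Probe,
    RepeatAnnotationRecord,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng, seq, n_changes):
    seq = list(seq)
    for i in rng.choice(len(seq), size=n_changes, replace=False):
        seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(seq)


@pytest.fixture(scope="module")
def small_genome():
    rng = np.random.default_rng(7)
    return Genome({"chr1": random_seq(rng, 10_000), "chr2": random_seq(rng, 5_000)})


class TestAlignProbe:
    def test_exact_self_match(self, small_genome):
        probe = Probe("p", small_genome.fetch("chr1", 400, 450))
        (aln,) = align_probe(probe, small_genome, max_mismatches=2)
        assert (aln.chrom, aln.start, aln.end, aln.strand) == ("chr1", 400, 450, "+")
        assert aln.identity == 1.0

    def test_reverse_complement_hits_minus_strand(self, small_genome):
        probe = Probe("p", revcomp(small_genome.fetch("chr2", 100, 150)))
        (aln,) = align_probe(probe, small_genome, max_mismatches=2)
        assert (aln.chrom, aln.start, aln.strand) == ("chr2", 100, "-")

    def test_three_mismatches_not_reported_at_cutoff_two(self, small_genome, rng):
        seq = mutate(rng, small_genome.fetch("chr1", 2_000, 2_050), 3)
        probe = Probe("p", seq)
        assert align_probe(probe, small_genome, max_mismatches=2) == []
        # the placement is recovered once the cutoff admits it
        hits = align_probe(probe, small_genome, max_mismatches=3)
        assert any(a.start == 2_000 and a.matches == 47 for a in hits)

    def test_n_in_probe_never_matches(self, small_genome):
        seq = small_genome.fetch("chr1", 300, 350)
        probe = Probe("p", "NNN" + seq[3:])
        assert align_probe(probe, small_genome, max_mismatches=2) == []
        hits = align_probe(probe, small_genome, max_mismatches=3)
        assert any(a.start == 300 and a.matches == 47 for a in hits)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError, match="empty genome"):
            Genome({})

    def test_sorted_by_matches_then_position(self, rng):
        core = random_seq(rng, 50)
        genome = Genome({
            "chr1": random_seq(rng, 200) + mutate(rng, core, 1) + random_seq(rng, 200)
            + core + random_seq(rng, 100),
        })
        probe = Probe("p", core)
        hits = align_probe(probe, genome, 2)
        assert [a.matches for a in hits] == sorted(
            (a.matches for a in hits), reverse=True)
        assert hits[0].matches == 50

    def test_agrees_with_exhaustive_hamming_scan(self, rng):
        """Completeness oracle: seeded aligner == brute-force scan of every
        offset on both strands."""
        core = random_seq(rng, 600)
        chunks = [random_seq(rng, 800)]
        for _ in range(4):  # plant mutated copies to create near-matches
            chunks.append(mutate(rng, core, int(rng.integers(0, 12))))
            chunks.append(random_seq(rng, 500))
        genome = {"chr1": "".join(chunks), "chr2": random_seq(rng, 2_000)}
        g = Genome(genome)
        for _ in range(30):
            offset = int(rng.integers(0, len(core) - 50))
            seq = core[offset:offset + 50]
            seq = mutate(rng, seq, int(rng.integers(0, 3)))
            if rng.random() < 0.5:
                seq = revcomp(seq)
            probe = Probe("p", seq)
            got = {
                (a.chrom, a.start, a.strand, a.matches)
                for a in align_probe(probe, g, 2)
            }
            assert got == brute_force_alignments(seq, genome, 2)


class TestTopHit:
    def aln(self, chrom="chr1", start=0, strand="+", matches=50):
        return GenomicAlignment(chrom, start, start + 50, strand, matches, 50)

    def test_single_perfect_hit(self):
        best, n = top_hit([self.aln()], min_matches=48)
        assert best.matches == 50 and n == 1

    def test_tie_broken_lexicographically(self):
        a = self.aln("chr2", 100, "+", 49)
        b = self.aln("chr1", 500, "-", 49)
        best, n = top_hit([a, b], min_matches=48)
        assert best is b and n == 2

    def test_below_cutoff_is_absent(self):
        best, n = top_hit([self.aln(matches=47)], min_matches=48)
        assert best is None and n == 0


class TestClassifyProbe:
    params = Parameters()

    def repeat(self, start, end, strand="+"):
        return RepeatAnnotationRecord(
            "chr1", start, end, strand, "MMERVK10C-int", "ERVK", "LTR",
            1, end - start, 8000)

    def hit(self, start=1000, strand="+"):
        return GenomicAlignment("chr1", start, start + 50, strand, 50, 50)

    def probe(self):
        return Probe("p", "A" * 50)

    def test_sense_repeat_probe(self):
        # hit overlaps the repeat by 48 nt, strands equal
        ann = classify_probe(
            self.probe(), self.hit(1000), [self.repeat(900, 1048)], self.params)
        assert ann.is_repeat and ann.detects_sense
        assert (ann.element, ann.family, ann.repeat_class) == (
            "MMERVK10C-int", "ERVK", "LTR")
        assert ann.overlap_nt == 48

    def test_overlap_47_not_repeat(self):
        ann = classify_probe(
            self.probe(), self.hit(1000), [self.repeat(900, 1047)], self.params)
        assert not ann.is_repeat

    def test_no_overlap_not_repeat(self):
        ann = classify_probe(
            self.probe(), self.hit(1000), [self.repeat(2000, 2500)], self.params)
        assert not ann.is_repeat

    def test_opposite_strand_hit_is_antisense(self):
        ann = classify_probe(
            self.probe(), self.hit(1000, "-"), [self.repeat(900, 1100)], self.params)
        assert ann.is_repeat and not ann.detects_sense

    def test_same_sense_chemistry_flips_orientation(self):
        ann = classify_probe(
            self.probe(), self.hit(1000, "-"), [self.repeat(900, 1100)],
            self.params, chemistry="probe_same_sense_as_transcript")
        assert ann.detects_sense

    def test_largest_overlap_wins(self):
        small = self.repeat(1000, 1049)
        big = RepeatAnnotationRecord(
            "chr1", 990, 1100, "+", "IAPEz-int", "ERVK", "LTR", 1, 110, 7000)
        ann = classify_probe(self.probe(), self.hit(1000), [small, big], self.params)
        assert ann.element == "IAPEz-int"

    def test_absent_hit_gives_nonrepeat(self):
        ann = classify_probe(self.probe(), None, [], self.params)
        assert not ann.is_repeat and ann.hit_count == 0


class TestAnnotatePlatform:
    def test_reproduces_planted_truth(self, toy_dataset, toy_annotations):
        truth = toy_dataset.probe_labels
        for ann in toy_annotations:
            expected = truth.loc[ann.probe_id]
            assert ann.is_repeat == expected["is_repeat"]
            if ann.is_repeat:
                assert ann.element == expected["element"]
                assert ann.detects_sense == expected["detects_sense"]

    def test_summary_partitions_repeat_probes(self, toy_annotations):
        totals, per_class = annotation_summary(toy_annotations)
        assert (
            totals["repeat_probes_complementary"]
            + totals["repeat_probes_noncomplementary"]
            == totals["repeat_probes"]
        )
        assert totals["repeat_probes"] <= totals["total_probes"]
        assert per_class["n_probes"].sum() == totals["repeat_probes_complementary"]

    def test_duplicate_probe_id_rejected(self, small_genome):
        probes = [Probe("dup", "A" * 50), Probe("dup", "C" * 50)]
        with pytest.raises(ValueError, match="duplicate"):
            annotate_platform(probes, small_genome, [], Parameters())

    def test_strand_symmetry_flips_sense(self, toy_dataset, toy_genome, toy_annotations):
        """Reverse-complementing a probe flips detects_sense, keeps the locus."""
        params = Parameters()
        originals = [a for a in toy_annotations if a.is_repeat][:5]
        by_id = {p.probe_id: p for p in toy_dataset.probes}
        for ann in originals:
            probe = by_id[ann.probe_id]
            flipped = Probe(probe.probe_id, revcomp(probe.sequence))
            alns = align_probe(flipped, toy_genome, params.max_mismatches)
            hit, n = top_hit(alns, flipped.length - params.max_mismatches)
            new = classify_probe(flipped, hit, toy_dataset.truth.records, params,
                                 hit_count=n)
            assert new.is_repeat and new.element == ann.element
            assert new.detects_sense != ann.detects_sense
            assert (new.top_hit.chrom, new.top_hit.start) == (
                ann.top_hit.chrom, ann.top_hit.start)

    def test_annotation_table_deterministic(self, toy_dataset, toy_genome, tmp_path):
        params = Parameters()
        seqs = {p.probe_id: p.sequence for p in toy_dataset.probes}
        contents = []
        for i in range(2):
            anns = annotate_platform(
                toy_dataset.probes[:40], toy_genome, toy_dataset.truth.records, params)
            path = tmp_path / f"annot{i}.tsv"
            raio.write_probe_annotation_table(anns, path, seqs)
            contents.append(path.read_bytes())
        assert contents[0] == contents[1]


class TestMultiLocusAndPcr:
    def test_unique_probe_counts_once(self, small_genome):
        probe = Probe("p", small_genome.fetch("chr1", 7_000, 7_050))
        assert count_genomic_matches(probe, small_genome, 48) == 1

    def test_planted_copies_counted(self, rng):
        core = random_seq(rng, 200)
        parts = [random_seq(rng, 300)]
        for _ in range(5):
            parts.append(mutate(rng, core, 2))
            parts.append(random_seq(rng, 300))
        genome = Genome({"chr1": "".join(parts)})
        # probe from a clean stretch of the consensus core
        probe = Probe("p", core[50:100])
        assert count_genomic_matches(probe, genome, 48) == 5

    def test_absent_probe_counts_zero(self, small_genome, rng):
        probe = Probe("p", random_seq(rng, 50))
        assert count_genomic_matches(probe, small_genome, 48) == 0

    def pcr_genome(self, rng, n_sites=1):
        fwd = random_seq(rng, 20)
        rev = random_seq(rng, 20)
        parts = []
        for _ in range(n_sites):
            parts.append(random_seq(rng, 150))
            parts.append(fwd + random_seq(rng, 160) + revcomp(rev))
        parts.append(random_seq(rng, 150))
        return fwd, rev, Genome({"chr1": "".join(parts)})

    def test_single_site_coordinates(self, rng):
        fwd, rev, genome = self.pcr_genome(rng)
        pair = PrimerPair("pp", fwd, rev, max_amplicon=500)
        (amp,) = in_silico_pcr(pair, genome)
        chrom, start, end, strand = amp
        assert chrom == "chr1" and strand == "+"
        assert end - start == 200
        assert genome.fetch(chrom, start, start + 20) == fwd

    def test_multiple_planted_sites(self, rng):
        fwd, rev, genome = self.pcr_genome(rng, n_sites=7)
        pair = PrimerPair("pp", fwd, rev, max_amplicon=500)
        assert len(in_silico_pcr(pair, genome)) == 7

    def test_same_orientation_yields_nothing(self, rng):
        fwd = random_seq(rng, 20)
        rev = random_seq(rng, 20)
        genome = Genome({"chr1": random_seq(rng, 100) + fwd
                         + random_seq(rng, 160) + rev + random_seq(rng, 100)})
        pair = PrimerPair("pp", fwd, rev, max_amplicon=500)
        assert in_silico_pcr(pair, genome) == []

    def test_amplicon_length_cap(self, rng):
        fwd, rev, genome = self.pcr_genome(rng)
        pair = PrimerPair("pp", fwd, rev, max_amplicon=150)
        assert in_silico_pcr(pair, genome) == []

    def test_primer_pair_invariants(self):
        with pytest.raises(ValueError, match=">=15"):
            PrimerPair("pp", "ACGT", "ACGTACGTACGTACGT", 100)
        with pytest.raises(ValueError, match="max_amplicon"):
            PrimerPair("pp", "ACGTACGTACGTACGT", "ACGTACGTACGTACGT", 30)
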