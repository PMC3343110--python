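"""Probe-to-genome alignment and repeat classification.

Array probes are short (25 or 50 nt) and the identity cut-offs in use
(>=24/25, >=48/50) imply at most 1 or 2 substitutions, so alignment is exact
and ungapped: pigeonhole k-mer seeding with ``k = floor(L / (m + 1))``
guarantees that every placement with at most ``m`` mismatches is found.  A
probe is a repeat probe when its top genomic hit overlaps a repeat-masked
interval by at least the configured minimum (48 nt for 50-mers, 24 nt for
25-mers), and it detects *sense* repeat transcripts when the orientation of
the hit matches the annotated repeat strand (for probes that are
complementary to the transcript, the default chemistry of both supported
platform families).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import (
    GenomicAlignment,
    Parameters,
    Probe,
    RepeatAnnotationRecord,
    RepeatProbeAnnotation,
)

logger = logging.getLogger("retroarray")

CHEMISTRIES = ("probe_complementary_to_transcript", "probe_same_sense_as_transcript")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A qRT-PCR primer pair for in-silico PCR."""

    name: str
    forward: str
    reverse: str
    max_amplicon: int

    def __post_init__(self):
        for primer in (self.forward, self.reverse):
            if len(primer) < 15:
                raise ValueError(f"{self.name}: primers must be >=15 nt")
            if set(primer.upper()) - set("ACGTN"):
                raise ValueError(f"{self.name}: invalid primer bases")
        if self.max_amplicon <= len(self.forward) + len(self.reverse):
            raise ValueError(f"{self.name}: max_amplicon shorter than the primers")


class Genome:
    """In-memory genome with cached k-mer indexes for seeding.

    ``seqs`` maps chromosome name to an uppercase sequence string.
    """

    def __init__(self, seqs: Dict[str, str]):
        if not seqs or all(len(s) == 0 for s in seqs.values()):
            raise ValueError("empty genome")
        self.seqs = {name: s.upper() for name, s in seqs.items()}
        self._arrays = {
            name: np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            for name, s in self.seqs.items()
        }
        self._kmer_index: Dict[int, Dict[str, list]] = {}

    def __len__(self):
        return sum(len(s) for s in self.seqs.values())

    def chrom_length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.seqs[chrom][start:end]

    def kmer_positions(self, k: int) -> Dict[str, list]:
        """kmer -> list of (chrom, offset); Ns never indexed."""
        if k not in self._kmer_index:
            index: Dict[str, list] = {}
            for chrom, seq in self.seqs.items():
                for i in range(len(seq) - k + 1):
                    kmer = seq[i:i + k]
                    if "N" in kmer:
                        continue
                    index.setdefault(kmer, []).append((chrom, i))
            self._kmer_index[k] = index
        return self._kmer_index[k]


def as_genome(genome) -> Genome:
    if isinstance(genome, Genome):
        return genome
    return Genome(dict(genome))


def _count_matches(garr: np.ndarray, parr: np.ndarray, start: int) -> int:
    """Matched positions of a candidate placement; N never counts as a match."""
    window = garr[start:start + parr.size]
    n = ord("N")
    return int(np.count_nonzero((window == parr) & (parr != n) & (window != n)))


def _ungapped_placements(seq: str, genome: Genome, max_mismatches: int):
    """All (chrom, start, strand, matches) placements of ``seq`` (both strands)
    with at most ``max_mismatches`` mismatches.  Complete by pigeonhole
    seeding: with m allowed mismatches, one of the m+1 disjoint seeds of any
    qualifying placement is an exact substring match.
    """
    length = len(seq)
    k = length // (max_mismatches + 1)
    if k < 1:
        raise ValueError("probe shorter than max_mismatches + 1")
    index = genome.kmer_positions(k)
    hits = []
    for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
        parr = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
        seen = set()
        for chunk in range(max_mismatches + 1):
            off = chunk * k
            for chrom, pos in index.get(oriented[off:off + k], ()):
                start = pos - off
                if start < 0 or start + length > genome.chrom_length(chrom):
                    continue
                if (chrom, start) in seen:
                    continue
                seen.add((chrom, start))
                matches = _count_matches(genome._arrays[chrom], parr, start)
                if matches >= length - max_mismatches:
                    hits.append((chrom, start, strand, matches))
    return hits


def align_probe(probe: Probe, genome, max_mismatches: int) -> List[GenomicAlignment]:
    """Every ungapped placement of the probe with <= max_mismatches mismatches.

    Results are sorted by descending matches then (chrom, start, strand).
    A position where either the probe or the genome has N never matches.
    """
    if probe.length < 20:
        raise ValueError(f"probe {probe.probe_id}: length must be >=20 nt")
    genome = as_genome(genome)
    hits = _ungapped_placements(probe.sequence, genome, max_mismatches)
    alignments = [
        GenomicAlignment(
            chrom=c, start=s, end=s + probe.length, strand=st,
            matches=m, probe_length=probe.length,
        )
        for c, s, st, m in hits
    ]
    alignments.sort(key=lambda a: (-a.matches, a.chrom, a.start, a.strand))
    return alignments


def top_hit(
    alignments: List[GenomicAlignment], min_matches: int
) -> Tuple[Optional[GenomicAlignment], int]:
    """Best qualifying alignment and the number of qualifying alignments.

    Ties on match count are broken lexicographically by (chrom, start,
    strand), which the sort order of :func:`align_probe` already provides.
    """
    qualifying = [a for a in alignments if a.matches >= min_matches]
    if not qualifying:
        return None, 0
    best = min(qualifying, key=lambda a: (-a.matches, a.chrom, a.start, a.strand))
    return best, len(qualifying)


class RepeatIndex:
    """Per-chromosome interval lookup over sorted annotation records."""

    def __init__(self, records: Iterable[RepeatAnnotationRecord]):
        self.by_chrom: Dict[str, list] = {}
        for rec in sorted(records, key=lambda r: (r.chrom, r.start, r.end)):
            self.by_chrom.setdefault(rec.chrom, []).append(rec)
        self._starts = {
            c: np.array([r.start for r in recs])
            for c, recs in self.by_chrom.items()
        }
        self._ends = {
            c: np.array([r.end for r in recs]) for c, recs in self.by_chrom.items()
        }

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        recs = self.by_chrom.get(chrom)
        if not recs:
            return []
        mask = (self._starts[chrom] < end) & (self._ends[chrom] > start)
        return [recs[i] for i in np.nonzero(mask)[0]]


def classify_probe(
    probe: Probe,
    hit: Optional[GenomicAlignment],
    repeats,
    params: Parameters,
    chemistry: str = "probe_complementary_to_transcript",
    hit_count: int = 1,
) -> RepeatProbeAnnotation:
    """Classify a probe from its top hit against the repeat annotation.

    The probe is a repeat probe iff some repeat interval overlaps the hit by
    at least ``params.min_overlap_nt``; the record with the largest overlap
    wins (ties -> first by genomic position).
    """
    if chemistry not in CHEMISTRIES:
        raise ValueError(f"unknown chemistry {chemistry!r}")
    if hit is None:
        return RepeatProbeAnnotation(probe.probe_id, is_repeat=False, hit_count=0)
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    best_rec, best_overlap = None, 0
    for rec in index.overlapping(hit.chrom, hit.start, hit.end):
        overlap = min(rec.end, hit.end) - max(rec.start, hit.start)
        if overlap > best_overlap:  # ties keep the first by position
            best_rec, best_overlap = rec, overlap
    if best_rec is None or best_overlap < params.min_overlap_nt:
        return RepeatProbeAnnotation(
            probe.probe_id, is_repeat=False, hit_count=hit_count, top_hit=hit,
        )
    same_strand = hit.strand == best_rec.strand
    if chemistry == "probe_complementary_to_transcript":
        detects_sense = same_strand
    else:
        detects_sense = not same_strand
    return RepeatProbeAnnotation(
        probe_id=probe.probe_id,
        is_repeat=True,
        detects_sense=detects_sense,
        element=best_rec.element,
        family=best_rec.family,
        repeat_class=best_rec.repeat_class,
        overlap_nt=best_overlap,
        hit_count=hit_count,
        top_hit=hit,
    )


def annotate_platform(
    probes: List[Probe],
    genome,
    repeats,
    params: Parameters,
    chemistry: str = "probe_complementary_to_transcript",
) -> List[RepeatProbeAnnotation]:
    """Annotate every probe of a platform table; one annotation per probe."""
    ids = [p.probe_id for p in probes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate probe ids: {dupes[:5]}")
    genome = as_genome(genome)
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    annotations = []
    for probe in probes:
        alignments = align_probe(probe, genome, params.max_mismatches)
        hit, n = top_hit(alignments, probe.length - params.max_mismatches)
        annotations.append(
            classify_probe(probe, hit, index, params, chemistry, hit_count=n)
        )
    summary, _ = annotation_summary(annotations)
    logger.info(
        "annotated %d probes: %d complementary repeat probes, "
        "%d non-complementary",
        summary["total_probes"],
        summary["repeat_probes_complementary"],
        summary["repeat_probes_noncomplementary"],
    )
    return annotations


def annotation_summary(
    annotations: List[RepeatProbeAnnotation],
) -> Tuple[dict, pd.DataFrame]:
    """Platform-level summary counts.

    Returns (totals dict, per-class table).  The totals split repeat probes
    into complementary (sense-detecting) and non-complementary; the per-class
    table counts distinct elements and probes among complementary repeat
    probes.
    """
    repeat = [a for a in annotations if a.is_repeat]
    sense = [a for a in repeat if a.detects_sense]
    totals = {
        "total_probes": len(annotations),
        "repeat_probes": len(repeat),
        "repeat_probes_complementary": len(sense),
        "repeat_probes_noncomplementary": len(repeat) - len(sense),
    }
    rows = {}
    for a in sense:
        cls = rows.setdefault(a.repeat_class, {"elements": set(), "probes": 0})
        cls["elements"].add(a.element)
        cls["probes"] += 1
    per_class = pd.DataFrame(
        [
            {"class": c, "n_elements": len(v["elements"]), "n_probes": v["probes"]}
            for c, v in sorted(rows.items())
        ],
        columns=["class", "n_elements", "n_probes"],
    )
    return totals, per_class


def count_genomic_matches(probe: Probe, genome, min_matches: int) -> int:
    """Number of distinct genomic placements with >= min_matches matches."""
    alignments = align_probe(probe, genome, probe.length - min_matches)
    return sum(1 for a in alignments if a.matches >= min_matches)


def in_silico_pcr(
    pair: PrimerPair, genome, max_mismatches_per_primer: int = 0
) -> List[Tuple[str, int, int, str]]:
    """Predicted amplicons (chrom, start, end, strand) for a primer pair.

    An amplicon requires the forward primer on one strand and the reverse
    primer on the opposite strand with 3' ends facing inward, non-overlapping
    primer sites, and a product no longer than ``pair.max_amplicon``.
    """
    genome = as_genome(genome)
    fwd = _ungapped_placements(pair.forward.upper(), genome, max_mismatches_per_primer)
    rev = _ungapped_placements(pair.reverse.upper(), genome, max_mismatches_per_primer)
    flen, rlen = len(pair.forward), len(pair.reverse)
    amplicons = []
    # plus-strand products: forward on '+', reverse on '-' downstream
    plus_f = [(c, s) for c, s, st, _ in fwd if st == "+"]
    minus_r = [(c, s) for c, s, st, _ in rev if st == "-"]
    for fc, fs in plus_f:
        for rc, rs in minus_r:
            if rc == fc and rs >= fs + flen:
                length = rs + rlen - fs
                if length <= pair.max_amplicon:
                    amplicons.append((fc, fs, rs + rlen, "+"))
    # minus-strand products: roles mirrored
    minus_f = [(c, s) for c, s, st, _ in fwd if st == "-"]
    plus_r = [(c, s) for c, s, st, _ in rev if st == "+"]
    for fc, fs in minus_f:
        for rc, rs in plus_r:
            if rc == fc and fs >= rs + rlen:
                length = fs + flen - rs
                if length <= pair.max_amplicon:
                    amplicons.append((fc, rs, fs + flen, "-"))
    amplicons.sort()
    return amplicons
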