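"""Assembly of per-element repeat genomic hits into contigs.

RepeatMasker fragments one genomic copy of an element into several hits
(deletions, nested insertions and alignment breaks all split hits), so
same-element hits that are adjacent in the genome, on the same strand,
consensus-collinear and separated by less than one consensus length are
merged into a contig representing a single putative genomic copy.  The
contig's consensus-coverage profile then supports full-length calls, ORF
intactness, recurrent-deletion clustering and LTR-flank detection.

Consensus coordinates are 1-based inclusive; interval lengths count both
endpoints, so one hit spanning the whole consensus gives coverage 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .model import GenomicAlignment, Parameters, RepeatAnnotationRecord

logger = logging.getLogger("retroarray")

PROBE_CLASSES = ("only_upregulated", "only_unaffected", "both", "neither")


@dataclass(frozen=True)
class RepeatContig:
    """An assembled multi-hit repeat locus."""

    contig_id: str
    chrom: str
    span_start: int  # 0-based half-open genomic span
    span_end: int
    strand: str
    element: str
    segments: Tuple[RepeatAnnotationRecord, ...]
    cons_length: int
    covered: Tuple[Tuple[int, int], ...]  # merged 1-based inclusive intervals
    coverage_fraction: float
    ltr_flanked: bool = False

    @property
    def full_length(self) -> bool:
        # strict: "contains more than 95% of the reference" with the default
        return self.coverage_fraction > 0.95


@dataclass(frozen=True)
class Deletion:
    """A consensus interval absent from one contig."""

    contig_id: str
    cons_start: int  # 1-based inclusive
    cons_end: int
    terminal: bool  # touches a consensus end (truncation, not deletion)

    @property
    def length(self) -> int:
        return self.cons_end - self.cons_start + 1


@dataclass(frozen=True)
class DeletionCluster:
    """A recurrent deletion: shared breakpoints across contigs."""

    cons_start: int
    cons_end: int
    n_contigs: int
    fraction: float
    contig_ids: Tuple[str, ...]


@dataclass(frozen=True)
class ContigProbeClass:
    contig_id: str
    probe_class: str

    def __post_init__(self):
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class {self.probe_class!r}")


def _merge_intervals(intervals: Iterable[Tuple[int, int]]) -> Tuple[Tuple[int, int], ...]:
    """Union of 1-based inclusive intervals (book-ended intervals merge)."""
    ivs = sorted(intervals)
    merged: List[List[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def consensus_coverage(
    segments: Sequence[RepeatAnnotationRecord], cons_length: int
) -> Tuple[Tuple[Tuple[int, int], ...], float]:
    """Union of segment consensus intervals and its fraction of the consensus."""
    if not segments:
        return (), 0.0
    covered = _merge_intervals((s.cons_start, s.cons_end) for s in segments)
    total = sum(e - s + 1 for s, e in covered)
    return covered, total / cons_length


def _build_contig(
    element: str, idx: int, segments: List[RepeatAnnotationRecord], cons_length: int
) -> RepeatContig:
    covered, fraction = consensus_coverage(segments, cons_length)
    return RepeatContig(
        contig_id=f"{element}_c{idx}",
        chrom=segments[0].chrom,
        span_start=min(s.start for s in segments),
        span_end=max(s.end for s in segments),
        strand=segments[0].strand,
        element=element,
        segments=tuple(segments),
        cons_length=cons_length,
        covered=covered,
        coverage_fraction=fraction,
    )


def assemble_contigs(
    hits: Sequence[RepeatAnnotationRecord],
    cons_length: int,
    params: Optional[Parameters] = None,
) -> List[RepeatContig]:
    """Greedy genomic-order assembly of one element's hits into contigs.

    A hit extends the current contig iff it is on the same chromosome and
    strand, the genomic gap to the contig is strictly less than the consensus
    length, and its consensus interval is collinear with the contig's running
    consensus position (ascending on '+', descending on '-'), allowing a
    small consensus overlap (RepeatMasker fragments commonly overlap by a few
    bases).  Every hit lands in exactly one contig.
    """
    params = params or Parameters()
    tol = params.consensus_overlap_tolerance
    hits = sorted(hits, key=lambda r: (r.chrom, r.start, r.end))
    if not hits:
        return []
    elements = {h.element for h in hits}
    if len(elements) > 1:
        raise ValueError(f"mixed elements in hit list: {sorted(elements)}")
    element = hits[0].element
    contigs: List[RepeatContig] = []
    current: List[RepeatAnnotationRecord] = [hits[0]]
    # running consensus frontier: max cons_end on '+', min cons_start on '-'
    for nxt in hits[1:]:
        prev_strand = current[0].strand
        span_end = max(s.end for s in current)
        gap = nxt.start - span_end
        same = nxt.chrom == current[0].chrom and nxt.strand == prev_strand
        close = gap < cons_length
        if prev_strand == "+":
            frontier = max(s.cons_end for s in current)
            collinear = nxt.cons_start >= frontier - tol
        else:
            frontier = min(s.cons_start for s in current)
            collinear = nxt.cons_end <= frontier + tol
        if same and close and collinear:
            current.append(nxt)
        else:
            contigs.append(_build_contig(element, len(contigs) + 1, current, cons_length))
            current = [nxt]
    contigs.append(_build_contig(element, len(contigs) + 1, current, cons_length))
    return contigs


def find_ltr_flanked(
    contigs: Sequence[RepeatContig],
    ltr_hits: Sequence[RepeatAnnotationRecord],
    params: Optional[Parameters] = None,
) -> List[RepeatContig]:
    """Flag contigs with a qualifying LTR within the flank gap of both ends.

    LTR hits shorter than ``params.ltr_min_length`` are ignored; the gap
    between LTR and contig end must be between 0 and
    ``params.ltr_flank_max_gap`` inclusive.  LTR orientation is not required
    to match the contig strand.
    """
    params = params or Parameters()
    good = [h for h in ltr_hits if h.genomic_length >= params.ltr_min_length]
    by_chrom: Dict[str, List[RepeatAnnotationRecord]] = {}
    for h in good:
        by_chrom.setdefault(h.chrom, []).append(h)
    out = []
    for c in contigs:
        near = by_chrom.get(c.chrom, ())
        upstream = any(0 <= c.span_start - h.end <= params.ltr_flank_max_gap for h in near)
        downstream = any(0 <= h.start - c.span_end <= params.ltr_flank_max_gap for h in near)
        out.append(replace(c, ltr_flanked=upstream and downstream))
    return out


def classify_full_length(contig: RepeatContig, params: Optional[Parameters] = None) -> bool:
    """True iff coverage exceeds the full-length fraction (strict >)."""
    params = params or Parameters()
    return contig.coverage_fraction > params.full_length_fraction


def detect_deletions(
    contig: RepeatContig, params: Optional[Parameters] = None
) -> List[Deletion]:
    """Consensus gaps of at least ``min_deletion_nt``.

    Gaps touching either consensus end are flagged terminal (truncations);
    internal gaps are candidate deletions.
    """
    params = params or Parameters()
    gaps: List[Deletion] = []
    pos = 1
    for s, e in contig.covered:
        if s > pos:
            gaps.append(Deletion(contig.contig_id, pos, s - 1, terminal=pos == 1))
        pos = max(pos, e + 1)
    if pos <= contig.cons_length:
        gaps.append(Deletion(contig.contig_id, pos, contig.cons_length, terminal=True))
    return [g for g in gaps if g.length >= params.min_deletion_nt]


def cluster_recurrent_deletions(
    deletions: Sequence[Deletion],
    n_total_contigs: int,
    params: Optional[Parameters] = None,
) -> List[DeletionCluster]:
    """Single-linkage clustering of internal deletions on shared breakpoints.

    Two deletions link when both their start and end breakpoints differ by at
    most ``deletion_cluster_tolerance``.  The cluster interval is the median
    breakpoint pair; the fraction is over all contigs analysed.
    """
    params = params or Parameters()
    tol = params.deletion_cluster_tolerance
    internal = [d for d in deletions if not d.terminal]
    n = len(internal)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = internal[i], internal[j]
            if abs(a.cons_start - b.cons_start) <= tol and abs(a.cons_end - b.cons_end) <= tol:
                parent[find(i)] = find(j)
    groups: Dict[int, List[Deletion]] = {}
    for i, d in enumerate(internal):
        groups.setdefault(find(i), []).append(d)
    clusters = []
    for members in groups.values():
        contig_ids = tuple(sorted({d.contig_id for d in members}))
        clusters.append(
            DeletionCluster(
                cons_start=int(np.median([d.cons_start for d in members])),
                cons_end=int(np.median([d.cons_end for d in members])),
                n_contigs=len(contig_ids),
                fraction=len(contig_ids) / n_total_contigs,
                contig_ids=contig_ids,
            )
        )
    clusters.sort(key=lambda c: (c.cons_start, c.cons_end))
    return clusters


def orf_intactness(
    contig: RepeatContig,
    orf: Tuple[int, int],
    params: Optional[Parameters] = None,
) -> bool:
    """True iff the covered share of the ORF interval exceeds the threshold.

    ``orf`` is a 1-based inclusive consensus interval.
    """
    params = params or Parameters()
    start, end = orf
    if not (1 <= start <= end <= contig.cons_length):
        raise ValueError(f"ORF {orf} outside consensus [1, {contig.cons_length}]")
    orf_len = end - start + 1
    covered = sum(
        max(0, min(e, end) - max(s, start) + 1) for s, e in contig.covered
    )
    return covered / orf_len > params.orf_intact_fraction


def match_probes_to_contigs(
    placements: Dict[str, List[GenomicAlignment]],
    contigs: Sequence[RepeatContig],
    up_set: Set[str],
    unaffected_set: Set[str],
) -> List[ContigProbeClass]:
    """Classify contigs by which responsive probe sets map into them.

    A probe matches a contig when any of its qualifying placements lies fully
    within the contig span padded by one probe length on each side (repeat
    probes hit many near-identical loci, so all placements count, not just
    the top hit).
    """
    overlap = up_set & unaffected_set
    if overlap:
        raise ValueError(f"probes in both sets: {sorted(overlap)[:5]}")
    out = []
    for c in contigs:
        hit_up = hit_un = False
        for pid, alns in placements.items():
            if pid not in up_set and pid not in unaffected_set:
                continue
            for a in alns:
                pad = a.probe_length
                if (
                    a.chrom == c.chrom
                    and a.start >= c.span_start - pad
                    and a.end <= c.span_end + pad
                ):
                    if pid in up_set:
                        hit_up = True
                    else:
                        hit_un = True
                    break
        if hit_up and hit_un:
            cls = "both"
        elif hit_up:
            cls = "only_upregulated"
        elif hit_un:
            cls = "only_unaffected"
        else:
            cls = "neither"
        out.append(ContigProbeClass(c.contig_id, cls))
    return out


def probe_class_counts(classes: Sequence[ContigProbeClass]) -> Dict[str, int]:
    counts = {c: 0 for c in PROBE_CLASSES}
    for c in classes:
        counts[c.probe_class] += 1
    return counts
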