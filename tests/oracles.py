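"""Independent reference implementations used only to check the package.

Everything here is deliberately written from the definitions (exhaustive
scans, enumerations, quadrature, step-by-step formulas) rather than sharing
code with the implementation under test.
"""

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.stats import rankdata

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq):
    return seq.translate(_COMPLEMENT)[::-1]


def brute_force_alignments(seq, genome, max_mismatches):
    """Hamming scan at every offset on both strands; N never matches.

    Returns a set of (chrom, start, strand, matches).
    """
    length = len(seq)
    n_code = ord("N")
    hits = set()
    for chrom, g in genome.items():
        garr = np.frombuffer(g.encode("ascii"), dtype=np.uint8)
        n_pos = len(g) - length + 1
        if n_pos <= 0:
            continue
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            parr = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
            mism = np.zeros(n_pos, dtype=np.int32)
            for j in range(length):
                window = garr[j:j + n_pos]
                mism += ((window != parr[j]) | (parr[j] == n_code) | (window == n_code))
            for pos in np.nonzero(mism <= max_mismatches)[0]:
                hits.add((chrom, int(pos), strand, length - int(mism[pos])))
    return hits


def step_up_bh(p):
    """BH adjustment written directly from the step-up definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, min(1.0, m * p[i] / rank))
        adjusted[i] = running_min
    return adjusted


def enumerate_ranksum_p(a, b):
    """Exact two-sided rank-sum p by enumerating every subset assignment."""
    pooled = list(a) + list(b)
    ranks = rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    sums = [sum(combo) for combo in itertools.combinations(ranks, n_a)]
    total = len(sums)
    lower = sum(1 for s in sums if s <= w_obs + 1e-9) / total
    upper = sum(1 for s in sums if s >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(lower, upper))


def normexp_posterior_mean_quadrature(x, bg_mean, bg_sd, signal_rate):
    """E[S | X=x] for X = B + S by direct numerical integration."""

    def joint(s):
        return signal_rate * math.exp(-signal_rate * s) * (
            math.exp(-0.5 * ((x - s - bg_mean) / bg_sd) ** 2)
        )

    upper = max(x - bg_mean, 0) + 20 * bg_sd + 20 / signal_rate
    peak = min(max(x - bg_mean, 1e-6), upper)
    num, _ = integrate.quad(lambda s: s * joint(s), 0, upper, points=[peak], limit=400)
    den, _ = integrate.quad(joint, 0, upper, points=[peak], limit=400)
    return num / den


def moderated_t_by_hand(log_fc, s2, df, n1, n2, d0, s0_sq):
    """Shrinkage, t and p evaluated value by value from the formulas."""
    from scipy.stats import t as t_dist

    out = []
    for lfc, v in zip(log_fc, s2):
        if math.isinf(d0):
            post = s0_sq
        else:
            post = (d0 * s0_sq + df * v) / (d0 + df)
        se = math.sqrt(post * (1.0 / n1 + 1.0 / n2))
        t = lfc / se
        p = 2.0 * t_dist.sf(abs(t), df + d0)
        out.append((post, t, p))
    return out


def brute_force_contigs(hits, cons_length, overlap_tol=20):
    """Quadratic scan applying the adjacency rules pair by pair.

    Returns a list of lists of hits (each inner list one contig, genomic
    order), built by explicitly testing the next hit against the running
    chain state rather than reusing the package's assembler.
    """
    ordered = sorted(hits, key=lambda r: (r.chrom, r.start, r.end))
    contigs = []
    for hit in ordered:
        placed = False
        if contigs:
            chain = contigs[-1]
            last_chrom = chain[0].chrom
            last_strand = chain[0].strand
            chain_end = max(h.end for h in chain)
            if hit.chrom == last_chrom and hit.strand == last_strand:
                if hit.start - chain_end < cons_length:
                    if last_strand == "+":
                        frontier = max(h.cons_end for h in chain)
                        ok = hit.cons_start >= frontier - overlap_tol
                    else:
                        frontier = min(h.cons_start for h in chain)
                        ok = hit.cons_end <= frontier + overlap_tol
                    if ok:
                        chain.append(hit)
                        placed = True
        if not placed:
            contigs.append([hit])
    return contigs


def random_hit_set(rng, n_hits, cons_length=1000):
    """A random same-element hit list for the contig oracle test."""
    from retroarray.model import RepeatAnnotationRecord

    hits = []
    pos = 0
    for _ in range(n_hits):
        pos += int(rng.integers(0, int(1.6 * cons_length)))
        length = int(rng.integers(50, cons_length // 2))
        cons_start = int(rng.integers(1, cons_length - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        hits.append(RepeatAnnotationRecord(
            "chr1", pos, pos + length, strand, "EL", "FAM", "LTR",
            cons_start, cons_start + length - 1, cons_length,
        ))
        pos += length
    return hits
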