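# Methods

## Probe re-annotation

Array probes are short (25- or 50-mers) and hybridise efficiently to targets
carrying a mismatch or two, so re-annotation uses an exact ungapped search
rather than a heuristic genome aligner. With `m` allowed mismatches a probe
is split into `m + 1` disjoint seeds of length `k = ⌊L/(m+1)⌋`; any placement
with ≤ m mismatches must contain one exact seed (pigeonhole), so looking up
each seed in a k-mer index of the genome and verifying candidates by Hamming
count is provably complete. Gapped alignments are not considered: the
identity cut-offs in use (≥48/50, ≥24/25) admit at most substitutions, and
short-probe hybridisation is not meaningfully tolerant of indels. `N` never
counts as a match on either side.

The top hit is the placement with the most matches; ties are broken
lexicographically by (chrom, start, strand) so results are deterministic. A
probe is a repeat probe when its top hit overlaps a repeat-annotation
interval by at least `min_overlap_nt` (48 for 50-mers, 24 for 25-mers);
among qualifying intervals the largest overlap wins, first-by-position on
ties. Orientation: for platforms whose probes are complementary to the
transcript (both supported platform families), a probe detects *sense*
repeat transcripts when its alignment strand equals the repeat's annotated
strand; an explicit chemistry flag flips this for same-sense probe designs.
Classification uses the single top hit only — a lower-scoring sense-oriented
repeat hit never overrides an antisense top hit — because anything else
would make the call depend on arbitrary ordering among near-identical loci.

Coordinates are 0-based half-open internally, converted at I/O boundaries
(UCSC rmsk tables are already half-open; RepeatMasker `.out` rows are
1-based inclusive). Consensus coordinates are 1-based inclusive and
minus-strand records are normalised at read time so that
`cons_start < cons_end` always, making coverage arithmetic strand-agnostic.

## Preprocessing

Background correction follows the normexp convolution model
`X = B + S`, `B ~ N(μ, σ²)`, `S ~ Exp(rate)`, replacing each intensity with
the posterior mean `E[S|X=x] = μ_sf + σ·φ(μ_sf/σ)/Φ(μ_sf/σ)` with
`μ_sf = x − μ − σ²·E[S]`, evaluated in log space for tail stability. The
output is strictly positive and monotone in `x`, so within-array ranks are
preserved. Per-array parameters are user-supplied or estimated by matching
the first three moments of the observed intensities
(`E[X] = μ + α`, `Var X = σ² + α²`, third central moment `= 2α³`, with
`α = E[S]`); the moments route is simple and adequate for the probe-level
workflow, which skips probeset summarisation entirely.

Beadchip-style input is assumed already background-subtracted by vendor
software, which can leave non-positive values; an offset (default 16) is
added before log2. Quantile normalization maps every column onto the
rank-wise mean distribution; a tie group within a column receives the mean
of the reference values its ranks span, the procedure is idempotent, and a
single-column matrix is returned unchanged.

Present/absent filtering: the beadchip rule drops probes called absent in
every sample (detection p < 0.01 counts as present — a vendor-style default,
configurable via `detection_alpha`, since detection thresholds vary between
installations); the GeneChip rule keeps probes whose intensity strictly
exceeds the per-array median (over all probes) in at least half the arrays
of some condition, rounding half up for odd array counts. Filters only drop
rows; retained values and row order are untouched.

## Differential expression

Only the two-group design is supported; every contrast of interest here is
mutant vs control. Per probe: `M = x̄₁ − x̄₀` (log2), `A` the grand mean,
pooled variance `s²` on `df = n₁ + n₂ − 2`. The empirical-Bayes prior
assumes `s² ~ s₀²·F(df, d₀)` and is fitted by matching moments of `log s²`:
with `e = log s² − ψ(df/2) + log(df/2)`, the prior degrees of freedom solve
`ψ′(d₀/2) = Var(e) − ψ′(df/2)` (trigamma inverse by Newton iteration) and
`s₀² = exp(ē + ψ(d₀/2) − log(d₀/2))`. When the moment equation has no
positive solution, or the estimate exceeds 500, the prior is taken as
infinite and every probe shares `s₀²`. Posterior variances are the usual
precision-weighted blend; the moderated t is referred to Student's t on
`df + d₀` degrees of freedom (normal when `d₀ = ∞`). Probes with `df = 0`
or zero standard error get p = 1 rather than being dropped.

Benjamini–Hochberg step-up adjustment is computed in-package (step-up
minimum of `m·p(j)/j`), and calls use the published rule: up when
`M ≥ log2(fold_threshold)` (inclusive, "at least f-fold") **and**
`adj_p < α` (strict). The strict/inclusive choice on α is switchable
(`alpha_inclusive`) because published usage mixes "p < 0.01" and "≤ 0.01";
strict is the default. The fold threshold applies to the model `M`, not to
raw group means.

Element summaries count only sense-detecting repeat probes, since antisense
repeat probes do not report sense repeat transcription. Percentage shares
(`percent()`) round half-away-from-zero at the reported precision.

## Population statistics

Rank-sum comparisons use the Wilcoxon–Mann–Whitney U with midranks for
ties. For pooled `n ≤ 30` the exact two-sided p is computed by dynamic
programming over the doubled midrank multiset (the full permutation null,
valid under ties); above that, a normal approximation with tie-corrected
variance and 0.5 continuity correction. Two-sided p is twice the smaller
tail, capped at 1; degenerate pooled data gives p = 1. The exact/approximate
switch at 30 keeps the DP cheap while the approximation error is already
below 10% at 15 vs 15. Tests are two-sided by construction (the direction of
a population shift is not assumed).

Kernel density estimates use a Gaussian kernel on a regular grid spanning
the data ± 3 bandwidths; the automatic bandwidth is Silverman's rule
`0.9·min(sd, IQR/1.34)·n^{−1/5}`. Plot rendering is intentionally out of
scope; the module's contract is the numeric tables (MA, densities, test
results) behind such figures.

## Contig assembly

RepeatMasker splits one genomic repeat copy into several hits wherever the
copy diverges from the consensus. Hits of one element are merged in genomic
order when they are on the same chromosome and strand, the gap from the end
of the growing contig to the next hit is strictly less than one consensus
length, and the next hit is consensus-collinear with the contig's frontier
(ascending consensus positions on `+`, descending on `−`), allowing up to
20 nt of consensus overlap because adjacent RepeatMasker fragments commonly
overlap slightly. Every hit lands in exactly one contig.

Consensus coverage is the union of the segments' 1-based inclusive
consensus intervals; a single full-length segment gives coverage exactly
1.0. Full-length calls are strict (`> 0.95`), as is ORF intactness
(covered share of the ORF interval `> 0.90`). Gaps in coverage of at least
50 nt are deletions; gaps touching a consensus end are flagged terminal
(truncations) and excluded from recurrent-deletion clustering, which
single-links internal deletions whose start and end breakpoints each differ
by at most 10 nt and reports the median breakpoint pair and the carrier
fraction over all contigs analysed.

LTR flank detection requires a partner-LTR hit of at least 250 nt ending
within 0–50 bp upstream of the contig start and another beginning within
0–50 bp downstream of its end; LTR orientation is recorded but not required
to match the contig strand (solo and inverted LTR arrangements occur, and
requiring strand match would silently drop real proviruses). Probe-to-contig
matching uses *all* qualifying placements of a probe, not just the top hit,
because a repeat probe's top hit is arbitrary among near-identical loci; a
placement matches when it lies within the contig span padded by one probe
length. Nested hits of other elements inside a contig's span are ignored —
only same-element hits participate in assembly.

## Synthetic data

The generator emulates the statistical structure the pipeline targets: a
random background genome with planted element copies (uniform substitutions
at 1%/nt by default; block deletions carried by a configured fraction of
copies, which split the copy into collinear fragments; optional flanking
LTRs within 0–10 bp of the internal region), probes drawn from background
and from planted fragments in both orientations, and a 3 vs 3 log2
expression matrix (baseline `N(8, 1.5²)` per probe, i.i.d. noise sd 0.25
per cell) in which all sense probes of a spiked element share a +2 log2
shift — an element-level coordinated response over a null probe population.
Detection dropout (rate 0.05) is confined to the lowest-baseline decile to
mimic vendor absent calls. Probe footprints are rejection-sampled to carry
at most the aligner's mismatch allowance of planted substitutions, so truth
labels are unambiguous. Planted copies are separated by at least 1500 bp of
background — more than any consensus length — so distinct copies can never
merge into one contig.

The default scenario (eight elements across LTR/ERVK, ERV1, ERVL, LINE,
SINE, DNA and satellite classes; the spiked ERVK internal element with six
copies, a recurrent 399–870 deletion in a third of them and flanking LTRs)
is toy-sized on purpose: 150 kb of genome, 296 probes, 3 vs 3 arrays keep
the full pipeline and its calibration loops fast while exercising every
code path. What passing tests on this generator do **not** show: robustness
to indel divergence, phylogenetic substructure within elements,
cross-hybridisation between related elements, intensity-dependent noise, or
array spatial artifacts — real data have all of these, and results there
depend on the quality of the genome build and repeat annotation supplied.

## Numerical and design choices

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configs reproduce byte-identical
  outputs.
- Tie-breaks are deterministic everywhere (lexicographic on genomic
  position).
- The pipeline runner executes stages as pure functions over files in a
  single process, writes outputs atomically, records a JSON manifest
  (config hash, input checksums, parameters, seed, per-stage outputs) on
  success and failure, and skips a completed run whose config hash is
  unchanged unless forced. Exit codes: 2 missing input, 3 parameter
  validation, 1 other failure.
- Known limitations: no gapped/spliced probe alignment, no probeset
  summarisation or multi-factor designs, no sequence-level realignment of
  contigs to the consensus, and no multiple-testing correction across
  population rank-sum tests (raw p is reported, matching field practice).
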