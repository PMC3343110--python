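"""Synthetic microarray study generator with known ground truth.

The generator emulates the structure the pipeline is designed to detect: a
genome carrying planted copies of repeat elements (mutated, deleted,
truncated, optionally flanked by long terminal repeats), a probe set drawn
from repeat and background loci in both orientations, and a two-condition
log-normal expression matrix where all sense probes of a spiked element share
a coordinated log2 fold change over a null probe population.

What this emulates and what it does not: copies diverge from their consensus
by uniform substitutions and block deletions only (no indel evolution, no
phylogenetic structure); expression noise is i.i.d. Gaussian on the log2
scale (no array spatial artifacts, no intensity-dependent variance); and
detection dropout is concentrated in the lowest-intensity decile to mimic
vendor absent calls.  Probe footprints are rejection-sampled to carry at
most the aligner's mismatch allowance of planted substitutions, so the
planted truth labels are unambiguous.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as raio
from .annotate import reverse_complement
from .model import ExpressionMatrix, Probe, RepeatAnnotationRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: background gap floor between planted units; larger than any consensus so
#: distinct copies can never merge into one contig
MIN_BACKGROUND_GAP = 1500


@dataclass(frozen=True)
class DeletionSpec:
    """A consensus interval deleted from a fraction of an element's copies."""

    cons_start: int
    cons_end: int
    fraction: float

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise ValueError("deletion fraction must be in [0, 1]")
        if self.cons_start > self.cons_end or self.cons_start < 1:
            raise ValueError("invalid deletion interval")


@dataclass(frozen=True)
class ElementSpec:
    name: str
    family: str
    repeat_class: str
    cons_length: int
    n_copies: int
    substitution_rate: float = 0.01
    deletions: Tuple[DeletionSpec, ...] = ()
    ltr_flank: bool = False
    ltr_name: str = ""
    ltr_length: int = 350

    def __post_init__(self):
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution rate must be in [0, 1]")
        ivs = sorted((d.cons_start, d.cons_end) for d in self.deletions)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.name}: overlapping deletion specs")
        for d in self.deletions:
            if d.cons_end > self.cons_length:
                raise ValueError(f"{self.name}: deletion beyond consensus")
        if self.ltr_flank and not self.ltr_name:
            raise ValueError(f"{self.name}: ltr_flank requires ltr_name")


@dataclass(frozen=True)
class ProbeSpec:
    n_non_repeat: int = 200
    per_element_sense: int = 10
    per_element_antisense: int = 2
    probe_length: int = 50
    max_planted_mismatches: int = 2  # rejection threshold for repeat probes


@dataclass(frozen=True)
class SpikeSpec:
    element: str
    log2_effect: float


@dataclass(frozen=True)
class ExpressionSpec:
    n_case: int = 3
    n_control: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    spikes: Tuple[SpikeSpec, ...] = ()
    detection_dropout_rate: float = 0.05

    def __post_init__(self):
        if not 0 <= self.detection_dropout_rate <= 1:
            raise ValueError("dropout rate must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 150_000
    chrom: str = "chr1"
    elements: Tuple[ElementSpec, ...] = ()
    probes: ProbeSpec = field(default_factory=ProbeSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)


@dataclass
class CopyTruth:
    """One planted genomic copy of an element."""

    element: str
    copy_index: int
    chrom: str
    start: int
    end: int
    strand: str
    records: List[RepeatAnnotationRecord]
    substituted_positions: set  # absolute genomic positions
    deletions: Tuple[DeletionSpec, ...]


@dataclass
class TruthSet:
    """Planted structure consistent with the emitted genome and tables."""

    records: List[RepeatAnnotationRecord]
    copies: List[CopyTruth]
    consensus: Dict[str, str]
    background: List[Tuple[int, int]]  # 0-based half-open background intervals


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: Dict[str, str]
    truth: TruthSet
    probes: List[Probe]
    probe_labels: pd.DataFrame
    expression: Optional[ExpressionMatrix] = None
    de_truth: Optional[pd.Series] = None  # planted log2 effect per probe


def default_config(seed: int = 0) -> SimulationConfig:
    """The bundled toy scenario: eight elements, one spiked, 3v3 arrays.

    The spiked internal element carries a recurrent internal deletion in a
    third of its copies and retains flanking LTRs, mirroring the structure of
    a partially degraded ERV family.
    """
    elements = (
        ElementSpec(
            "simERVK-A-int", "ERVK", "LTR", cons_length=1200, n_copies=6,
            deletions=(DeletionSpec(399, 870, 1 / 3),),
            ltr_flank=True, ltr_name="simLTR-A", ltr_length=350,
        ),
        ElementSpec(
            "simERVK-B-int", "ERVK", "LTR", cons_length=900, n_copies=4,
            deletions=(DeletionSpec(1, 120, 0.5),),
        ),
        ElementSpec("simERV1-A-int", "ERV1", "LTR", cons_length=800, n_copies=4),
        ElementSpec("simERVL-A-int", "ERVL", "LTR", cons_length=700, n_copies=3),
        ElementSpec("simL1-A", "L1", "LINE", cons_length=1000, n_copies=5),
        ElementSpec("simB1-A", "Alu", "SINE", cons_length=600, n_copies=4),
        ElementSpec("simDNA-A", "hAT", "DNA", cons_length=600, n_copies=3),
        ElementSpec("simSat-A", "Satellite", "Satellite", cons_length=600, n_copies=3),
    )
    return SimulationConfig(
        seed=seed,
        genome_length=150_000,
        elements=elements,
        probes=ProbeSpec(n_non_repeat=200, per_element_sense=10,
                         per_element_antisense=2, probe_length=50),
        expression=ExpressionSpec(
            n_case=3, n_control=3, baseline_mean=8.0, baseline_sd=1.5,
            noise_sd=0.25, spikes=(SpikeSpec("simERVK-A-int", 2.0),),
            detection_dropout_rate=0.05,
        ),
    )


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def config_from_dict(data: dict) -> SimulationConfig:
    elements = []
    for e in data.get("elements", []):
        dels = tuple(DeletionSpec(**d) for d in e.pop("deletions", []))
        elements.append(ElementSpec(**e, deletions=dels))
    expr = dict(data.get("expression", {}))
    spikes = tuple(SpikeSpec(**s) for s in expr.pop("spikes", []))
    return SimulationConfig(
        seed=data.get("seed", 0),
        genome_length=data.get("genome_length", 150_000),
        chrom=data.get("chrom", "chr1"),
        elements=tuple(elements),
        probes=ProbeSpec(**data.get("probes", {})),
        expression=ExpressionSpec(**expr, spikes=spikes),
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> Tuple[str, np.ndarray]:
    """Substitute bases at ``rate`` per nt; returns (sequence, positions)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii"), hits


def _copy_fragments(cons_length: int, deletions) -> List[Tuple[int, int]]:
    """Retained consensus intervals (1-based inclusive) after deletions."""
    fragments = []
    pos = 1
    for d in sorted(deletions, key=lambda d: d.cons_start):
        if d.cons_start > pos:
            fragments.append((pos, d.cons_start - 1))
        pos = d.cons_end + 1
    if pos <= cons_length:
        fragments.append((pos, cons_length))
    if not fragments:
        raise ValueError("deletions remove the whole copy")
    return fragments


def simulate_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[Dict[str, str], TruthSet]:
    """Plant mutated, deleted, optionally LTR-flanked element copies in a
    random background genome.

    Returns the genome ({chrom: sequence}) and the truth set whose records
    carry exact consensus coordinates for every planted fragment.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom = config.chrom
    consensus: Dict[str, str] = {}
    for e in config.elements:
        consensus[e.name] = _random_seq(rng, e.cons_length)
        if e.ltr_flank and e.ltr_name not in consensus:
            consensus[e.ltr_name] = _random_seq(rng, e.ltr_length)

    # plan each copy: which deletions it carries, its strand
    units = []  # (ElementSpec, copy_index, deletions, strand)
    for e in config.elements:
        carriers: Dict[int, List[DeletionSpec]] = {i: [] for i in range(e.n_copies)}
        for d in e.deletions:
            k = int(round(d.fraction * e.n_copies))
            for i in rng.choice(e.n_copies, size=k, replace=False):
                carriers[int(i)].append(d)
        for i in range(e.n_copies):
            strand = "+" if rng.random() < 0.5 else "-"
            units.append((e, i, tuple(carriers[i]), strand))
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    # build the sequence of each unit before layout
    built = []  # (unit_seq, callback(offset) -> (records, copy_truth))
    total_insert = 0
    for e, idx, dels, strand in units:
        fragments = _copy_fragments(e.cons_length, dels)
        internal = "".join(consensus[e.name][s - 1:e_] for s, e_ in fragments)
        internal, sub_offsets = _mutate(rng, internal, e.substitution_rate)
        if strand == "-":
            internal_genomic = reverse_complement(internal)
            sub_genomic = {len(internal) - 1 - int(o) for o in sub_offsets}
        else:
            internal_genomic = internal
            sub_genomic = {int(o) for o in sub_offsets}
        parts = [internal_genomic]
        ltr_info = []
        if e.ltr_flank:
            for side in ("up", "down"):
                ltr_seq, _ = _mutate(rng, consensus[e.ltr_name], e.substitution_rate)
                if strand == "-":
                    ltr_seq = reverse_complement(ltr_seq)
                gap = _random_seq(rng, int(rng.integers(0, 11)))
                ltr_info.append((side, ltr_seq, gap))
            up_side, up_seq, up_gap = ltr_info[0]
            down_side, down_seq, down_gap = ltr_info[1]
            parts = [up_seq, up_gap, internal_genomic, down_gap, down_seq]
        unit_seq = "".join(parts)
        built.append((e, idx, dels, strand, fragments, unit_seq, parts, sub_genomic))
        total_insert += len(unit_seq)

    n_gaps = len(units) + 1
    background_total = config.genome_length - total_insert
    if background_total < n_gaps * MIN_BACKGROUND_GAP:
        raise ValueError(
            f"insertions ({total_insert} nt) exceed genome length budget; "
            f"need >= {total_insert + n_gaps * MIN_BACKGROUND_GAP} nt"
        )
    extra = background_total - n_gaps * MIN_BACKGROUND_GAP
    extra_split = rng.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps))
    gap_lengths = [MIN_BACKGROUND_GAP + int(x) for x in extra_split]

    seq_parts: List[str] = []
    records: List[RepeatAnnotationRecord] = []
    copies: List[CopyTruth] = []
    background: List[Tuple[int, int]] = []
    pos = 0
    for i, (e, idx, dels, strand, fragments, unit_seq, parts, sub_genomic) in enumerate(built):
        bg = _random_seq(rng, gap_lengths[i])
        background.append((pos, pos + len(bg)))
        seq_parts.append(bg)
        pos += len(bg)
        unit_start = pos
        # locate the internal block and LTRs inside the unit
        if e.ltr_flank:
            up_seq, up_gap, internal_genomic, down_gap, down_seq = parts
            up_start = unit_start
            internal_start = up_start + len(up_seq) + len(up_gap)
            down_start = internal_start + len(internal_genomic) + len(down_gap)
            records.append(RepeatAnnotationRecord(
                chrom, up_start, up_start + len(up_seq), strand,
                e.ltr_name, e.family, "LTR", 1, e.ltr_length, e.ltr_length,
            ))
            records.append(RepeatAnnotationRecord(
                chrom, down_start, down_start + len(down_seq), strand,
                e.ltr_name, e.family, "LTR", 1, e.ltr_length, e.ltr_length,
            ))
        else:
            internal_genomic = parts[0]
            internal_start = unit_start
        # fragment records: consensus order maps to genomic order on '+',
        # reversed on '-'
        frag_records = []
        offset = 0
        genomic_frags = fragments if strand == "+" else list(reversed(fragments))
        for s, e_ in genomic_frags:
            flen = e_ - s + 1
            frag_records.append(RepeatAnnotationRecord(
                chrom, internal_start + offset, internal_start + offset + flen,
                strand, e.name, e.family, e.repeat_class,
                s, e_, e.cons_length,
            ))
            offset += flen
        records.extend(frag_records)
        copies.append(CopyTruth(
            element=e.name, copy_index=idx, chrom=chrom,
            start=internal_start, end=internal_start + len(internal_genomic),
            strand=strand, records=frag_records,
            substituted_positions={internal_start + p for p in sub_genomic},
            deletions=dels,
        ))
        seq_parts.append(unit_seq)
        pos += len(unit_seq)
    bg = _random_seq(rng, gap_lengths[-1])
    background.append((pos, pos + len(bg)))
    seq_parts.append(bg)

    genome = {chrom: "".join(seq_parts)}
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return genome, TruthSet(records, copies, consensus, background)


def simulate_probes(
    genome: Dict[str, str],
    truth: TruthSet,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[Probe], pd.DataFrame]:
    """Draw non-repeat probes from background and repeat probes from planted
    fragments in sense and antisense orientation.

    Repeat probe footprints are rejection-sampled to lie within a single
    planted fragment and to carry at most ``max_planted_mismatches``
    substitutions, so the expected annotation of every probe is unambiguous.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    spec = config.probes
    plen = spec.probe_length
    chrom = config.chrom
    seq = genome[chrom]
    probes: List[Probe] = []
    labels = []

    usable_bg = [(s, e) for s, e in truth.background if e - s >= plen + 2]
    if not usable_bg:
        raise ValueError("not enough background sequence for non-repeat probes")
    weights = np.array([e - s - plen for s, e in usable_bg], dtype=float)
    weights /= weights.sum()
    for i in range(spec.n_non_repeat):
        j = rng.choice(len(usable_bg), p=weights)
        s, e = usable_bg[j]
        start = int(rng.integers(s, e - plen + 1))
        sub = seq[start:start + plen]
        if rng.random() < 0.5:
            sub = reverse_complement(sub)
        pid = f"bg_{i:04d}"
        probes.append(Probe(pid, sub, "generic"))
        labels.append(dict(probe_id=pid, is_repeat=False, element="", family="",
                           repeat_class="", detects_sense=False,
                           source_start=start))

    for e in config.elements:
        element_copies = [c for c in truth.copies if c.element == e.name]
        for orientation, count in (("sense", spec.per_element_sense),
                                   ("antisense", spec.per_element_antisense)):
            made = 0
            attempts = 0
            while made < count:
                attempts += 1
                if attempts > 200 * max(count, 1):
                    raise RuntimeError(
                        f"{e.name}: cannot place {orientation} probes "
                        "(fragments too short or too diverged)"
                    )
                copy = element_copies[int(rng.integers(len(element_copies)))]
                frags = [r for r in copy.records if r.end - r.start >= plen]
                if not frags:
                    continue
                frag = frags[int(rng.integers(len(frags)))]
                start = int(rng.integers(frag.start, frag.end - plen + 1))
                footprint = range(start, start + plen)
                n_sub = sum(1 for p in footprint if p in copy.substituted_positions)
                if n_sub > spec.max_planted_mismatches:
                    continue
                sub = seq[start:start + plen]
                # sense probe: alignment strand equals the repeat strand
                want_same_strand = orientation == "sense"
                if (copy.strand == "-") == want_same_strand:
                    sub = reverse_complement(sub)
                pid = f"{e.name}_{orientation[0]}{made:02d}"
                probes.append(Probe(pid, sub, "generic"))
                labels.append(dict(
                    probe_id=pid, is_repeat=True, element=e.name,
                    family=e.family, repeat_class=e.repeat_class,
                    detects_sense=orientation == "sense",
                    source_start=start,
                ))
                made += 1

    df = pd.DataFrame(labels).set_index("probe_id")
    return probes, df


def simulate_expression(
    probe_labels: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ExpressionMatrix, pd.Series]:
    """Two-condition log2 expression with element-level spiked effects.

    Per-probe baselines are drawn once; case samples of a spiked element's
    sense probes are shifted by the spike's log2 effect; i.i.d. Gaussian
    noise is added to every cell.  Detection calls are present except for
    dropouts concentrated in the lowest-baseline decile.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    spec = config.expression
    probe_ids = list(probe_labels.index)
    n = len(probe_ids)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    effect = np.zeros(n)
    for spike in spec.spikes:
        mask = (
            (probe_labels["element"] == spike.element)
            & probe_labels["detects_sense"]
        ).to_numpy()
        effect[mask] += spike.log2_effect
    samples = [f"case_{i + 1}" for i in range(spec.n_case)] + [
        f"control_{i + 1}" for i in range(spec.n_control)
    ]
    conditions = {s: ("case" if s.startswith("case") else "control") for s in samples}
    is_case = np.array([conditions[s] == "case" for s in samples])
    values = (
        baseline[:, None]
        + np.outer(effect, is_case.astype(float))
        + rng.normal(0.0, spec.noise_sd, size=(n, len(samples)))
    )
    detection = np.ones((n, len(samples)), dtype=int)
    decile = np.quantile(baseline, 0.1)
    low = baseline <= decile
    dropout = (rng.random((n, len(samples))) < spec.detection_dropout_rate) & low[:, None]
    detection[dropout] = 0
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=samples),
        scale="log2",
        detection=pd.DataFrame(detection, index=probe_ids, columns=samples),
        conditions=conditions,
    )
    return matrix, pd.Series(effect, index=probe_ids, name="log2_effect")


def simulate_all(config: Optional[SimulationConfig] = None) -> SimulatedDataset:
    """Run the three generators with seeds derived from the config seed."""
    config = config or default_config()
    genome, truth = simulate_genome(config)
    probes, labels = simulate_probes(genome, truth, config)
    expression, de_truth = simulate_expression(labels, config)
    return SimulatedDataset(config, genome, truth, probes, labels, expression, de_truth)


def write_dataset(dataset: SimulatedDataset, outdir) -> Dict[str, Path]:
    """Write the dataset as plain-text files; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "rmsk": outdir / "rmsk.tsv",
        "probes": outdir / "probes.tsv",
        "expression": outdir / "expr.tsv",
        "detection": outdir / "detection.tsv",
        "design": outdir / "design.tsv",
        "probe_truth": outdir / "truth_probes.tsv",
        "de_truth": outdir / "truth_effects.tsv",
    }
    raio.write_fasta(dataset.genome, paths["genome"])
    raio.write_rmsk_table(dataset.truth.records, paths["rmsk"])
    raio.write_probe_table(dataset.probes, paths["probes"])
    if dataset.expression is not None:
        raio.write_expression_table(dataset.expression, paths["expression"])
        dataset.expression.detection.to_csv(
            paths["detection"], sep="\t", index_label="probe_id"
        )
        raio.write_design_table(dataset.expression.conditions, paths["design"])
    dataset.probe_labels.to_csv(paths["probe_truth"], sep="\t")
    if dataset.de_truth is not None:
        dataset.de_truth.to_csv(paths["de_truth"], sep="\t", index_label="probe_id")
    return paths
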