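"""Readers and writers for the plain-text formats the pipeline consumes.

Supported formats: FASTA genomes/probe sets (via Biopython), repeat
annotation tables in the UCSC ``rmsk`` and RepeatMasker ``.out`` dialects,
probe tables and probe-annotation tables as TSV, expression/detection
matrices as TSV, and YAML parameter files.

All genomic coordinates are converted to 0-based half-open on read.
Minus-strand consensus coordinates are normalised so ``cons_start <
cons_end`` on the consensus.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ExpressionMatrix,
    GenomicAlignment,
    Parameters,
    Probe,
    RepeatAnnotationRecord,
    RepeatProbeAnnotation,
)

logger = logging.getLogger("retroarray")

_UCSC_COLUMNS = [
    "bin", "swScore", "milliDiv", "milliDel", "milliIns",
    "genoName", "genoStart", "genoEnd", "genoLeft", "strand",
    "repName", "repClass", "repFamily", "repStart", "repEnd", "repLeft", "id",
]


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict:
    """Load a FASTA file into an ordered {name: uppercase sequence} dict."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Repeat annotation tables

def _ucsc_row_to_record(fields, lineno) -> RepeatAnnotationRecord:
    if len(fields) == 16:  # without the leading bin column
        fields = [0] + fields
    if len(fields) != 17:
        raise FormatError(f"line {lineno}: expected 16/17 columns, got {len(fields)}")
    d = dict(zip(_UCSC_COLUMNS, fields))
    try:
        strand = d["strand"]
        rep_start, rep_end, rep_left = (
            int(d["repStart"]), int(d["repEnd"]), int(d["repLeft"]))
        if strand == "+":
            # repLeft is -(bases of consensus beyond repEnd)
            cons_start, cons_end = rep_start, rep_end
            cons_length = rep_end - rep_left
        elif strand == "-":
            # repStart is -(bases of consensus beyond repEnd); repLeft holds
            # the consensus start.
            cons_start, cons_end = rep_left, rep_end
            cons_length = rep_end - rep_start
        else:
            raise FormatError(f"line {lineno}: bad strand {strand!r}")
        return RepeatAnnotationRecord(
            chrom=d["genoName"],
            start=int(d["genoStart"]),  # UCSC is already 0-based half-open
            end=int(d["genoEnd"]),
            strand=strand,
            element=d["repName"],
            family=d["repFamily"],
            repeat_class=d["repClass"],
            cons_start=cons_start,
            cons_end=cons_end,
            cons_length=cons_length,
        )
    except (KeyError, ValueError, TypeError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"line {lineno}: malformed UCSC rmsk row ({exc})") from exc


def _out_row_to_record(fields, lineno) -> RepeatAnnotationRecord:
    if len(fields) < 14:
        raise FormatError(f"line {lineno}: expected >=14 columns, got {len(fields)}")
    try:
        chrom = fields[4]
        start = int(fields[5]) - 1  # .out is 1-based inclusive
        end = int(fields[6])
        strand = "+" if fields[8] == "+" else "-"
        if fields[8] not in ("+", "C"):
            raise FormatError(f"line {lineno}: bad strand {fields[8]!r}")
        element = fields[9]
        cls_fam = fields[10].split("/")
        repeat_class = cls_fam[0]
        family = cls_fam[1] if len(cls_fam) > 1 else cls_fam[0]
        f12, f13, f14 = fields[11], fields[12], fields[13]
        if fields[8] == "+":
            cons_start, cons_end = int(f12), int(f13)
            left = int(f14.strip("()"))
        else:  # C strand prints (left) end begin
            left = int(f12.strip("()"))
            cons_end, cons_start = int(f13), int(f14)
        cons_length = cons_end + left
        return RepeatAnnotationRecord(
            chrom=chrom, start=start, end=end, strand=strand,
            element=element, family=family, repeat_class=repeat_class,
            cons_start=cons_start, cons_end=cons_end, cons_length=cons_length,
        )
    except (ValueError, IndexError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"line {lineno}: malformed .out row ({exc})") from exc


def read_rmsk_table(path, dialect: str = "ucsc") -> list:
    """Read a repeat annotation table.

    ``dialect`` is ``"ucsc"`` (UCSC rmsk tab-delimited dump, 0-based
    half-open) or ``"out"`` (RepeatMasker ``.out``, 1-based inclusive with
    three header lines).  Records are returned sorted by (chrom, start).
    """
    if dialect not in ("ucsc", "out"):
        raise ValueError(f"unknown rmsk dialect {dialect!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "ucsc":
                if line.startswith("#"):
                    continue
                records.append(_ucsc_row_to_record(line.split("\t"), lineno))
            else:
                low = line.strip().lower()
                if low.startswith(("sw", "score")):
                    continue
                records.append(_out_row_to_record(line.split(), lineno))
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def write_rmsk_table(records: Iterable[RepeatAnnotationRecord], path) -> None:
    """Write records in the UCSC rmsk dialect (round-trips via read_rmsk_table)."""
    rows = []
    for r in records:
        left = -(r.cons_length - r.cons_end)
        if r.strand == "+":
            rep_start, rep_end, rep_left = r.cons_start, r.cons_end, left
        else:
            rep_start, rep_end, rep_left = left, r.cons_end, r.cons_start
        rows.append([
            0, 0, 0, 0, 0, r.chrom, r.start, r.end, 0, r.strand,
            r.element, r.repeat_class, r.family, rep_start, rep_end, rep_left, 0,
        ])
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_UCSC_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Probe tables

def read_probe_table(path, platform: str = "generic") -> list:
    """Read probes from a TSV (probe_id, sequence columns) or FASTA file."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return [
            Probe(rec.id, str(rec.seq), platform)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "probe_id" not in cols or "sequence" not in cols:
        raise FormatError(f"{path}: need probe_id and sequence columns")
    return [
        Probe(row[cols["probe_id"]], row[cols["sequence"]], platform)
        for _, row in df.iterrows()
    ]


def write_probe_table(probes: Iterable[Probe], path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tsequence\n")
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.sequence}\n")


# ---------------------------------------------------------------------------
# Probe annotation tables (mirrors the published supplementary datasets)

_ANNOT_COLUMNS = [
    "probe_id", "sequence", "chrom", "start", "end", "strand",
    "element", "family", "class", "overlap_nt", "detects_sense",
    "hit_count", "matches",
]


def write_probe_annotation_table(
    annotations: Iterable[RepeatProbeAnnotation],
    path,
    sequences: Optional[dict] = None,
) -> None:
    """Write annotations as TSV; empty fields are serialised as '.'."""
    annotations = list(annotations)
    if not annotations:
        raise ValueError("no annotations to write")
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLUMNS) + "\n")
        for a in annotations:
            seq = (sequences or {}).get(a.probe_id, ".")
            hit = a.top_hit
            row = [
                a.probe_id, seq,
                hit.chrom if hit else ".",
                str(hit.start) if hit else ".",
                str(hit.end) if hit else ".",
                hit.strand if hit else ".",
                a.element or ".", a.family or ".", a.repeat_class or ".",
                str(a.overlap_nt), str(int(a.detects_sense)), str(a.hit_count),
                str(hit.matches) if hit else ".",
            ]
            fh.write("\t".join(row) + "\n")


def read_probe_annotation_table(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_ANNOT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        hit = None
        if row["chrom"] != ".":
            start, end = int(row["start"]), int(row["end"])
            hit = GenomicAlignment(
                chrom=row["chrom"], start=start, end=end,
                strand=row["strand"], matches=int(row["matches"]),
                probe_length=end - start,
            )
        element = "" if row["element"] == "." else row["element"]
        out.append(RepeatProbeAnnotation(
            probe_id=row["probe_id"],
            is_repeat=bool(element),
            detects_sense=bool(int(row["detects_sense"])),
            element=element,
            family="" if row["family"] == "." else row["family"],
            repeat_class="" if row["class"] == "." else row["class"],
            overlap_nt=int(row["overlap_nt"]),
            hit_count=int(row["hit_count"]),
            top_hit=hit,
        ))
    return out


# ---------------------------------------------------------------------------
# Expression matrices

def read_expression_table(
    path,
    scale: str = "raw",
    detection_path=None,
    design_path=None,
) -> ExpressionMatrix:
    """Read a probes x samples TSV (first column probe_id).

    ``detection_path`` optionally supplies an aligned detection p-value or
    0/1 matrix; ``design_path`` a two-column sample_id/condition TSV.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, sep="\t", index_col=0)
    conditions = None
    if design_path is not None:
        conditions = read_design_table(design_path)
    return ExpressionMatrix(values, scale, detection, conditions)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id")


def read_design_table(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "condition" not in cols:
        raise FormatError(f"{path}: need sample_id and condition columns")
    return dict(zip(df[cols["sample_id"]], df[cols["condition"]]))


def write_design_table(conditions: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\n")
        for sample, cond in conditions.items():
            fh.write(f"{sample}\t{cond}\n")


# ---------------------------------------------------------------------------
# Parameters

def load_parameters(path) -> Parameters:
    """Load Parameters from a YAML mapping (top-level or under 'parameters')."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "parameters" in data:
        data = data["parameters"] or {}
    valid = set(Parameters.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return Parameters(**data)
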