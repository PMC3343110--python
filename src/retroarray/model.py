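"""Shared domain types and parameters.

Coordinate conventions
----------------------
Genomic intervals are 0-based half-open throughout the package; converters
live at the I/O boundaries (see :mod:`retroarray.io`).  Consensus coordinates
on a repeat element's reference sequence are 1-based inclusive, with
``cons_start <= cons_end`` regardless of genomic strand (minus-strand records
are normalised at read time so downstream coverage arithmetic is
strand-agnostic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGTN")

PLATFORMS = ("illumina_wg6", "affymetrix_u74", "affymetrix_430", "generic")

#: Per-platform (probe length, max mismatches, min repeat overlap in nt).
#: 50-mer beadchip probes tolerate 2 mismatches and must overlap a repeat by
#: >=48 nt; 25-mer GeneChip probes tolerate 1 mismatch and >=24 nt.
PLATFORM_RULES = {
    "illumina_wg6": (50, 2, 48),
    "affymetrix_u74": (25, 1, 24),
    "affymetrix_430": (25, 1, 24),
}


@dataclass(frozen=True)
class Probe:
    """A single array probe with its DNA sequence."""

    probe_id: str
    sequence: str
    platform: str = "generic"

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"probe {self.probe_id}: invalid bases {sorted(bad)}"
            )
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        rule = PLATFORM_RULES.get(self.platform)
        if rule is not None and len(self.sequence) != rule[0]:
            raise ValueError(
                f"probe {self.probe_id}: {self.platform} probes are "
                f"{rule[0]}-mers, got length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatAnnotationRecord:
    """One repeat-masked genomic interval with its consensus placement."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    element: str  # e.g. MMERVK10C-int
    family: str  # e.g. ERVK
    repeat_class: str  # e.g. LTR, LINE, SINE, DNA, Satellite, Simple
    cons_start: int  # 1-based inclusive on the element consensus
    cons_end: int
    cons_length: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self}: require start < end")
        if not (1 <= self.cons_start <= self.cons_end <= self.cons_length):
            raise ValueError(
                f"{self}: require 1 <= cons_start <= cons_end <= cons_length"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def genomic_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicAlignment:
    """An ungapped placement of a probe on the genome."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    matches: int
    probe_length: int

    def __post_init__(self):
        if self.end - self.start != self.probe_length:
            raise ValueError("ungapped alignment: end - start must equal probe_length")
        if not 0 <= self.matches <= self.probe_length:
            raise ValueError("matches out of range")

    @property
    def identity(self) -> float:
        return self.matches / self.probe_length


@dataclass(frozen=True)
class RepeatProbeAnnotation:
    """A probe's repeat classification from its top genomic hit."""

    probe_id: str
    is_repeat: bool
    detects_sense: bool = False
    element: str = ""
    family: str = ""
    repeat_class: str = ""
    overlap_nt: int = 0
    hit_count: int = 0
    top_hit: Optional[GenomicAlignment] = None

    def __post_init__(self):
        if self.is_repeat and not (self.element and self.family and self.repeat_class):
            raise ValueError(
                f"{self.probe_id}: repeat annotation requires element/family/class"
            )


@dataclass
class Parameters:
    """Every numeric threshold used by the pipeline, with field defaults.

    Defaults correspond to 50-mer probes; use :meth:`for_platform` to get the
    25-mer variants (1 mismatch, 24 nt overlap).
    """

    max_mismatches: int = 2
    min_overlap_nt: int = 48
    fold_threshold: float = 2.0
    alpha: float = 0.01
    alpha_inclusive: bool = False  # significance strict '<' by default
    ltr_flank_max_gap: int = 50
    ltr_min_length: int = 250
    full_length_fraction: float = 0.95
    orf_intact_fraction: float = 0.90
    detection_alpha: float = 0.01
    deletion_cluster_tolerance: int = 10
    min_deletion_nt: int = 50
    consensus_overlap_tolerance: int = 20
    log2_offset: float = 16.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "min_overlap_nt", "fold_threshold", "alpha", "ltr_flank_max_gap",
            "ltr_min_length", "full_length_fraction", "orf_intact_fraction",
            "detection_alpha", "deletion_cluster_tolerance", "min_deletion_nt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @classmethod
    def for_platform(cls, platform: str, **overrides) -> "Parameters":
        if platform in PLATFORM_RULES:
            _, mm, ov = PLATFORM_RULES[platform]
            overrides.setdefault("max_mismatches", mm)
            overrides.setdefault("min_overlap_nt", ov)
        return cls(**overrides)

    def replace(self, **kw) -> "Parameters":
        return replace(self, **kw)


class ExpressionMatrix:
    """Probes x samples intensity matrix with optional detection calls.

    ``values`` is a pandas DataFrame indexed by probe id with one column per
    sample.  ``scale`` flags whether values are raw intensities or log2.
    ``detection`` (optional, same shape) holds detection p-values or booleans
    (True/low p = present).  ``conditions`` maps sample id -> condition label.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        scale: str = "raw",
        detection: Optional[pd.DataFrame] = None,
        conditions: Optional[dict] = None,
    ):
        if scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {scale!r}")
        if values.index.has_duplicates:
            raise ValueError("duplicate probe ids in expression matrix")
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        if detection is not None:
            if detection.shape != values.shape:
                raise ValueError("detection matrix shape mismatch")
            detection = detection.set_axis(values.index, axis=0).set_axis(
                values.columns, axis=1
            )
        if conditions is not None:
            missing = [s for s in values.columns if s not in conditions]
            if missing:
                raise ValueError(f"samples without condition label: {missing}")
        self.values = values
        self.scale = scale
        self.detection = detection
        self.conditions = dict(conditions) if conditions else None

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def subset(self, probe_ids) -> "ExpressionMatrix":
        """Row subset preserving order of ``probe_ids``; values untouched."""
        det = self.detection.loc[probe_ids] if self.detection is not None else None
        return ExpressionMatrix(
            self.values.loc[probe_ids], self.scale, det, self.conditions
        )

    def with_values(self, values: pd.DataFrame, scale: Optional[str] = None):
        return ExpressionMatrix(
            values, scale or self.scale, self.detection, self.conditions
        )

    def condition_samples(self) -> dict:
        """Condition label -> list of sample ids, in column order."""
        if not self.conditions:
            raise ValueError("no condition labels attached")
        out: dict = {}
        for s in self.values.columns:
            out.setdefault(self.conditions[s], []).append(s)
        empty = set(self.conditions.values()) - set(out)
        if empty:
            raise ValueError(f"conditions with no samples: {sorted(empty)}")
        return out


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """A count ratio as a percentage, rounded half-away-from-zero.

    This is the formatting used for summary fractions such as "84 (0.8%) of
    the 10,316 expressed repeat probes".
    """
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    pct = 100.0 * numerator / denominator
    scale = 10 ** decimals
    return float(np.floor(np.abs(pct) * scale + 0.5) / scale * np.sign(pct))
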