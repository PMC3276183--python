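"""Core domain types for array-based CNV analysis.

All genomic coordinates are held internally as 0-based half-open intervals
(BED convention); file dialects that use 1-based inclusive coordinates are
converted at the I/O boundary (:mod:`cnvburden.io`).  Only autosomes 1-22 and
chromosome X are modelled; X is retained but reported separately downstream.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

VALID_CHROMS = tuple(str(c) for c in range(1, 23)) + ("X",)


class CnvState(str, enum.Enum):
    """Copy-number state relative to the diploid autosome: loss or gain."""

    DEL = "DEL"
    DUP = "DUP"


class Algorithm(str, enum.Enum):
    """CNV-calling algorithms whose call sets the pipeline consumes."""

    IPATTERN = "iPattern"
    PENNCNV = "PennCNV"
    QUANTISNP = "QuantiSNP"
    CNVPARTITION = "CNVpartition"


#: Algorithms eligible to corroborate an iPattern call in the stringent set.
SUPPORT_ALGORITHMS = frozenset({Algorithm.PENNCNV, Algorithm.QUANTISNP})
#: Algorithms whose per-sample call counts feed the outlier rule.
DISCOVERY_ALGORITHMS = (Algorithm.IPATTERN, Algorithm.PENNCNV, Algorithm.QUANTISNP)


class Phenotype(str, enum.Enum):
    CASE = "CASE"
    CONTROL = "CONTROL"


class ExclusionFlag(str, enum.Enum):
    """Reasons a sample is dropped from burden analysis."""

    QC_METRIC = "QC_METRIC"
    CALL_COUNT_OUTLIER = "CALL_COUNT_OUTLIER"
    KARYOTYPE_SCALE = "KARYOTYPE_SCALE"
    AGGREGATE_LENGTH = "AGGREGATE_LENGTH"


class MaskName(str, enum.Enum):
    SEGDUP = "SEGDUP"
    CENTROMERIC = "CENTROMERIC"
    IMMUNOGLOBULIN = "IMMUNOGLOBULIN"
    CUSTOM = "custom"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and validate the label.

    Raises
    ------
    ValueError
        For chromosome Y, mitochondrial, or any unrecognised label.
    """
    label = str(chrom).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label == "23":
        label = "X"
    if label not in VALID_CHROMS:
        raise ValueError(f"unsupported chromosome label {chrom!r}")
    return label


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    assembly: str = field(default="hg18", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 across chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def union_span(self, other: "GenomicInterval") -> "GenomicInterval":
        """Smallest interval covering both (same chromosome required)."""
        if self.chrom != other.chrom:
            raise ValueError("cannot union intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end),
            self.assembly,
        )

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class CnvCall:
    """A single algorithm's CNV call for one sample.

    ``confidence`` is the algorithm-native score (log Bayes factor for
    QuantiSNP).  ``copy_number`` may be None when the source file reports only
    a del/dup state.
    """

    sample_id: str
    interval: GenomicInterval
    state: CnvState
    n_probes: int
    confidence: float
    algorithm: Algorithm
    copy_number: int | None = None
    call_id: str = ""

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError(f"call {self.call_id or self.sample_id}: n_probes must be >= 1")
        if self.copy_number is not None:
            if self.copy_number < 0:
                raise ValueError("copy_number must be >= 0")
            if self.state is CnvState.DEL and self.copy_number >= 2:
                raise ValueError("DEL call with copy_number >= 2")
            if self.state is CnvState.DUP and self.copy_number <= 2:
                raise ValueError("DUP call with copy_number <= 2")
        if not self.call_id:
            object.__setattr__(self, "call_id", self._default_id())

    def _default_id(self) -> str:
        iv = self.interval
        return (
            f"{self.algorithm.value}:{self.sample_id}:{iv.chrom}:"
            f"{iv.start}-{iv.end}:{self.state.value}"
        )

    @property
    def length(self) -> int:
        return self.interval.length()


def state_from_copy_number(cn: int) -> CnvState:
    """Map an integer copy number to a DEL/DUP state (2 is not a CNV)."""
    if cn < 0:
        raise ValueError(f"negative copy number {cn}")
    if cn < 2:
        return CnvState.DEL
    if cn > 2:
        return CnvState.DUP
    raise ValueError("copy number 2 is diploid, not a CNV")


@dataclass
class SampleRecord:
    """Phenotype plus array QC metrics for one genotyped sample.

    A sample contributes to burden analysis iff ``exclusion_flags`` is empty.
    """

    sample_id: str
    phenotype: Phenotype
    sex: str = "unknown"
    call_rate: float = float("nan")
    lrr_sd: float = float("nan")
    baf_sd: float = float("nan")
    wave_factor: float = float("nan")
    per_algorithm_call_count: dict[Algorithm, int] = field(default_factory=dict)
    exclusion_flags: set[ExclusionFlag] = field(default_factory=set)

    @property
    def passes_qc(self) -> bool:
        return not self.exclusion_flags

    def with_flag(self, flag: ExclusionFlag) -> "SampleRecord":
        return replace(self, exclusion_flags=self.exclusion_flags | {flag})


@dataclass(frozen=True)
class GeneModel:
    """A gene span with its (sorted, non-overlapping) exon intervals."""

    gene_name: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.span.chrom:
                raise ValueError(f"{self.gene_name}: exon on wrong chromosome")
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValueError(f"{self.gene_name}: exon outside gene span")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"{self.gene_name}: exons overlap or are unsorted")
            prev_end = exon.end


def merge_intervals(regions: list[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Sort intervals and merge any overlapping or abutting pairs per chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sorted(regions):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end, iv.assembly
                )
        else:
            merged.append(iv)
    return tuple(merged)


@dataclass(frozen=True)
class RegionMask:
    """A named set of sorted, non-overlapping genomic regions.

    Construct with :meth:`from_intervals`, which merges overlapping inputs
    (merging is logged, never an error).
    """

    name: MaskName
    regions: tuple[GenomicInterval, ...] = ()

    @classmethod
    def from_intervals(
        cls, name: MaskName, regions: list[GenomicInterval]
    ) -> "RegionMask":
        merged = merge_intervals(list(regions))
        if len(merged) < len(regions):
            logger.info(
                "mask %s: merged %d input regions into %d",
                name.value, len(regions), len(merged),
            )
        return cls(name=name, regions=merged)

    def overlap_len(self, interval: GenomicInterval) -> int:
        """Total masked bases inside ``interval`` (regions are disjoint)."""
        return sum(r.overlap_len(interval) for r in self.regions)

    def overlaps(self, interval: GenomicInterval) -> bool:
        return any(r.overlaps(interval) for r in self.regions)
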