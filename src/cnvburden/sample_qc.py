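"""Sample-level quality control for array CNV analysis.

Three families of exclusions are applied before any CNV statistics:

1. array-quality metrics (chip call rate < 97%, LRR SD > 0.27, BAF SD > 0.17,
   |wave factor| > 0.04);
2. per-algorithm call-count outliers (count exceeding Q3 + 3*IQR of the
   cohort distribution, any algorithm);
3. karyotype-scale events (any single CNV > 7.5 Mb) and excessive aggregate
   CNV length per sample.

All comparisons are strict inequalities.  Flagging operations are idempotent,
preserve input order and never modify call lists, only flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import defaultdict

import numpy as np

from .core import (
    Algorithm,
    CnvCall,
    DISCOVERY_ALGORITHMS,
    ExclusionFlag,
    SampleRecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """Sample-QC thresholds; defaults follow common Illumina-array practice."""

    min_call_rate: float = 0.97
    max_lrr_sd: float = 0.27
    max_baf_sd: float = 0.17
    max_abs_wave_factor: float = 0.04
    outlier_multiplier: float = 3.0
    karyotype_size_bp: int = 7_500_000
    aggregate_length_bp: int = 10_000_000
    quantile_method: str = "linear"  # numpy quantile method name

    def __post_init__(self) -> None:
        for name in (
            "min_call_rate", "max_lrr_sd", "max_baf_sd", "max_abs_wave_factor",
            "outlier_multiplier", "karyotype_size_bp", "aggregate_length_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")


def apply_metric_qc(
    samples: list[SampleRecord], thr: QcThresholds | None = None
) -> list[SampleRecord]:
    """Flag samples whose array metrics violate any QC threshold.

    The wave-factor rule is two-sided: |wave factor| > threshold excludes.
    Returns a new list in input order; unflagged samples pass through
    unchanged.  A missing (NaN) metric raises, naming the sample.
    """
    thr = thr or QcThresholds()
    out: list[SampleRecord] = []
    for s in samples:
        metrics = (s.call_rate, s.lrr_sd, s.baf_sd, s.wave_factor)
        if any(np.isnan(m) for m in metrics):
            raise ValueError(f"sample {s.sample_id}: missing QC metric")
        fails = (
            s.call_rate < thr.min_call_rate
            or s.lrr_sd > thr.max_lrr_sd
            or s.baf_sd > thr.max_baf_sd
            or abs(s.wave_factor) > thr.max_abs_wave_factor
        )
        out.append(s.with_flag(ExclusionFlag.QC_METRIC) if fails else s)
    return out


def call_count_cutoff(counts: list[int], thr: QcThresholds | None = None) -> float:
    """Outlier cutoff Q3 + multiplier * IQR with interpolated quantiles."""
    if len(counts) == 0:
        raise ValueError("cannot compute a call-count cutoff from an empty list")
    thr = thr or QcThresholds()
    q1, q3 = np.quantile(np.asarray(counts, dtype=float), [0.25, 0.75],
                         method=thr.quantile_method)
    return float(q3 + thr.outlier_multiplier * (q3 - q1))


def flag_call_count_outliers(
    samples: list[SampleRecord],
    per_algorithm_counts: dict[Algorithm, dict[str, int]] | None = None,
    thr: QcThresholds | None = None,
) -> tuple[list[SampleRecord], dict[Algorithm, float]]:
    """Flag samples with an excessive call count under ANY discovery algorithm.

    Cutoffs (Q3 + 3*IQR) are computed per algorithm from the cohort's count
    distribution and returned alongside the flagged samples.  A sample at
    exactly the cutoff is kept; the rule is strictly "exceeding".

    ``per_algorithm_counts`` maps algorithm -> {sample_id: count}; when None,
    counts stored on the samples are used.  Samples absent from a count table
    are treated as having zero calls for that algorithm.
    """
    thr = thr or QcThresholds()
    if per_algorithm_counts is None:
        per_algorithm_counts = {
            algo: {
                s.sample_id: s.per_algorithm_call_count.get(algo, 0)
                for s in samples
            }
            for algo in DISCOVERY_ALGORITHMS
        }
    cutoffs: dict[Algorithm, float] = {}
    for algo in DISCOVERY_ALGORITHMS:
        table = per_algorithm_counts.get(algo)
        if not table:
            raise ValueError(f"no call counts available for {algo.value}")
        counts = [table.get(s.sample_id, 0) for s in samples]
        cutoffs[algo] = call_count_cutoff(counts, thr)
        logger.info("call-count cutoff for %s: %.2f", algo.value, cutoffs[algo])
    out: list[SampleRecord] = []
    for s in samples:
        exceeded = any(
            per_algorithm_counts[algo].get(s.sample_id, 0) > cutoffs[algo]
            for algo in DISCOVERY_ALGORITHMS
        )
        out.append(s.with_flag(ExclusionFlag.CALL_COUNT_OUTLIER) if exceeded else s)
    return out, cutoffs


def flag_karyotype_scale(
    samples: list[SampleRecord],
    calls: list[CnvCall],
    thr: QcThresholds | None = None,
) -> list[SampleRecord]:
    """Flag likely karyotype abnormalities and excessive aggregate CNV length.

    A sample owning any single call longer than ``karyotype_size_bp`` gets
    KARYOTYPE_SCALE; a sample whose summed call length exceeds
    ``aggregate_length_bp`` gets AGGREGATE_LENGTH.  Both rules are strict.
    """
    thr = thr or QcThresholds()
    max_len: dict[str, int] = defaultdict(int)
    total_len: dict[str, int] = defaultdict(int)
    for c in calls:
        max_len[c.sample_id] = max(max_len[c.sample_id], c.length)
        total_len[c.sample_id] += c.length
    out: list[SampleRecord] = []
    for s in samples:
        new = s
        if max_len.get(s.sample_id, 0) > thr.karyotype_size_bp:
            new = new.with_flag(ExclusionFlag.KARYOTYPE_SCALE)
        if total_len.get(s.sample_id, 0) > thr.aggregate_length_bp:
            new = new.with_flag(ExclusionFlag.AGGREGATE_LENGTH)
        out.append(new)
    return out


def run_sample_qc(
    samples: list[SampleRecord],
    calls: list[CnvCall],
    thr: QcThresholds | None = None,
) -> tuple[list[SampleRecord], dict[Algorithm, float]]:
    """Apply all sample-QC stages in order; returns flagged samples and cutoffs.

    Call-count cutoffs are computed after metric QC, over the metric-passing
    samples only (configurable by calling the stages individually).
    """
    thr = thr or QcThresholds()
    flagged = apply_metric_qc(samples, thr)
    passing = [s for s in flagged if ExclusionFlag.QC_METRIC not in s.exclusion_flags]
    counts_per_algo: dict[Algorithm, dict[str, int]] = {
        algo: {s.sample_id: 0 for s in samples} for algo in DISCOVERY_ALGORITHMS
    }
    for c in calls:
        if c.algorithm in counts_per_algo:
            counts_per_algo[c.algorithm][c.sample_id] = (
                counts_per_algo[c.algorithm].get(c.sample_id, 0) + 1
            )
    if not passing:
        logger.warning("no samples passed metric QC; skipping outlier rule")
        return flag_karyotype_scale(flagged, calls, thr), {
            algo: float("nan") for algo in DISCOVERY_ALGORITHMS
        }
    # cutoffs from metric-passing cohort, then applied to every sample
    _, cutoffs = flag_call_count_outliers(passing, counts_per_algo, thr)
    out: list[SampleRecord] = []
    for s in flagged:
        exceeded = any(
            counts_per_algo[algo].get(s.sample_id, 0) > cutoffs[algo]
            for algo in DISCOVERY_ALGORITHMS
        )
        out.append(s.with_flag(ExclusionFlag.CALL_COUNT_OUTLIER) if exceeded else s)
    out = flag_karyotype_scale(out, calls, thr)
    return out, cutoffs
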