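"""Stringent consensus CNV calling from multiple algorithms' call sets.

The stringent set is anchored on iPattern: an iPattern call enters the
consensus iff a same-sample, same-state call from PennCNV or QuantiSNP
overlaps it reciprocally by at least ``min_overlap`` (default 50%).  The
consensus interval is the union of the outside boundaries of the iPattern
call and its supporting calls.  CNVpartition input is accepted but never
contributes (it is a visualization aid only).

Call-level filters (probe count, size, QuantiSNP confidence) and region
masks (any-overlap exclusion for centromeric/immunoglobulin regions,
>50%-of-length exclusion for segmental duplications) live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import defaultdict

from intervaltree import IntervalTree

from .core import (
    Algorithm,
    CnvCall,
    CnvState,
    GenomicInterval,
    MaskName,
    RegionMask,
    SUPPORT_ALGORITHMS,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusCall:
    """A merged stringent call: an iPattern seed plus corroborating calls."""

    sample_id: str
    interval: GenomicInterval
    state: CnvState
    supporting_algorithms: frozenset[Algorithm]
    supporting_call_ids: tuple[str, ...]
    n_probes: int
    min_confidence: float
    call_id: str = ""

    def __post_init__(self) -> None:
        if Algorithm.IPATTERN not in self.supporting_algorithms:
            raise ValueError("consensus call must include iPattern support")
        if not (self.supporting_algorithms & SUPPORT_ALGORITHMS):
            raise ValueError(
                "consensus call needs PennCNV or QuantiSNP corroboration"
            )
        if not self.call_id:
            iv = self.interval
            object.__setattr__(
                self, "call_id",
                f"cons:{self.sample_id}:{iv.chrom}:{iv.start}-{iv.end}:{self.state.value}",
            )

    @property
    def length(self) -> int:
        return self.interval.length()


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Shared span as a fraction of each interval's own length.

    Returns ``(overlap/len(a), overlap/len(b))``; (0, 0) across chromosomes.
    """
    ov = a.overlap_len(b)
    return ov / a.length(), ov / b.length()


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min of the two one-sided overlap fractions (the reciprocal criterion)."""
    fa, fb = overlap_fraction(a, b)
    return min(fa, fb)


def build_consensus(
    calls_by_algorithm: dict[Algorithm, list[CnvCall]],
    min_overlap: float = 0.5,
    reciprocal: bool = True,
    boundary_support: str = "all",
) -> list[ConsensusCall]:
    """Build the stringent consensus set from per-algorithm call lists.

    Parameters
    ----------
    calls_by_algorithm
        Map algorithm -> calls.  Only iPattern seeds and PennCNV/QuantiSNP
        support are used; other algorithms are ignored.
    min_overlap
        Overlap fraction in (0, 1] required between seed and support.
    reciprocal
        If True (default) the fraction must hold for BOTH calls' lengths;
        if False, only relative to the iPattern seed's length.
    boundary_support
        ``"all"``: every supporting call extends the union boundary
        (default); ``"first"``: only the best-overlapping supporting call
        does, the rest corroborate without extending.

    Each supported iPattern call yields exactly one consensus call (union
    boundaries); unsupported seeds are dropped.  Output is sorted by
    (sample, chrom, start).  Duplicate call ids raise.
    """
    if not (0 < min_overlap <= 1):
        raise ValueError("min_overlap must be in (0, 1]")
    if boundary_support not in ("all", "first"):
        raise ValueError("boundary_support must be 'all' or 'first'")

    seeds = calls_by_algorithm.get(Algorithm.IPATTERN, [])
    support_calls = [
        c for algo in SUPPORT_ALGORITHMS
        for c in calls_by_algorithm.get(algo, [])
    ]
    all_ids = [c.call_id for c in seeds + support_calls]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("duplicate call ids in input")

    # index support calls per (sample, chrom, state) for fast lookup
    trees: dict[tuple[str, str, CnvState], IntervalTree] = defaultdict(IntervalTree)
    for c in support_calls:
        trees[(c.sample_id, c.interval.chrom, c.state)].addi(
            c.interval.start, c.interval.end, c
        )

    support_usage: dict[str, int] = defaultdict(int)
    out: list[ConsensusCall] = []
    for seed in seeds:
        key = (seed.sample_id, seed.interval.chrom, seed.state)
        matched: list[tuple[float, CnvCall]] = []
        for hit in trees[key].overlap(seed.interval.start, seed.interval.end):
            cand: CnvCall = hit.data
            f_seed, f_cand = overlap_fraction(seed.interval, cand.interval)
            frac = min(f_seed, f_cand) if reciprocal else f_seed
            if frac >= min_overlap:
                matched.append((frac, cand))
        if not matched:
            continue
        matched.sort(key=lambda t: (-t[0], t[1].call_id))
        if boundary_support == "first":
            extenders = [matched[0][1]]
        else:
            extenders = [c for _, c in matched]
        interval = seed.interval
        for c in extenders:
            interval = interval.union_span(c.interval)
        members = [seed] + [c for _, c in matched]
        for _, c in matched:
            support_usage[c.call_id] += 1
            if support_usage[c.call_id] == 2:
                logger.warning(
                    "support call %s corroborates multiple iPattern seeds "
                    "(possible fragmentation)", c.call_id,
                )
        out.append(
            ConsensusCall(
                sample_id=seed.sample_id,
                interval=interval,
                state=seed.state,
                supporting_algorithms=frozenset(c.algorithm for c in members),
                supporting_call_ids=tuple(c.call_id for c in members),
                n_probes=max(c.n_probes for c in members),
                min_confidence=min(c.confidence for c in members),
            )
        )
    out.sort(key=lambda c: (c.sample_id, c.interval.chrom, c.interval.start, c.interval.end))
    return out


def group_calls_by_algorithm(calls: list[CnvCall]) -> dict[Algorithm, list[CnvCall]]:
    grouped: dict[Algorithm, list[CnvCall]] = defaultdict(list)
    for c in calls:
        grouped[c.algorithm].append(c)
    return dict(grouped)


def filter_calls(
    calls: list,
    min_probes: int = 5,
    min_size_bp: int = 100_000,
    min_quantisnp_lbf: float = 15.0,
) -> tuple[list, list[tuple[object, str]]]:
    """Drop low-confidence calls: few probes, small size, weak QuantiSNP score.

    All criteria are strict ("< 5 probes", "< 100 kb", "log Bayes factor
    < 15"); the confidence criterion applies only to QuantiSNP-sourced calls.
    Works on raw :class:`~cnvburden.core.CnvCall` lists and on consensus
    calls (which carry ``n_probes``/``min_confidence``).

    Returns (kept, rejects) where rejects pairs each removed call with a
    reason code.
    """
    kept: list = []
    rejects: list[tuple[object, str]] = []
    for c in calls:
        reasons = []
        if c.n_probes < min_probes:
            reasons.append("min_probes")
        if c.length < min_size_bp:
            reasons.append("min_size")
        algo = getattr(c, "algorithm", None)
        if algo is Algorithm.QUANTISNP and c.confidence < min_quantisnp_lbf:
            reasons.append("quantisnp_lbf")
        if reasons:
            rejects.append((c, "+".join(reasons)))
            logger.debug("filtered call %s: %s", c.call_id, reasons)
        else:
            kept.append(c)
    return kept, rejects


def apply_region_masks(
    calls: list,
    masks: list[RegionMask],
    segdup_max_frac: float = 0.5,
) -> tuple[list, list[tuple[object, str]]]:
    """Remove calls falling in artifact-prone regions.

    Any overlap with a CENTROMERIC or IMMUNOGLOBULIN mask removes the call;
    summed overlap with the SEGDUP mask strictly exceeding ``segdup_max_frac``
    of the call's length removes it.  Custom masks behave like any-overlap.
    """
    kept: list = []
    rejects: list[tuple[object, str]] = []
    for c in calls:
        reason = None
        for mask in masks:
            if mask.name is MaskName.SEGDUP:
                if mask.overlap_len(c.interval) > segdup_max_frac * c.length:
                    reason = "segdup_overlap"
                    break
            else:
                if mask.overlaps(c.interval):
                    reason = f"mask_{mask.name.value.lower()}"
                    break
        if reason:
            rejects.append((c, reason))
        else:
            kept.append(c)
    return kept, rejects
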