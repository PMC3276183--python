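"""Cross-sample CNV locus clustering, carrier frequencies and rarity.

Consensus calls from different samples are grouped into loci by
single-linkage clustering of same-state calls with reciprocal overlap at or
above ``min_overlap`` (the same 50% constant used for consensus).  A locus'
frequency is its carrier count over the combined post-QC cohort; loci above
``max_freq`` (default 1%) are COMMON and excluded from the rare-CNV burden
but retained for per-locus association.  Reference CNV sets (DGV-style
carrier tables) provide external frequencies for candidate screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .consensus import ConsensusCall, reciprocal_overlap
from .core import CnvState, GenomicInterval, Phenotype

RARE = "RARE"
COMMON = "COMMON"


@dataclass
class CnvLocus:
    """A cluster of overlapping same-state calls across samples."""

    locus_id: str
    state: CnvState
    envelope: GenomicInterval
    member_calls: list[ConsensusCall] = field(default_factory=list)
    case_carriers: set[str] = field(default_factory=set)
    control_carriers: set[str] = field(default_factory=set)
    rarity: str | None = None

    @property
    def carrier_count(self) -> int:
        return len(self.case_carriers) + len(self.control_carriers)

    def frequency(self, n_total: int) -> float:
        if n_total <= 0:
            raise ValueError("cohort size must be positive")
        return self.carrier_count / n_total


@dataclass(frozen=True)
class ReferenceRecord:
    interval: GenomicInterval
    state: CnvState
    carrier_count: int
    cohort_size: int

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("reference cohort_size must be positive")
        if self.carrier_count > self.cohort_size:
            raise ValueError("carrier_count exceeds cohort_size")


@dataclass(frozen=True)
class ReferenceCnvSet:
    """A named reference carrier table (e.g. a DGV-like catalogue)."""

    name: str
    records: tuple[ReferenceRecord, ...] = ()


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_loci(
    calls: list[ConsensusCall],
    min_overlap: float = 0.5,
    phenotypes: dict[str, Phenotype] | None = None,
) -> list[CnvLocus]:
    """Single-linkage clustering of same-state calls by reciprocal overlap.

    Two calls join the same locus if a chain of pairwise reciprocal overlaps
    >= ``min_overlap`` connects them.  Multiple calls from one sample collapse
    to a single carrier.  Locus ids are deterministic, derived from the sorted
    envelope coordinates.  ``phenotypes`` (sample -> CASE/CONTROL) populates
    the carrier sets; unknown samples count as controls-of-convenience only if
    listed, otherwise they are ignored with their calls retained as members.
    """
    ordered = sorted(
        calls, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.call_id)
    )
    n = len(ordered)
    uf = _UnionFind(n)
    # sweep: calls sorted by start; only neighbours within the same chrom/state
    # whose spans overlap can satisfy reciprocal overlap
    for i in range(n):
        a = ordered[i]
        for j in range(i + 1, n):
            b = ordered[j]
            if b.interval.chrom != a.interval.chrom:
                break
            if b.interval.start >= a.interval.end:
                break
            if b.state is not a.state:
                continue
            if reciprocal_overlap(a.interval, b.interval) >= min_overlap:
                uf.union(i, j)
    groups: dict[int, list[ConsensusCall]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(ordered[i])

    loci: list[CnvLocus] = []
    for members in groups.values():
        envelope = members[0].interval
        for c in members[1:]:
            envelope = envelope.union_span(c.interval)
        locus = CnvLocus(
            locus_id=(
                f"{members[0].state.value}_{envelope.chrom}_"
                f"{envelope.start}_{envelope.end}"
            ),
            state=members[0].state,
            envelope=envelope,
            member_calls=members,
        )
        for c in members:
            if phenotypes is None:
                continue
            pheno = phenotypes.get(c.sample_id)
            if pheno is Phenotype.CASE:
                locus.case_carriers.add(c.sample_id)
            elif pheno is Phenotype.CONTROL:
                locus.control_carriers.add(c.sample_id)
        loci.append(locus)
    loci.sort(key=lambda l: (l.envelope.chrom, l.envelope.start, l.envelope.end, l.state.value))
    return loci


def classify_rarity(
    loci: list[CnvLocus],
    n_cases: int,
    n_controls: int,
    max_freq: float = 0.01,
    scope: str = "combined",
) -> tuple[list[CnvLocus], list[CnvLocus]]:
    """Partition loci into (rare, common) by carrier frequency.

    ``scope="combined"`` (default, the usual convention): a locus is COMMON
    iff carriers / (n_cases + n_controls) > max_freq.  ``scope="each"``:
    COMMON iff the frequency exceeds max_freq in cases AND in controls
    separately.  Member calls inherit the label via ``locus.rarity``.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("group sizes must be positive")
    if scope not in ("combined", "each"):
        raise ValueError("scope must be 'combined' or 'each'")
    rare: list[CnvLocus] = []
    common: list[CnvLocus] = []
    for locus in loci:
        if scope == "combined":
            is_common = locus.carrier_count / (n_cases + n_controls) > max_freq
        else:
            is_common = (
                len(locus.case_carriers) / n_cases > max_freq
                and len(locus.control_carriers) / n_controls > max_freq
            )
        locus.rarity = COMMON if is_common else RARE
        (common if is_common else rare).append(locus)
    return rare, common


def reference_frequency(
    locus: CnvLocus,
    ref: ReferenceCnvSet,
    min_overlap: float = 0.5,
) -> float:
    """Carrier frequency of a locus in a reference set.

    Sums carrier counts of same-state records overlapping the locus envelope
    reciprocally by >= ``min_overlap``, divided by the (shared) cohort size;
    the total is capped at the cohort size.  Returns 0.0 when nothing matches.
    """
    matched = [
        r for r in ref.records
        if r.state is locus.state
        and reciprocal_overlap(locus.envelope, r.interval) >= min_overlap
    ]
    if not matched:
        return 0.0
    cohort = matched[0].cohort_size
    carriers = min(sum(r.carrier_count for r in matched), cohort)
    return carriers / cohort
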