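"""Gene-content annotation of CNV calls.

Three nested gene sets are computed per call:

* overlapped — the gene span shares at least one base with the call;
* disrupted — a call breakpoint falls strictly inside the gene span
  (the CNV truncates the gene rather than engulfing or missing it);
* exonic — at least one exon shares a base with the call.

Per-sample gene counts for the burden grid use the union of overlapped
genes across a sample's calls, so one gene hit by two calls counts once.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval


@dataclass(frozen=True)
class GeneAnnotation:
    call_id: str
    genes_overlapped: frozenset[str]
    genes_disrupted: frozenset[str]
    genes_with_exons_in_cnv: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes_disrupted <= self.genes_overlapped:
            raise ValueError("disrupted genes must be a subset of overlapped")
        if not self.genes_with_exons_in_cnv <= self.genes_overlapped:
            raise ValueError("exonic genes must be a subset of overlapped")


class GeneIndex:
    """Interval-tree index over gene models for fast repeated annotation."""

    def __init__(self, genes: list[GeneModel]) -> None:
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            self._trees[g.span.chrom].addi(g.span.start, g.span.end, g)

    def query(self, interval: GenomicInterval) -> list[GeneModel]:
        hits = self._trees[interval.chrom].overlap(interval.start, interval.end)
        return sorted((h.data for h in hits), key=lambda g: (g.span.start, g.gene_name))


def annotate_call(call, genes: list[GeneModel] | GeneIndex) -> GeneAnnotation:
    """Annotate one call (anything with ``interval`` and ``call_id``)."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    iv = call.interval
    overlapped: set[str] = set()
    disrupted: set[str] = set()
    exonic: set[str] = set()
    for g in index.query(iv):
        overlapped.add(g.gene_name)
        if (g.span.start < iv.start < g.span.end) or (g.span.start < iv.end < g.span.end):
            disrupted.add(g.gene_name)
        if any(e.overlaps(iv) for e in g.exons):
            exonic.add(g.gene_name)
    return GeneAnnotation(
        call_id=call.call_id,
        genes_overlapped=frozenset(overlapped),
        genes_disrupted=frozenset(disrupted),
        genes_with_exons_in_cnv=frozenset(exonic),
    )


def annotate_calls(calls: list, genes: list[GeneModel] | GeneIndex) -> dict[str, GeneAnnotation]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return {c.call_id: annotate_call(c, index) for c in calls}


def per_sample_gene_count(
    calls_of_sample: list,
    genes: list[GeneModel] | GeneIndex,
    annotations: dict[str, GeneAnnotation] | None = None,
) -> int:
    """Number of distinct genes overlapped by any of a sample's calls."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    hit: set[str] = set()
    for c in calls_of_sample:
        ann = annotations.get(c.call_id) if annotations else None
        if ann is None:
            ann = annotate_call(c, index)
        hit |= ann.genes_overlapped
    return len(hit)
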