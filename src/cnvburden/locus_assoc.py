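"""Per-locus case-control association on carrier counts.

Each CNV locus (common loci included — this analysis deliberately covers
common genic CNVs that the rare-burden grid excludes) is tested with an
uncorrected Pearson chi-square on the 2x2 carrier table and a one-tailed P
oriented toward case enrichment.  Candidate screens reproduce the two
reporting rules for novel events: large case-only loci absent from
reference sets, and genes hit by CNVs in two or more distinct cases but no
controls and absent/rare in every reference set.

A small helper implements the comparative-threshold-cycle (ddCt) relative
dosage arithmetic used when qPCR-validating a locus: relative dosage
= 2**(-ddCt), ~1.5 for a heterozygous duplication (3 vs 2 copies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneAnnotation
from .core import Phenotype
from .frequency import CnvLocus, ReferenceCnvSet, reference_frequency

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusAssociation:
    locus: CnvLocus
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    p_one_tailed: float
    case_freq: float
    control_freq: float


@dataclass(frozen=True)
class DosageMeasurement:
    """A qPCR relative-dosage result for one target gene."""

    target_gene: str
    ddct: float
    replicate_count: int = 3

    @property
    def relative_dosage(self) -> float:
        return relative_dosage(self.ddct)


def carrier_table(
    locus: CnvLocus, n_cases: int, n_controls: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    """2x2 counts [[case carriers, case non-carriers], [ctrl ..., ...]]."""
    a, c = len(locus.case_carriers), len(locus.control_carriers)
    if a > n_cases or c > n_controls:
        raise ValueError(
            f"locus {locus.locus_id}: carrier count exceeds group size"
        )
    return ((a, n_cases - a), (c, n_controls - c))


def chi_square_2x2(table) -> float:
    """Pearson chi-square without continuity correction.

    chi2 = N (ad - bc)^2 / (r1 r2 c1 c2).  Returns NaN with a warning when a
    margin is zero (test undefined).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        logger.warning("chi-square undefined: zero margin in %s", table)
        return float("nan")
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def one_tailed_p(chi2: float, direction_case_enriched: bool) -> float:
    """One-tailed P from the 1-df chi-square distribution.

    Half the two-sided tail when the observed direction matches case
    enrichment, 1 minus that half otherwise; chi2 = 0 gives exactly 0.5.
    """
    if np.isnan(chi2):
        return float("nan")
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    half = stats.chi2.sf(chi2, df=1) / 2.0
    return half if direction_case_enriched else 1.0 - half


def associate_locus(
    locus: CnvLocus, n_cases: int, n_controls: int
) -> LocusAssociation:
    table = carrier_table(locus, n_cases, n_controls)
    chi2 = chi_square_2x2(table)
    case_freq = table[0][0] / n_cases
    control_freq = table[1][0] / n_controls
    return LocusAssociation(
        locus=locus,
        table=table,
        chi2=chi2,
        p_one_tailed=one_tailed_p(chi2, case_freq >= control_freq),
        case_freq=case_freq,
        control_freq=control_freq,
    )


def associate_loci(
    loci: list[CnvLocus],
    n_cases: int,
    n_controls: int,
    refs: list[ReferenceCnvSet] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Association table over all loci (common variants included).

    No multiple-testing correction by default (locus P values are reported
    as nominal); ``bh_correct=True`` adds a Benjamini-Hochberg column.
    """
    rows = []
    for locus in loci:
        assoc = associate_locus(locus, n_cases, n_controls)
        row = {
            "locus_id": locus.locus_id,
            "chrom": locus.envelope.chrom,
            "start": locus.envelope.start,
            "end": locus.envelope.end,
            "state": locus.state.value,
            "n_case_carriers": len(locus.case_carriers),
            "case_freq": assoc.case_freq,
            "n_control_carriers": len(locus.control_carriers),
            "control_freq": assoc.control_freq,
            "chi2": assoc.chi2,
            "p_one_tailed": assoc.p_one_tailed,
        }
        for ref in refs or []:
            row[f"ref_freq_{ref.name}"] = reference_frequency(locus, ref)
        rows.append(row)
    df = pd.DataFrame(rows)
    if bh_correct and len(df):
        p = df["p_one_tailed"].to_numpy(dtype=float)
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
        bh = np.empty_like(adj)
        bh[order] = adj
        df["p_bh"] = bh
    return df


def candidate_case_only_calls(
    loci: list[CnvLocus],
    size_min: int = 1_000_000,
    refs: list[ReferenceCnvSet] | None = None,
    max_ref_freq: float = 0.0,
) -> list[CnvLocus]:
    """Large loci carried only by cases and absent (or rare) in references.

    ``max_ref_freq=0`` demands absence from every reference set; a small
    positive bound tolerates rare catalogue entries.
    """
    out = []
    for locus in loci:
        if not locus.case_carriers or locus.control_carriers:
            continue
        if locus.envelope.length() < size_min:
            continue
        if any(reference_frequency(locus, ref) > max_ref_freq for ref in refs or []):
            continue
        out.append(locus)
    return out


def candidate_recurrent_genes(
    calls: list,
    annotations: dict[str, GeneAnnotation],
    phenotypes: dict[str, Phenotype],
    refs: list[ReferenceCnvSet] | None = None,
    ref_loci: dict[str, list[CnvLocus]] | None = None,
    min_cases: int = 2,
    max_ref_freq: float = 0.0,
) -> pd.DataFrame:
    """Genes hit by CNVs in >= ``min_cases`` distinct cases and no controls.

    ``ref_loci`` optionally maps gene name -> loci used for the reference
    screen (a gene is excluded when any of its loci is common in any
    reference set).  The report lists carrier samples, call coordinates and
    disruption status per gene.
    """
    gene_case_samples: dict[str, set[str]] = {}
    gene_control_samples: dict[str, set[str]] = {}
    gene_calls: dict[str, list] = {}
    gene_disrupted: dict[str, bool] = {}
    for c in calls:
        ann = annotations.get(c.call_id)
        if ann is None:
            continue
        pheno = phenotypes.get(c.sample_id)
        for gene in ann.genes_overlapped:
            gene_calls.setdefault(gene, []).append(c)
            gene_disrupted[gene] = gene_disrupted.get(gene, False) or (
                gene in ann.genes_disrupted
            )
            if pheno is Phenotype.CASE:
                gene_case_samples.setdefault(gene, set()).add(c.sample_id)
            elif pheno is Phenotype.CONTROL:
                gene_control_samples.setdefault(gene, set()).add(c.sample_id)
    rows = []
    for gene, case_samples in sorted(gene_case_samples.items()):
        if len(case_samples) < min_cases:
            continue
        if gene_control_samples.get(gene):
            continue
        if refs and ref_loci and gene in ref_loci:
            if any(
                reference_frequency(locus, ref) > max_ref_freq
                for locus in ref_loci[gene]
                for ref in refs
            ):
                continue
        rows.append({
            "gene": gene,
            "n_case_carriers": len(case_samples),
            "case_samples": ",".join(sorted(case_samples)),
            "calls": ";".join(
                str(c.interval) for c in gene_calls[gene]
                if c.sample_id in case_samples
            ),
            "disrupted": gene_disrupted[gene],
        })
    return pd.DataFrame(rows, columns=[
        "gene", "n_case_carriers", "case_samples", "calls", "disrupted",
    ])


def relative_dosage(ddct: float) -> float:
    """ddCt relative dosage 2**(-ddCt); 1.0 at the calibrator, ~1.5 for 3/2 copies."""
    return float(2.0 ** (-ddct))
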