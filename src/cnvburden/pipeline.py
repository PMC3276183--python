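"""End-to-end orchestration: QC -> consensus -> frequency -> burden + association.

The pipeline can run fully in memory (:func:`run_cohort`, used by the tests
and the simulator round trip) or from files via a YAML-backed
:class:`PipelineConfig` (:func:`run_pipeline`, used by the CLI).  Every run
emits a manifest recording the resolved configuration, the seed, and the
sample/call funnel counts at each stage, sufficient to re-derive every
denominator used in any reported frequency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cnv_io
from .annotation import GeneIndex, annotate_calls
from .burden import BurdenResults, CnvBurdenModel
from .consensus import (
    apply_region_masks,
    build_consensus,
    filter_calls,
)
from .core import (
    Algorithm,
    CnvState,
    GenomicInterval,
    MaskName,
    Phenotype,
    RegionMask,
)
from .frequency import (
    CnvLocus,
    ReferenceCnvSet,
    ReferenceRecord,
    classify_rarity,
    cluster_loci,
)
from .locus_assoc import (
    associate_loci,
    candidate_case_only_calls,
    candidate_recurrent_genes,
)
from .sample_qc import QcThresholds, run_sample_qc

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (one YAML key per field)."""

    samples: str
    call_files: dict[str, str]  # algorithm name -> calls TSV
    out_dir: str
    masks: dict[str, str] = field(default_factory=dict)  # mask name -> BED
    genes: str | None = None
    references: str | None = None
    min_overlap: float = 0.5
    max_freq: float = 0.01
    rare_scope: str = "combined"
    min_probes: int = 5
    min_size_bp: int = 100_000
    min_quantisnp_lbf: float = 15.0
    segdup_max_frac: float = 0.5
    permutations: int = 100_000
    seed: int = 17
    qc: QcThresholds = field(default_factory=QcThresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        qc = QcThresholds(**raw.pop("qc", {}))
        return cls(qc=qc, **raw)

    def validate_paths(self) -> None:
        missing = [
            p for p in (
                [self.samples, *self.call_files.values(), *self.masks.values()]
                + ([self.genes] if self.genes else [])
                + ([self.references] if self.references else [])
            )
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def case_control_shares(case_calls: int, control_calls: int) -> tuple[float, float]:
    """Percent shares of the stringent call set held by each group (1 dp)."""
    total = case_calls + control_calls
    if total == 0:
        return float("nan"), float("nan")
    return round(100 * case_calls / total, 1), round(100 * control_calls / total, 1)


@dataclass
class PipelineResult:
    manifest: dict
    qc_report: pd.DataFrame
    consensus_calls: list
    rejected_calls: pd.DataFrame
    loci: list[CnvLocus]
    loci_table: pd.DataFrame
    burden: BurdenResults | None
    association: pd.DataFrame
    candidates_case_only: list[CnvLocus]
    candidate_genes: pd.DataFrame


def read_references(path: str | Path) -> list[ReferenceCnvSet]:
    df = pd.read_csv(path, sep="\t")
    sets = []
    for name, grp in df.groupby("set_name", sort=True):
        records = tuple(
            ReferenceRecord(
                interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                state=CnvState(str(r.state).upper()),
                carrier_count=int(r.carrier_count),
                cohort_size=int(r.cohort_size),
            )
            for r in grp.itertuples()
        )
        sets.append(ReferenceCnvSet(name=str(name), records=records))
    return sets


def run_cohort(
    samples,
    calls_by_algorithm,
    masks: list[RegionMask] | None = None,
    genes=None,
    references: list[ReferenceCnvSet] | None = None,
    qc_thresholds: QcThresholds | None = None,
    min_overlap: float = 0.5,
    max_freq: float = 0.01,
    rare_scope: str = "combined",
    min_probes: int = 5,
    min_size_bp: int = 100_000,
    min_quantisnp_lbf: float = 15.0,
    segdup_max_frac: float = 0.5,
    permutations: int = 10_000,
    seed: int = 17,
    run_burden: bool = True,
) -> PipelineResult:
    """Run the full analysis on in-memory objects.

    Stage order: sample QC (metrics, call-count outliers, karyotype scale)
    -> call-level filters -> region masks -> stringent consensus (size
    re-checked after boundary union) -> locus clustering and rarity ->
    rare-CNV burden grid -> per-locus association and candidate reports.
    """
    masks = masks or []
    all_calls = [c for calls in calls_by_algorithm.values() for c in calls]
    manifest: dict = {
        "seed": seed,
        "permutations": permutations,
        "n_samples_input": len(samples),
        "calls_input": {a.value: len(v) for a, v in calls_by_algorithm.items()},
    }

    # ---- sample QC -------------------------------------------------------
    flagged, cutoffs = run_sample_qc(samples, all_calls, qc_thresholds)
    qc_report = pd.DataFrame([
        {
            "sample_id": s.sample_id,
            "phenotype": s.phenotype.value,
            "call_rate": s.call_rate,
            "lrr_sd": s.lrr_sd,
            "baf_sd": s.baf_sd,
            "wave_factor": s.wave_factor,
            "flags": ",".join(sorted(f.value for f in s.exclusion_flags)),
            "passes_qc": s.passes_qc,
        }
        for s in flagged
    ])
    passing = [s for s in flagged if s.passes_qc]
    passing_ids = {s.sample_id for s in passing}
    n_cases = sum(1 for s in passing if s.phenotype is Phenotype.CASE)
    n_controls = len(passing) - n_cases
    manifest["call_count_cutoffs"] = {a.value: c for a, c in cutoffs.items()}
    manifest["n_samples_qc_passed"] = len(passing)
    manifest["n_cases"] = n_cases
    manifest["n_controls"] = n_controls

    # ---- call-level filters and masks ------------------------------------
    rejects_rows = []
    filtered_by_algo = {}
    for algo, calls in calls_by_algorithm.items():
        calls = [c for c in calls if c.sample_id in passing_ids]
        kept, rej = filter_calls(calls, min_probes, min_size_bp, min_quantisnp_lbf)
        kept, rej2 = apply_region_masks(kept, masks, segdup_max_frac)
        filtered_by_algo[algo] = kept
        rejects_rows += [
            {"call_id": c.call_id, "stage": "call_filter", "reason": r}
            for c, r in rej
        ] + [
            {"call_id": c.call_id, "stage": "region_mask", "reason": r}
            for c, r in rej2
        ]
    manifest["calls_after_filters"] = {
        a.value: len(v) for a, v in filtered_by_algo.items()
    }

    # ---- stringent consensus ---------------------------------------------
    consensus = build_consensus(filtered_by_algo, min_overlap=min_overlap)
    # boundary union can only grow intervals, but re-check size for safety
    consensus, rej3 = filter_calls(consensus, min_probes=1, min_size_bp=min_size_bp,
                                   min_quantisnp_lbf=float("-inf"))
    rejects_rows += [
        {"call_id": c.call_id, "stage": "post_merge_size", "reason": r}
        for c, r in rej3
    ]
    manifest["n_consensus_calls"] = len(consensus)
    phenotypes = {s.sample_id: s.phenotype for s in passing}
    case_calls = sum(
        1 for c in consensus if phenotypes.get(c.sample_id) is Phenotype.CASE
    )
    control_calls = len(consensus) - case_calls
    manifest["consensus_case_calls"] = case_calls
    manifest["consensus_control_calls"] = control_calls
    if consensus:
        case_share, control_share = case_control_shares(case_calls, control_calls)
        manifest["consensus_case_share_pct"] = case_share
        manifest["consensus_control_share_pct"] = control_share

    # ---- loci, rarity -----------------------------------------------------
    loci = cluster_loci(consensus, min_overlap=min_overlap, phenotypes=phenotypes)
    if n_cases and n_controls:
        rare, common = classify_rarity(loci, n_cases, n_controls, max_freq, rare_scope)
    else:
        rare, common = [], []
    rare_calls = [c for locus in rare for c in locus.member_calls]
    manifest["n_loci"] = len(loci)
    manifest["n_rare_loci"] = len(rare)
    manifest["n_common_loci"] = len(common)
    manifest["n_rare_calls"] = len(rare_calls)
    manifest["n_rare_dels"] = sum(1 for c in rare_calls if c.state is CnvState.DEL)
    manifest["n_rare_dups"] = sum(1 for c in rare_calls if c.state is CnvState.DUP)

    loci_table = pd.DataFrame([
        {
            "locus_id": l.locus_id, "chrom": l.envelope.chrom,
            "start": l.envelope.start, "end": l.envelope.end,
            "state": l.state.value,
            "n_case_carriers": len(l.case_carriers),
            "n_control_carriers": len(l.control_carriers),
            "freq": l.frequency(len(passing)) if passing else float("nan"),
            "rarity": l.rarity,
        }
        for l in loci
    ])

    # ---- burden -----------------------------------------------------------
    burden = None
    if run_burden and passing and n_cases and n_controls:
        gene_index = GeneIndex(genes) if genes else None
        model = CnvBurdenModel(passing, rare_calls, gene_index)
        burden = model.fit(B=permutations, seed=seed)

    # ---- association and candidates ---------------------------------------
    refs = references or []
    if n_cases and n_controls:
        association = associate_loci(loci, n_cases, n_controls, refs)
        candidates = candidate_case_only_calls(loci, refs=refs)
        gene_index = GeneIndex(genes) if genes else None
        if gene_index is not None:
            annotations = annotate_calls(consensus, gene_index)
            candidate_genes = candidate_recurrent_genes(
                consensus, annotations, phenotypes, refs=refs,
            )
        else:
            candidate_genes = pd.DataFrame()
    else:
        association = pd.DataFrame()
        candidates = []
        candidate_genes = pd.DataFrame()

    return PipelineResult(
        manifest=manifest,
        qc_report=qc_report,
        consensus_calls=consensus,
        rejected_calls=pd.DataFrame(
            rejects_rows, columns=["call_id", "stage", "reason"]
        ),
        loci=loci,
        loci_table=loci_table,
        burden=burden,
        association=association,
        candidates_case_only=candidates,
        candidate_genes=candidate_genes,
    )


_MASK_NAMES = {m.value.lower(): m for m in MaskName}
_ALGO_NAMES = {a.value.lower(): a for a in Algorithm}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the file-based pipeline and write the report bundle."""
    config.validate_paths()
    samples = cnv_io.read_samples(config.samples)
    calls_by_algorithm = {}
    for algo_name, path in config.call_files.items():
        algo = _ALGO_NAMES.get(algo_name.lower())
        if algo is None:
            raise ValueError(f"unknown algorithm {algo_name!r} in config")
        dialect = "plink_cnv" if str(path).endswith(".cnv") else "tsv"
        calls_by_algorithm[algo] = cnv_io.read_calls(path, dialect, algorithm=algo)
    masks = [
        cnv_io.read_mask(path, _MASK_NAMES.get(name.lower(), MaskName.CUSTOM))
        for name, path in config.masks.items()
    ]
    genes = cnv_io.read_genes(config.genes) if config.genes else None
    references = read_references(config.references) if config.references else None

    result = run_cohort(
        samples, calls_by_algorithm, masks=masks, genes=genes,
        references=references, qc_thresholds=config.qc,
        min_overlap=config.min_overlap, max_freq=config.max_freq,
        rare_scope=config.rare_scope, min_probes=config.min_probes,
        min_size_bp=config.min_size_bp,
        min_quantisnp_lbf=config.min_quantisnp_lbf,
        segdup_max_frac=config.segdup_max_frac,
        permutations=config.permutations, seed=config.seed,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    result.rejected_calls.to_csv(out / "rejected_calls.tsv", sep="\t", index=False)
    result.loci_table.to_csv(out / "loci.tsv", sep="\t", index=False)
    result.association.to_csv(out / "association.tsv", sep="\t", index=False)
    result.candidate_genes.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
    _write_consensus_tsv(result.consensus_calls, out / "stringent_calls.tsv")
    if result.burden is not None:
        result.burden.table.to_csv(out / "burden_grid.tsv", sep="\t", index=False)
        (out / "burden_summary.txt").write_text(result.burden.summary() + "\n")
    result.manifest["outputs"] = sorted(p.name for p in out.iterdir())
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    return result


def _write_consensus_tsv(calls, path: Path) -> None:
    rows = [
        {
            "call_id": c.call_id, "sample_id": c.sample_id,
            "chrom": c.interval.chrom, "start": c.interval.start + 1,
            "end": c.interval.end, "state": c.state.value.lower(),
            "n_probes": c.n_probes, "min_confidence": c.min_confidence,
            "supporting_algorithms": ",".join(
                sorted(a.value for a in c.supporting_algorithms)
            ),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=[
        "call_id", "sample_id", "chrom", "start", "end", "state",
        "n_probes", "min_confidence", "supporting_algorithms",
    ]).to_csv(path, sep="\t", index=False)
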