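"""Synthetic CNV cohort generator.

Produces complete, self-consistent inputs for every pipeline stage — probe
map, case-control samples with array-QC metrics, per-algorithm CNV call
sets sharing true events, region masks, gene models, reference carrier
tables, and a truth table — on a desk-scale toy genome (2 chromosomes x
25 Mb, evenly spaced probes), so the absolute size thresholds (100 kb,
500 kb, 1 Mb, 7.5 Mb) stay meaningful without rescaling.

The generative model:

* each sample carries Poisson(background_cnv_rate) rare background events
  with log-normal sizes (calibrated so roughly 88% of rare calls fall in
  100-500 kb) placed uniformly away from masks;
* one (configurable) spiked duplication locus is carried by
  Binomial(n, case_freq) cases and Binomial(n, control_freq) controls,
  emulating a common genic duplication enriched in cases;
* every true event enters each caller's output independently with that
  caller's sensitivity, with Gaussian boundary jitter snapped to probe
  positions (so the union-of-boundaries merge is exercised with
  non-identical supporting calls);
* a configurable fraction of samples fails at least one array-QC
  threshold, and a few outlier samples receive enough junk calls to exceed
  the Q3 + 3*IQR per-algorithm cutoff by construction.

Same config + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import reciprocal_overlap
from .core import (
    Algorithm,
    CnvCall,
    CnvState,
    GeneModel,
    GenomicInterval,
    MaskName,
    Phenotype,
    RegionMask,
    SampleRecord,
)
from .frequency import ReferenceCnvSet, ReferenceRecord
from . import io as cnv_io

CHROM_LENGTH = 25_000_000
CHROMS = ("1", "2")


@dataclass(frozen=True)
class TrueLocus:
    """A planted CNV locus with per-group carrier frequencies."""

    interval: GenomicInterval
    state: CnvState
    case_freq: float
    control_freq: float
    gene_count: int = 0
    name: str = "spiked"

    def __post_init__(self) -> None:
        if not (0 <= self.case_freq <= 1 and 0 <= self.control_freq <= 1):
            raise ValueError("carrier frequencies must be in [0, 1]")


def default_spiked_locus() -> TrueLocus:
    """A ~470 kb duplication carried by 2.6% of cases and 0.8% of controls."""
    return TrueLocus(
        interval=GenomicInterval("2", 20_300_000, 20_770_000),
        state=CnvState.DUP,
        case_freq=0.026,
        control_freq=0.008,
        gene_count=5,
        name="spiked_dup",
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 392
    n_controls: int = 357
    n_probes: int = 10_000
    true_locus_table: tuple[TrueLocus, ...] = field(
        default_factory=lambda: (default_spiked_locus(),)
    )
    caller_sensitivity: tuple[tuple[Algorithm, float], ...] = (
        (Algorithm.IPATTERN, 0.95),
        (Algorithm.PENNCNV, 0.85),
        (Algorithm.QUANTISNP, 0.85),
    )
    boundary_jitter_sd_bp: float = 5_000.0
    qc_fail_fraction: float = 0.05
    outlier_sample_count: int = 2
    background_cnv_rate: float = 0.98
    del_fraction: float = 0.38  # paper-scale DEL share among rare calls
    size_log_mean: float = float(np.log(180_000))
    size_log_sd: float = 0.8
    min_event_size: int = 100_000
    max_event_size: int = 5_000_000
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("qc_fail_fraction", "del_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for _, s in self.caller_sensitivity:
            if not 0 <= s <= 1:
                raise ValueError("caller sensitivities must be in [0, 1]")
        for locus in self.true_locus_table:
            if locus.interval.chrom not in CHROMS or locus.interval.end > CHROM_LENGTH:
                raise ValueError(
                    f"true locus {locus.name} lies outside the toy genome"
                )

    @property
    def sensitivity(self) -> dict[Algorithm, float]:
        return dict(self.caller_sensitivity)

    @property
    def probe_spacing(self) -> int:
        return (CHROM_LENGTH * len(CHROMS)) // self.n_probes


@dataclass
class CohortData:
    """Everything one simulated cohort comprises."""

    config: SimulationConfig
    samples: list[SampleRecord]
    calls_by_algorithm: dict[Algorithm, list[CnvCall]]
    masks: list[RegionMask]
    genes: list[GeneModel]
    references: list[ReferenceCnvSet]
    truth: pd.DataFrame

    @property
    def phenotypes(self) -> dict[str, Phenotype]:
        return {s.sample_id: s.phenotype for s in self.samples}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every artifact in the formats the pipeline reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["samples"] = cnv_io.write_samples(self.samples, out / "samples.tsv")
        for algo, calls in sorted(self.calls_by_algorithm.items(), key=lambda kv: kv[0].value):
            paths[f"calls_{algo.value}"] = cnv_io.write_calls(
                calls, out / f"calls_{algo.value.lower()}.tsv"
            )
        for mask in self.masks:
            paths[f"mask_{mask.name.value}"] = cnv_io.write_mask(
                mask, out / f"mask_{mask.name.value.lower()}.bed"
            )
        paths["genes"] = cnv_io.write_genes(self.genes, out / "genes.bed")
        ref_rows = [
            {
                "set_name": ref.name, "chrom": r.interval.chrom,
                "start": r.interval.start, "end": r.interval.end,
                "state": r.state.value, "carrier_count": r.carrier_count,
                "cohort_size": r.cohort_size,
            }
            for ref in self.references for r in ref.records
        ]
        ref_path = out / "references.tsv"
        pd.DataFrame(ref_rows).to_csv(ref_path, sep="\t", index=False)
        paths["references"] = ref_path
        truth_path = out / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        return paths


def _default_masks() -> list[RegionMask]:
    return [
        RegionMask.from_intervals(MaskName.SEGDUP, [
            GenomicInterval("1", 5_000_000, 5_400_000),
            GenomicInterval("2", 8_000_000, 8_300_000),
        ]),
        RegionMask.from_intervals(MaskName.CENTROMERIC, [
            GenomicInterval("1", 12_400_000, 12_600_000),
            GenomicInterval("2", 12_400_000, 12_600_000),
        ]),
        RegionMask.from_intervals(MaskName.IMMUNOGLOBULIN, [
            GenomicInterval("2", 2_000_000, 2_200_000),
        ]),
    ]


def _default_genes() -> list[GeneModel]:
    """Genes tiled every 100 kb (30 kb long, 5 exons of 2 kb)."""
    genes: list[GeneModel] = []
    idx = 0
    for chrom in CHROMS:
        for start in range(50_000, CHROM_LENGTH - 50_000, 100_000):
            idx += 1
            exons = tuple(
                GenomicInterval(chrom, start + k * 6_000, start + k * 6_000 + 2_000)
                for k in range(5)
            )
            genes.append(GeneModel(
                gene_name=f"GENE{idx:04d}",
                span=GenomicInterval(chrom, start, start + 30_000),
                exons=exons,
            ))
    return genes


def _snap(pos: int, spacing: int) -> int:
    """Snap a position to the probe grid (probes sit at spacing/2 + k*spacing)."""
    half = spacing // 2
    k = round((pos - half) / spacing)
    return int(half + k * spacing)


def _in_any_mask(iv: GenomicInterval, masks: list[RegionMask]) -> bool:
    return any(m.overlaps(iv) for m in masks)


def generate_cohort(config: SimulationConfig | None = None) -> CohortData:
    """Simulate a full case-control cohort; deterministic for a given config."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    spacing = config.probe_spacing
    masks = _default_masks()
    genes = _default_genes()

    n_total = config.n_cases + config.n_controls
    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    phenotypes = (
        [Phenotype.CASE] * config.n_cases + [Phenotype.CONTROL] * config.n_controls
    )

    # --- true events ------------------------------------------------------
    truth_rows: list[dict] = []
    events: list[tuple[str, GenomicInterval, CnvState, str]] = []

    for locus in config.true_locus_table:
        for sid, pheno in zip(sample_ids, phenotypes):
            freq = locus.case_freq if pheno is Phenotype.CASE else locus.control_freq
            if rng.random() < freq:
                events.append((sid, locus.interval, locus.state, locus.name))

    for sid in sample_ids:
        n_events = rng.poisson(config.background_cnv_rate)
        for _ in range(n_events):
            iv = _draw_background_interval(rng, config, masks)
            state = CnvState.DEL if rng.random() < config.del_fraction else CnvState.DUP
            events.append((sid, iv, state, "background"))

    for k, (sid, iv, state, kind) in enumerate(events):
        truth_rows.append({
            "event_id": f"T{k:05d}", "sample_id": sid,
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "state": state.value, "kind": kind,
        })

    # --- per-caller emission ---------------------------------------------
    calls_by_algorithm: dict[Algorithm, list[CnvCall]] = {
        algo: [] for algo in config.sensitivity
    }
    counter = 0
    for sid, iv, state, _kind in events:
        for algo, sens in config.caller_sensitivity:
            if rng.random() >= sens:
                continue
            counter += 1
            call = _emit_call(rng, config, sid, iv, state, algo, spacing, counter)
            calls_by_algorithm[algo].append(call)

    # --- samples with QC metrics -----------------------------------------
    samples = _draw_samples(rng, config, sample_ids, phenotypes)

    # --- outlier samples: junk calls exceeding the count cutoff -----------
    outliers = sample_ids[: config.outlier_sample_count]
    for sid in outliers:
        for algo in calls_by_algorithm:
            for _ in range(50):
                counter += 1
                start = _snap(int(rng.integers(1_000_000, CHROM_LENGTH - 1_000_000)), spacing)
                size = int(rng.integers(2, 5)) * spacing  # tiny, filtered later
                chrom = CHROMS[int(rng.integers(len(CHROMS)))]
                state = CnvState.DEL if rng.random() < 0.5 else CnvState.DUP
                calls_by_algorithm[algo].append(CnvCall(
                    sample_id=sid,
                    interval=GenomicInterval(chrom, start, start + size),
                    state=state,
                    n_probes=max(2, size // spacing),
                    confidence=20.0,
                    algorithm=algo,
                    call_id=f"{algo.value}:junk:{counter}",
                ))

    references = [_default_reference(config)]
    truth = pd.DataFrame(
        truth_rows,
        columns=["event_id", "sample_id", "chrom", "start", "end", "state", "kind"],
    )
    return CohortData(
        config=config, samples=samples, calls_by_algorithm=calls_by_algorithm,
        masks=masks, genes=genes, references=references, truth=truth,
    )


def _draw_background_interval(
    rng: np.random.Generator, config: SimulationConfig, masks: list[RegionMask]
) -> GenomicInterval:
    spacing = config.probe_spacing
    spiked = [l.interval for l in config.true_locus_table]
    for _ in range(1000):
        size = float(rng.lognormal(config.size_log_mean, config.size_log_sd))
        if not (config.min_event_size <= size <= config.max_event_size):
            continue
        size_bp = max(spacing * 2, _snap(int(size), spacing) - spacing // 2)
        chrom = CHROMS[int(rng.integers(len(CHROMS)))]
        start = _snap(int(rng.integers(0, CHROM_LENGTH - int(size_bp))), spacing)
        if start < 0:
            continue
        iv = GenomicInterval(chrom, start, start + size_bp)
        if iv.end > CHROM_LENGTH:
            continue
        if _in_any_mask(iv, masks):
            continue
        if any(iv.overlaps(s) for s in spiked):
            continue
        return iv
    raise RuntimeError("could not place a background event clear of masks")


def _emit_call(
    rng: np.random.Generator,
    config: SimulationConfig,
    sid: str,
    iv: GenomicInterval,
    state: CnvState,
    algo: Algorithm,
    spacing: int,
    counter: int,
) -> CnvCall:
    jitter = config.boundary_jitter_sd_bp
    start, end = iv.start, iv.end
    if jitter > 0:
        start = _snap(int(start + rng.normal(0, jitter)), spacing)
        end = _snap(int(end + rng.normal(0, jitter)), spacing)
    start = max(0, start)
    end = min(CHROM_LENGTH, end)
    if end <= start + spacing:
        end = start + 2 * spacing
    n_probes = max(2, (end - start) // spacing)
    if algo is Algorithm.QUANTISNP:
        confidence = float(20.0 + rng.random() * 40.0)  # log Bayes factor >= 20
    else:
        confidence = float(10.0 + rng.random() * 80.0)
    return CnvCall(
        sample_id=sid,
        interval=GenomicInterval(iv.chrom, start, end),
        state=state,
        n_probes=int(n_probes),
        confidence=confidence,
        algorithm=algo,
        call_id=f"{algo.value}:{sid}:{counter}",
    )


def _draw_samples(
    rng: np.random.Generator,
    config: SimulationConfig,
    sample_ids: list[str],
    phenotypes: list[Phenotype],
) -> list[SampleRecord]:
    n = len(sample_ids)
    fail = rng.random(n) < config.qc_fail_fraction
    samples = []
    for i, (sid, pheno) in enumerate(zip(sample_ids, phenotypes)):
        call_rate = float(0.985 + rng.random() * 0.014)
        lrr_sd = float(0.10 + rng.random() * 0.10)
        baf_sd = float(0.03 + rng.random() * 0.07)
        wave = float(rng.normal(0, 0.012))
        wave = max(-0.035, min(0.035, wave))
        if fail[i]:
            which = int(rng.integers(4))
            if which == 0:
                call_rate = float(0.94 + rng.random() * 0.02)   # < 0.97
            elif which == 1:
                lrr_sd = float(0.28 + rng.random() * 0.05)      # > 0.27
            elif which == 2:
                baf_sd = float(0.18 + rng.random() * 0.05)      # > 0.17
            else:
                wave = float(rng.choice([-1, 1]) * (0.045 + rng.random() * 0.02))
        samples.append(SampleRecord(
            sample_id=sid, phenotype=pheno,
            sex="F" if rng.random() < 0.7 else "M",
            call_rate=call_rate, lrr_sd=lrr_sd, baf_sd=baf_sd, wave_factor=wave,
        ))
    return samples


def _default_reference(config: SimulationConfig) -> ReferenceCnvSet:
    """DGV-like catalogue: the spiked duplication seen in 24 of 5056 people."""
    records = tuple(
        ReferenceRecord(
            interval=locus.interval, state=locus.state,
            carrier_count=24, cohort_size=5056,
        )
        for locus in config.true_locus_table
    )
    return ReferenceCnvSet(name="DGV-like", records=records)


def truth_eval(
    stage_calls: dict[str, list],
    truth: pd.DataFrame,
    min_overlap: float = 0.5,
    kinds: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-stage recall/precision of pipeline calls against the truth table.

    A pipeline call matches a truth event when sample and state agree and
    the intervals overlap reciprocally by >= ``min_overlap``.  ``kinds``
    restricts the truth events considered (e.g. only ``("background",)``).
    """
    rows = []
    t = truth if kinds is None else truth[truth["kind"].isin(kinds)]
    truth_events = [
        (r.sample_id, GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
         CnvState(r.state))
        for r in t.itertuples()
    ]
    for stage, calls in stage_calls.items():
        matched_truth = [False] * len(truth_events)
        tp_calls = 0
        for c in calls:
            hit = False
            for k, (sid, iv, state) in enumerate(truth_events):
                if c.sample_id != sid or c.state is not state:
                    continue
                if reciprocal_overlap(c.interval, iv) >= min_overlap:
                    matched_truth[k] = True
                    hit = True
            if hit:
                tp_calls += 1
        n_truth, n_called = len(truth_events), len(calls)
        rows.append({
            "stage": stage,
            "n_truth": n_truth,
            "n_called": n_called,
            "truth_recovered": int(sum(matched_truth)),
            "recall": sum(matched_truth) / n_truth if n_truth else float("nan"),
            "precision": tp_calls / n_called if n_called else float("nan"),
        })
    return pd.DataFrame(rows)


def simulate_carrier_counts(
    n_cases: int,
    n_controls: int,
    case_freq: float,
    control_freq: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Binomial carrier counts for one locus (locus-level shortcut)."""
    return (
        int(rng.binomial(n_cases, case_freq)),
        int(rng.binomial(n_controls, control_freq)),
    )
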