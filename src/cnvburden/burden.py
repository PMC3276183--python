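"""Genome-wide rare-CNV burden testing with one-sided permutation P values.

For every stratum (CNV type x size class) and burden metric (per-sample CNV
rate, carrier proportion, total and average CNV size in kb, genes hit), the
case/control ratio of group means is tested against the null of
exchangeable phenotype labels: labels are permuted B times preserving group
sizes and the one-sided empirical P toward case enrichment is
``(1 + #{permutations with ratio >= observed}) / (B + 1)``.

The gene-count metric additionally gets a corrected P (``p_corr``) that
removes global case-control differences in CNV rate and total size: each
sample's gene count is replaced by its residual from an ordinary
least-squares fit on (rate, total size) — the fit ignores phenotype, so the
residuals are permutation-invariant — and the one-sided mean-difference
statistic on residuals is permuted.  (A ratio of residual means is not
well-defined because residual means can be zero or negative.)

The module exposes both the individual operations and a model-style
wrapper, :class:`CnvBurdenModel`, whose :meth:`~CnvBurdenModel.fit` returns
a :class:`BurdenResults` carrying the full grid with a ``summary()`` table.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneIndex, annotate_calls, per_sample_gene_count
from .core import CnvState, GeneModel, Phenotype, SampleRecord

logger = logging.getLogger(__name__)


class Metric(str, enum.Enum):
    RATE = "RATE"
    SAMPLE_PROPORTION = "SAMPLE_PROPORTION"
    TOTAL_SIZE = "TOTAL_SIZE"
    AVG_SIZE = "AVG_SIZE"
    GENE_COUNT = "GENE_COUNT"


#: (type, size class) grid mirroring the burden tables.
TYPE_STRATA = ("ALL", CnvState.DEL.value, CnvState.DUP.value)
SIZE_STRATA = ("ALL", "100-500kb", ">=500kb", ">=1Mb")


def size_class_membership(length_bp: int) -> tuple[str, ...]:
    """Size classes a call belongs to; >=500kb and >=1Mb are cumulative."""
    classes = ["ALL"]
    if length_bp < 500_000:
        classes.append("100-500kb")
    else:
        classes.append(">=500kb")
        if length_bp >= 1_000_000:
            classes.append(">=1Mb")
    return tuple(classes)


def stratify(calls: list) -> dict[tuple[str, str], list]:
    """Map every (type, size-class) stratum to its call subset."""
    strata: dict[tuple[str, str], list] = {
        (t, s): [] for t in TYPE_STRATA for s in SIZE_STRATA
    }
    for c in calls:
        for t in ("ALL", c.state.value):
            for s in size_class_membership(c.length):
                strata[(t, s)].append(c)
    return strata


def per_sample_metrics(
    samples: list[SampleRecord],
    calls: list,
    gene_index: GeneIndex | None = None,
    annotations: dict | None = None,
) -> pd.DataFrame:
    """Per-sample burden metrics for one call subset.

    Returns a DataFrame indexed by sample_id with columns ``rate`` (call
    count), ``any_cnv`` (0/1), ``total_kb``, ``avg_kb`` (NaN when rate is 0,
    so zero-call samples drop out of average-size group means), and
    ``gene_count`` (0 when no gene index is supplied).  A call referencing an
    unknown sample raises.
    """
    known = {s.sample_id for s in samples}
    by_sample: dict[str, list] = {s.sample_id: [] for s in samples}
    for c in calls:
        if c.sample_id not in known:
            raise ValueError(f"call {c.call_id} references unknown sample {c.sample_id}")
        by_sample[c.sample_id].append(c)
    rows = {}
    for s in samples:
        mine = by_sample[s.sample_id]
        rate = len(mine)
        total_kb = sum(c.length for c in mine) / 1000.0
        gene_count = (
            per_sample_gene_count(mine, gene_index, annotations)
            if gene_index is not None else 0
        )
        rows[s.sample_id] = {
            "rate": float(rate),
            "any_cnv": 1.0 if rate else 0.0,
            "total_kb": total_kb,
            "avg_kb": total_kb / rate if rate else np.nan,
            "gene_count": float(gene_count),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


_METRIC_COLUMN = {
    Metric.RATE: "rate",
    Metric.SAMPLE_PROPORTION: "any_cnv",
    Metric.TOTAL_SIZE: "total_kb",
    Metric.AVG_SIZE: "avg_kb",
    Metric.GENE_COUNT: "gene_count",
}


@dataclass(frozen=True)
class BurdenStat:
    metric: Metric
    type_stratum: str
    size_stratum: str
    case_mean: float
    control_mean: float
    ratio: float  # NaN when control_mean is 0
    n_cnvs: int


@dataclass(frozen=True)
class BurdenResult:
    stat: BurdenStat
    p: float
    p_corr: float | None
    n_permutations: int
    seed: int


def _group_means(values: np.ndarray, is_case: np.ndarray) -> tuple[float, float]:
    """NaN-aware group means (NaN entries drop out of their group's mean)."""
    with np.errstate(invalid="ignore"):
        case_mean = np.nanmean(values[is_case]) if np.any(~np.isnan(values[is_case])) else np.nan
        ctrl_mean = np.nanmean(values[~is_case]) if np.any(~np.isnan(values[~is_case])) else np.nan
    return float(case_mean), float(ctrl_mean)


def burden_ratio(
    metric: Metric,
    values: np.ndarray,
    is_case: np.ndarray,
    type_stratum: str = "ALL",
    size_stratum: str = "ALL",
    n_cnvs: int = 0,
) -> BurdenStat:
    """Case/control ratio of group means for one metric in one stratum.

    ``values`` is the per-sample metric vector aligned with ``is_case``.
    A zero control mean yields ratio NaN (reported NA) with a log message.
    """
    if is_case.all() or (~is_case).all():
        raise ValueError("both phenotype groups must be non-empty")
    case_mean, ctrl_mean = _group_means(values, is_case)
    if ctrl_mean == 0 or np.isnan(ctrl_mean):
        logger.warning("control mean is 0/undefined for %s (%s, %s); ratio NA",
                       metric.value, type_stratum, size_stratum)
        ratio = np.nan
    else:
        ratio = case_mean / ctrl_mean
    return BurdenStat(
        metric=metric, type_stratum=type_stratum, size_stratum=size_stratum,
        case_mean=case_mean, control_mean=ctrl_mean, ratio=float(ratio),
        n_cnvs=n_cnvs,
    )


def _permuted_case_masks(
    n: int, n_cases: int, B: int, rng: np.random.Generator, chunk: int = 2000
):
    """Yield boolean (chunk, n) case-assignment matrices, B rows in total."""
    done = 0
    while done < B:
        b = min(chunk, B - done)
        u = rng.random((b, n))
        idx = np.argpartition(u, n_cases - 1, axis=1)[:, :n_cases]
        mask = np.zeros((b, n), dtype=bool)
        np.put_along_axis(mask, idx, True, axis=1)
        yield mask
        done += b


def _perm_group_means(values: np.ndarray, masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group means per permutation, NaN-aware, vectorized over rows of masks."""
    finite = ~np.isnan(values)
    w = np.where(finite, values, 0.0)
    case_sum = masks @ w
    case_n = masks @ finite.astype(float)
    ctrl_sum = w[finite].sum() - case_sum
    ctrl_n = finite.sum() - case_n
    with np.errstate(invalid="ignore", divide="ignore"):
        return case_sum / case_n, ctrl_sum / ctrl_n


def permutation_p(
    metric: Metric,
    values: np.ndarray,
    is_case: np.ndarray,
    B: int = 100_000,
    seed: int = 0,
    statistic: str = "ratio",
    type_stratum: str = "ALL",
    size_stratum: str = "ALL",
    n_cnvs: int = 0,
) -> BurdenResult:
    """One-sided permutation P toward case enrichment for one grid cell.

    ``statistic="ratio"`` compares case/control mean ratios (the burden-table
    convention); ``"difference"`` compares mean differences (used for the
    residual-based corrected test).  P = (1 + #{perm stat >= observed}) /
    (B + 1), so P is never 0 and never below 1/(B+1).  Deterministic given
    ``seed``.  A degenerate metric (all values equal) returns P = 1.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    values = np.asarray(values, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    stat = burden_ratio(metric, values, is_case, type_stratum, size_stratum, n_cnvs)
    if statistic == "ratio":
        observed = stat.ratio
    elif statistic == "difference":
        observed = stat.case_mean - stat.control_mean
    else:
        raise ValueError("statistic must be 'ratio' or 'difference'")

    finite_vals = values[~np.isnan(values)]
    # tolerance-based: residualized metrics can be constant up to rounding
    if finite_vals.size == 0 or np.allclose(finite_vals, finite_vals[0]):
        logger.warning("degenerate metric %s: all values equal; p = 1", metric.value)
        return BurdenResult(stat=stat, p=1.0, p_corr=None, n_permutations=B, seed=seed)
    if np.isnan(observed):
        return BurdenResult(stat=stat, p=float("nan"), p_corr=None,
                            n_permutations=B, seed=seed)

    rng = np.random.default_rng(seed)
    n_cases = int(is_case.sum())
    exceed = 0
    for masks in _permuted_case_masks(values.size, n_cases, B, rng):
        case_mean, ctrl_mean = _perm_group_means(values, masks)
        if statistic == "ratio":
            with np.errstate(invalid="ignore", divide="ignore"):
                perm_stat = case_mean / ctrl_mean
        else:
            perm_stat = case_mean - ctrl_mean
        exceed += int(np.count_nonzero(perm_stat >= observed))
    p = (1 + exceed) / (B + 1)
    return BurdenResult(stat=stat, p=p, p_corr=None, n_permutations=B, seed=seed)


def corrected_p(
    table: pd.DataFrame,
    is_case: np.ndarray,
    B: int = 100_000,
    seed: int = 0,
    type_stratum: str = "ALL",
    size_stratum: str = "ALL",
) -> float:
    """Permutation P for gene count corrected for global CNV rate and size.

    Residualizes ``gene_count`` on (rate, total_kb) by OLS — the covariates
    carry no phenotype information, so the residuals are identical in every
    permutation — then permutes labels on the residuals with a one-sided
    mean-difference statistic.  Falls back to the uncorrected metric when the
    design matrix is singular (constant covariates).
    """
    y = table["gene_count"].to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(table)),
        table["rate"].to_numpy(dtype=float),
        table["total_kb"].to_numpy(dtype=float),
    ])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning("singular covariates in gene-count correction; "
                       "falling back to uncorrected metric")
        resid = y
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    result = permutation_p(
        Metric.GENE_COUNT, resid, is_case, B=B, seed=seed, statistic="difference",
        type_stratum=type_stratum, size_stratum=size_stratum,
    )
    return result.p


class CnvBurdenModel:
    """Rare-CNV burden grid for a case-control cohort.

    Parameters
    ----------
    samples
        QC-passed samples (records with exclusion flags are dropped with a
        log message).
    rare_calls
        QC-passed rare calls (consensus or raw), each with ``sample_id``,
        ``interval``, ``state``, ``length``.
    genes
        Optional gene models enabling the gene-count metric.
    """

    def __init__(
        self,
        samples: list[SampleRecord],
        rare_calls: list,
        genes: list[GeneModel] | GeneIndex | None = None,
    ) -> None:
        dropped = [s.sample_id for s in samples if not s.passes_qc]
        if dropped:
            logger.info("dropping %d flagged samples from burden", len(dropped))
        self.samples = [s for s in samples if s.passes_qc]
        if not self.samples:
            raise ValueError("no QC-passed samples")
        self.calls = rare_calls
        self.gene_index = (
            genes if isinstance(genes, GeneIndex) or genes is None else GeneIndex(genes)
        )
        self.annotations = (
            annotate_calls(rare_calls, self.gene_index) if self.gene_index else None
        )
        self.is_case = np.array(
            [s.phenotype is Phenotype.CASE for s in self.samples], dtype=bool
        )
        self.n_cases = int(self.is_case.sum())
        self.n_controls = len(self.samples) - self.n_cases

    @classmethod
    def from_dataframes(
        cls, samples: pd.DataFrame, calls: pd.DataFrame, **kwargs
    ) -> "CnvBurdenModel":
        """Build from plain DataFrames matching the samples/calls TSV schemas."""
        from .core import CnvCall, Algorithm, GenomicInterval, CnvState

        sample_records = [
            SampleRecord(
                sample_id=str(r.sample_id),
                phenotype=Phenotype.CASE if int(r.phenotype) == 2 else Phenotype.CONTROL,
            )
            for r in samples.itertuples()
        ]
        call_records = [
            CnvCall(
                sample_id=str(r.sample_id),
                interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                state=CnvState(str(r.state).upper()),
                n_probes=int(getattr(r, "n_probes", 10)),
                confidence=float(getattr(r, "confidence", 99.0)),
                algorithm=Algorithm.IPATTERN,
            )
            for r in calls.itertuples()
        ]
        return cls(sample_records, call_records, **kwargs)

    def fit(
        self,
        B: int = 100_000,
        seed: int = 0,
        metrics: tuple[Metric, ...] | None = None,
    ) -> "BurdenResults":
        """Compute the full burden grid with permutation P values."""
        if metrics is None:
            metrics = tuple(Metric)
            if self.gene_index is None:
                metrics = tuple(m for m in metrics if m is not Metric.GENE_COUNT)
        strata = stratify(self.calls)
        rows = []
        seed_seq = np.random.SeedSequence(seed)
        # one child seed per grid cell, in a fixed iteration order
        for (t, s), subset in sorted(strata.items()):
            table = per_sample_metrics(
                self.samples, subset, self.gene_index, self.annotations
            )
            for metric in metrics:
                cell_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
                values = table[_METRIC_COLUMN[metric]].to_numpy(dtype=float)
                res = permutation_p(
                    metric, values, self.is_case, B=B, seed=cell_seed,
                    type_stratum=t, size_stratum=s, n_cnvs=len(subset),
                )
                p_corr = None
                if metric is Metric.GENE_COUNT:
                    p_corr = corrected_p(
                        table, self.is_case, B=B, seed=cell_seed,
                        type_stratum=t, size_stratum=s,
                    )
                rows.append(
                    BurdenResult(stat=res.stat, p=res.p, p_corr=p_corr,
                                 n_permutations=B, seed=cell_seed)
                )
        return BurdenResults(self, rows, B=B, seed=seed)


class BurdenResults:
    """Fitted burden grid; ``table`` holds one row per (stratum, metric) cell."""

    def __init__(self, model: CnvBurdenModel, results: list[BurdenResult],
                 B: int, seed: int) -> None:
        self.model = model
        self.results = results
        self.B = B
        self.seed = seed
        self.table = pd.DataFrame(
            [
                {
                    "type": r.stat.type_stratum,
                    "size_class": r.stat.size_stratum,
                    "metric": r.stat.metric.value,
                    "n_cnvs": r.stat.n_cnvs,
                    "case_mean": r.stat.case_mean,
                    "control_mean": r.stat.control_mean,
                    "ratio": r.stat.ratio,
                    "p": r.p,
                    "p_corr": r.p_corr,
                }
                for r in results
            ]
        )

    def cell(self, metric: Metric, type_stratum: str = "ALL",
             size_stratum: str = "ALL") -> BurdenResult:
        for r in self.results:
            if (r.stat.metric is metric and r.stat.type_stratum == type_stratum
                    and r.stat.size_stratum == size_stratum):
                return r
        raise KeyError((metric, type_stratum, size_stratum))

    def summary(self) -> str:
        lines = [
            f"Rare-CNV burden: {self.model.n_cases} cases vs "
            f"{self.model.n_controls} controls, {len(self.model.calls)} calls, "
            f"B={self.B} permutations (seed {self.seed})",
            f"{'Type':<6} {'Size':<10} {'Metric':<18} {'n':>5} "
            f"{'Case/ctrl':>10} {'Baseline':>10} {'P':>8} {'Pcorr':>8}",
        ]
        for r in self.results:
            ratio = f"{r.stat.ratio:.4f}" if np.isfinite(r.stat.ratio) else "NA"
            base = (f"{r.stat.control_mean:.4f}"
                    if np.isfinite(r.stat.control_mean) else "NA")
            pcorr = f"{r.p_corr:.4f}" if r.p_corr is not None else "-"
            p = f"{r.p:.4f}" if np.isfinite(r.p) else "NA"
            lines.append(
                f"{r.stat.type_stratum:<6} {r.stat.size_stratum:<10} "
                f"{r.stat.metric.value:<18} {r.stat.n_cnvs:>5} "
                f"{ratio:>10} {base:>10} {p:>8} {pcorr:>8}"
            )
        return "\n".join(lines)
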