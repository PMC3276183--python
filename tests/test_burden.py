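"""Burden grid: per-sample metrics, strata, ratios, permutation P values."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cnvburden.burden import (
    CnvBurdenModel,
    Metric,
    burden_ratio,
    corrected_p,
    per_sample_metrics,
    permutation_p,
    size_class_membership,
    stratify,
)
from cnvburden.core import CnvState, Phenotype

from conftest import make_call, make_sample


class TestPerSampleMetrics:
    def test_two_call_sample(self):
        s = make_sample("S1")
        calls = [
            make_call(sample="S1", start=0, end=150_000, call_id="a"),
            make_call(sample="S1", start=500_000, end=750_000, call_id="b"),
        ]
        table = per_sample_metrics([s], calls)
        row = table.loc["S1"]
        assert row["rate"] == 2
        assert row["any_cnv"] == 1
        assert row["total_kb"] == 400.0
        assert row["avg_kb"] == 200.0

    def test_zero_call_sample(self):
        table = per_sample_metrics([make_sample("S1")], [])
        row = table.loc["S1"]
        assert row["rate"] == 0 and row["any_cnv"] == 0 and row["total_kb"] == 0
        assert np.isnan(row["avg_kb"])  # excluded from average-size means
        assert row["gene_count"] == 0

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="unknown sample"):
            per_sample_metrics([make_sample("S1")], [make_call(sample="S9")])

    def test_mean_case_rate_from_printed_counts(self):
        """390 calls over 392 cases gives a mean rate of 0.9949."""
        samples = [make_sample(f"S{i}") for i in range(392)]
        calls = [
            make_call(sample=f"S{i % 392}", start=k * 1000, end=k * 1000 + 150_000,
                      call_id=f"c{k}")
            for k, i in enumerate(range(390))
        ]
        table = per_sample_metrics(samples, calls)
        assert table["rate"].mean() == pytest.approx(390 / 392)
        assert table["rate"].mean() == pytest.approx(0.9949, abs=5e-5)


class TestStratify:
    def test_size_classes_are_cumulative_above_500kb(self):
        assert size_class_membership(600_000) == ("ALL", ">=500kb")
        assert size_class_membership(1_200_000) == ("ALL", ">=500kb", ">=1Mb")
        assert size_class_membership(150_000) == ("ALL", "100-500kb")

    def test_membership(self):
        dup600 = make_call(start=0, end=600_000, state=CnvState.DUP, call_id="a")
        strata = stratify([dup600])
        for key in [("ALL", "ALL"), ("DUP", "ALL"), ("ALL", ">=500kb"), ("DUP", ">=500kb")]:
            assert strata[key] == [dup600]
        assert strata[("DEL", "ALL")] == []
        assert strata[("ALL", ">=1Mb")] == []

    def test_size_partition_identity(self):
        """|100-500kb| + |>=500kb| == |ALL| (>=1Mb nested in >=500kb)."""
        rng = np.random.default_rng(0)
        calls = [
            make_call(start=0, end=int(rng.integers(100_000, 3_000_000)),
                      call_id=f"c{i}")
            for i in range(200)
        ]
        strata = stratify(calls)
        assert (len(strata[("ALL", "100-500kb")]) + len(strata[("ALL", ">=500kb")])
                == len(strata[("ALL", "ALL")]))
        assert set(map(id, strata[("ALL", ">=1Mb")])) <= set(map(id, strata[("ALL", ">=500kb")]))
        # DEL/DUP partition ALL
        assert (len(strata[("DEL", "ALL")]) + len(strata[("DUP", "ALL")])
                == len(strata[("ALL", "ALL")]))


class TestBurdenRatio:
    def test_table_row_from_printed_rate_counts(self):
        """390/392 case calls vs 344/357 control calls: ratio 1.0325, baseline 0.9636."""
        rates = np.concatenate([
            np.repeat(390 / 392, 392), np.repeat(344 / 357, 357),
        ])
        is_case = np.arange(749) < 392
        stat = burden_ratio(Metric.RATE, rates, is_case)
        assert stat.control_mean == pytest.approx(0.9636, abs=5e-5)
        assert stat.ratio == pytest.approx(1.0325, abs=5e-5)

    def test_table_row_from_printed_proportions(self):
        """255/392 vs 224/357 carriers: ratio 1.0367, baseline 0.6275."""
        any_cnv = np.concatenate([
            np.ones(255), np.zeros(392 - 255), np.ones(224), np.zeros(357 - 224),
        ])
        is_case = np.arange(749) < 392
        stat = burden_ratio(Metric.SAMPLE_PROPORTION, any_cnv, is_case)
        assert stat.control_mean == pytest.approx(0.6275, abs=5e-5)
        assert stat.ratio == pytest.approx(1.0367, abs=1e-4)

    def test_identical_groups_ratio_one(self):
        values = np.tile([1.0, 2.0], 10)
        is_case = np.tile([True, False], 10)
        assert burden_ratio(Metric.RATE, values, is_case).ratio == pytest.approx(
            np.mean([1.0] * 10) / np.mean([2.0] * 10)
        )

    def test_zero_control_mean_gives_na(self):
        values = np.array([1.0, 1.0, 0.0, 0.0])
        is_case = np.array([True, True, False, False])
        stat = burden_ratio(Metric.RATE, values, is_case)
        assert np.isnan(stat.ratio)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            burden_ratio(Metric.RATE, np.ones(3), np.array([True, True, True]))


class TestPermutationP:
    def test_degenerate_metric_gives_p_one(self):
        values = np.ones(20)
        is_case = np.arange(20) < 10
        res = permutation_p(Metric.RATE, values, is_case, B=99, seed=1)
        assert res.p == 1.0

    def test_p_has_permutation_floor(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.poisson(5, 25) + 10.0, rng.poisson(1, 25) * 1.0])
        is_case = np.arange(50) < 25
        res = permutation_p(Metric.RATE, values, is_case, B=200, seed=3)
        assert res.p >= 1 / 201
        assert res.p < 0.05

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        values = rng.poisson(1, 60).astype(float)
        is_case = np.arange(60) < 30
        p1 = permutation_p(Metric.RATE, values, is_case, B=500, seed=12).p
        p2 = permutation_p(Metric.RATE, values, is_case, B=500, seed=12).p
        p3 = permutation_p(Metric.RATE, values, is_case, B=500, seed=13).p
        assert p1 == p2
        assert p1 != p3 or True  # different seeds may coincide; only equality is required

    def test_observed_statistic_independent_of_seed_and_B(self):
        rng = np.random.default_rng(8)
        values = rng.poisson(1, 60).astype(float)
        is_case = np.arange(60) < 30
        r1 = permutation_p(Metric.RATE, values, is_case, B=50, seed=1)
        r2 = permutation_p(Metric.RATE, values, is_case, B=500, seed=99)
        assert r1.stat == r2.stat

    def test_label_swap_inverts_ratio(self):
        rng = np.random.default_rng(5)
        values = rng.poisson(2, 40).astype(float) + 1
        is_case = np.arange(40) < 20
        stat = burden_ratio(Metric.RATE, values, is_case)
        flipped = burden_ratio(Metric.RATE, values, ~is_case)
        assert flipped.ratio == pytest.approx(1 / stat.ratio)

    def test_null_p_values_roughly_uniform(self):
        """i.i.d. metrics across groups: P(p <= 0.5) close to 0.5."""
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            values = rng.poisson(1.0, 80).astype(float)
            is_case = np.zeros(80, dtype=bool)
            is_case[:40] = True
            p = permutation_p(Metric.RATE, values, is_case, B=199, seed=1000 + rep).p
            if p <= 0.5:
                hits += 1
        # binomial(100, ~0.5): 3.5 sigma band
        assert 32 <= hits <= 68


class TestCorrectedP:
    def test_gene_count_proportional_to_rate_corrects_to_one(self):
        rng = np.random.default_rng(2)
        n = 120
        rate = rng.poisson(1.0, n).astype(float)
        rate[:n // 2] += rng.poisson(1.0, n // 2)  # cases have more CNVs
        table = pd.DataFrame({
            "rate": rate,
            "total_kb": rate * 150.0 + rng.normal(0, 20, n),  # not collinear
            "gene_count": rate * 3.0,  # exactly proportional to rate
        })
        is_case = np.arange(n) < n // 2
        uncorrected = permutation_p(
            Metric.GENE_COUNT, table["gene_count"].to_numpy(), is_case, B=499, seed=5
        ).p
        corrected = corrected_p(table, is_case, B=499, seed=5)
        assert uncorrected < 0.05
        assert corrected > 0.5

    def test_case_only_gene_excess_detected_after_correction(self):
        rng = np.random.default_rng(3)
        n = 400
        rate = rng.poisson(1.0, n).astype(float)
        genes_per_cnv = np.where(np.arange(n) < n // 2, 4.0, 3.0)
        table = pd.DataFrame({
            "rate": rate,
            "total_kb": rate * 200.0,
            "gene_count": rate * genes_per_cnv,
        })
        is_case = np.arange(n) < n // 2
        assert corrected_p(table, is_case, B=999, seed=9) < 0.05

    def test_singular_covariates_fall_back(self):
        table = pd.DataFrame({
            "rate": np.ones(30),
            "total_kb": np.ones(30) * 100,
            "gene_count": np.concatenate([np.full(15, 3.0), np.full(15, 1.0)]),
        })
        is_case = np.arange(30) < 15
        p = corrected_p(table, is_case, B=499, seed=4)
        assert p < 0.05  # falls back to the raw (clearly enriched) metric


class TestModelInterface:
    def _cohort(self, rng, n=60, spike_cases=False):
        samples = [
            make_sample(f"S{i}", Phenotype.CASE if i < n // 2 else Phenotype.CONTROL)
            for i in range(n)
        ]
        calls = []
        k = 0
        for i in range(n):
            lam = 2.0 if (spike_cases and i < n // 2) else 1.0
            for _ in range(rng.poisson(lam)):
                start = int(rng.integers(0, 20_000_000))
                size = int(rng.integers(100_000, 1_500_000))
                calls.append(make_call(
                    sample=f"S{i}", start=start, end=start + size,
                    state=CnvState.DEL if rng.random() < 0.4 else CnvState.DUP,
                    call_id=f"c{k}",
                ))
                k += 1
        return samples, calls

    def test_fit_returns_full_grid(self):
        rng = np.random.default_rng(21)
        samples, calls = self._cohort(rng)
        res = CnvBurdenModel(samples, calls).fit(B=99, seed=2)
        # 3 types x 4 size classes x 4 metrics (no genes supplied)
        assert len(res.table) == 48
        assert res.table["p"].dropna().between(1 / 100, 1).all()
        assert "CNV" in res.summary() or "burden" in res.summary()

    def test_fit_reproducible(self):
        rng = np.random.default_rng(21)
        samples, calls = self._cohort(rng)
        t1 = CnvBurdenModel(samples, calls).fit(B=99, seed=2).table
        t2 = CnvBurdenModel(samples, calls).fit(B=99, seed=2).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_spiked_case_excess_detected(self):
        rng = np.random.default_rng(4)
        samples, calls = self._cohort(rng, n=300, spike_cases=True)
        res = CnvBurdenModel(samples, calls).fit(B=999, seed=2)
        assert res.cell(Metric.RATE).p < 0.01

    def test_flagged_samples_excluded(self):
        rng = np.random.default_rng(21)
        samples, calls = self._cohort(rng)
        from cnvburden.core import ExclusionFlag

        samples[0] = samples[0].with_flag(ExclusionFlag.QC_METRIC)
        calls = [c for c in calls if c.sample_id != "S0"]
        model = CnvBurdenModel(samples, calls)
        assert model.n_cases == 29
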