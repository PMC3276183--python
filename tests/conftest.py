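from __future__ import annotations

import numpy as np
import pytest

from cnvburden.core import (
    Algorithm,
    CnvCall,
    CnvState,
    GenomicInterval,
    Phenotype,
    SampleRecord,
)
from cnvburden.simulate import SimulationConfig, generate_cohort


def make_call(
    sample="S1",
    chrom="1",
    start=1_000_000,
    end=1_200_000,
    state=CnvState.DUP,
    algorithm=Algorithm.IPATTERN,
    n_probes=20,
    confidence=30.0,
    call_id="",
) -> CnvCall:
    return CnvCall(
        sample_id=sample,
        interval=GenomicInterval(chrom, start, end),
        state=state,
        n_probes=n_probes,
        confidence=confidence,
        algorithm=algorithm,
        call_id=call_id,
    )


def make_sample(
    sample_id="S1",
    phenotype=Phenotype.CASE,
    call_rate=0.99,
    lrr_sd=0.15,
    baf_sd=0.05,
    wave_factor=0.01,
) -> SampleRecord:
    return SampleRecord(
        sample_id=sample_id,
        phenotype=phenotype,
        call_rate=call_rate,
        lrr_sd=lrr_sd,
        baf_sd=baf_sd,
        wave_factor=wave_factor,
    )


def random_call_set(rng: np.random.Generator, n_calls: int) -> list[CnvCall]:
    """Random per-algorithm calls dense enough to force overlaps."""
    algos = [Algorithm.IPATTERN, Algorithm.PENNCNV, Algorithm.QUANTISNP]
    calls = []
    for k in range(n_calls):
        start = int(rng.integers(0, 2_000_000))
        length = int(rng.integers(100_000, 600_000))
        calls.append(make_call(
            sample=f"S{int(rng.integers(4))}",
            chrom=str(1 + int(rng.integers(2))),
            start=start,
            end=start + length,
            state=CnvState.DEL if rng.random() < 0.5 else CnvState.DUP,
            algorithm=algos[int(rng.integers(3))],
            call_id=f"rc{k}",
        ))
    return calls


def random_segmentation_call_set(
    rng: np.random.Generator, n_per_algo: int = 12
) -> list[CnvCall]:
    """Caller-like random input: per sample+algorithm calls never overlap."""
    algos = [Algorithm.IPATTERN, Algorithm.PENNCNV, Algorithm.QUANTISNP]
    calls = []
    k = 0
    for sample in ("S0", "S1"):
        for algo in algos:
            pos = 0
            for _ in range(n_per_algo):
                pos += int(rng.integers(0, 400_000))
                length = int(rng.integers(100_000, 500_000))
                calls.append(make_call(
                    sample=sample, chrom="1", start=pos, end=pos + length,
                    state=CnvState.DEL if rng.random() < 0.5 else CnvState.DUP,
                    algorithm=algo, call_id=f"seg{k}",
                ))
                pos += length
                k += 1
    return calls


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort shared across tests."""
    return generate_cohort(SimulationConfig(seed=7))
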