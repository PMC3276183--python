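# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the design decisions taken where the design was genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

Internally every interval is 0-based half-open, so length = end − start
with no off-by-one arithmetic. The calls TSV and PLINK `.cnv` dialects are
declared 1-based inclusive and converted at the I/O boundary
(file → internal: start−1, end); BED inputs are kept as-is. The
conversion is a bijection: internal length equals file_end − file_start
+ 1 for the inclusive dialects, and write∘read round-trips are
byte-stable. Chromosome labels are normalized by stripping a leading
`chr`; autosomes 1–22 and X are accepted (X calls are retained and
carried through but reported with their chromosome so they can be
reviewed separately); Y and mitochondrial rows are skipped with a logged
warning, since dosage inference for them is not meaningful on this kind
of array analysis. PLINK `TYPE` tokens map 0,1 → deletion, 3+ →
duplication; 2 is diploid and rejected as an error.

## Sample QC

Thresholds (all strict inequalities, as conventional for these metrics):
chip call rate < 0.97, LRR SD > 0.27, BAF SD > 0.17, |wave factor| >
0.04. The wave-factor rule is deliberately two-sided: genomic waves
distort intensities in either direction, and the waviness-factor
convention uses the absolute value.

Call-count outliers are flagged per algorithm: a sample whose count for
*any* of the three discovery algorithms strictly exceeds
Q3 + 3·IQR of the cohort's count distribution is excluded. Quantiles use
linear interpolation between order statistics (the default in mainstream
numerical environments); both the multiplier and the quantile method are
configurable so alternative conventions (e.g. Tukey hinges) can be
compared. The cutoffs are computed after metric QC, over metric-passing
samples only — a metrics-failing sample with hundreds of junk calls
should not inflate the cutoff — and each stage can also be invoked
separately if the other order is wanted.

Samples owning any single call > 7.5 Mb are flagged as likely karyotype
abnormalities. An aggregate-length rule (sum of call lengths > 10 Mb by
default) catches samples with many moderately sized artifacts; the 10 Mb
default is a judgment call (no standard constant exists for it) and is
configurable. Excluded samples are always reported with their flags,
never silently dropped, and flagging operations are idempotent and never
modify calls.

## Stringent consensus

Seeds are iPattern calls; support comes from PennCNV or QuantiSNP calls
of the same sample and same DEL/DUP state with overlap ≥ 50%. The overlap
criterion is *reciprocal* by default (both calls must be covered ≥ 50%),
the strictest common reading — it prevents a small call from validating a
much larger one — with a one-sided mode (relative to the seed only)
behind a switch. Deletions and duplications never merge; matching is at
the DEL/DUP level, not exact copy number, since different callers encode
integer copy numbers inconsistently.

The consensus interval is the union of the outer boundaries of the seed
and its supporting calls. By default every supporting call extends the
union (`boundary_support="all"`); a `"first"` mode lets only the
best-overlapping supporter extend boundaries while the rest merely
corroborate, for users worried about boundary over-extension. When one
supporting call corroborates two seeds, both consensus calls are emitted
and a fragmentation warning is logged. CNVpartition input is accepted and
ignored (it is a visualization aid, not a discovery caller here).

Call-level filters (< 5 probes, < 100 kb, QuantiSNP log Bayes factor
< 15 — all strict) are applied to input calls before merging; merged
consensus intervals are size-checked again afterwards (the union can only
grow intervals, so this is a safety net, and both stages log removals
with reason codes). Region masks: any overlap with centromeric or
immunoglobulin masks removes a call; summed segmental-duplication overlap
strictly exceeding 50% of the call's length removes it. Filters and masks
commute, so their order does not affect the surviving set.

The sweep-based implementation is checked in the tests against an
independent all-pairs brute-force oracle on hundreds of random call sets.

## Loci, rarity, reference sets

Carrier frequency requires grouping calls across samples; the package
reuses the analysis's own overlap constant and clusters same-state
consensus calls by single-linkage with reciprocal overlap ≥ 50%
(configurable). Locus ids derive deterministically from the envelope
coordinates. Multiple calls from one sample collapse to a single carrier.

A locus is *common* when carriers / (n_cases + n_controls) > 1% — the
combined-sample convention; a per-group mode (common only if > 1% in each
group) is available behind `rare_scope="each"`. Denominators are always
post-QC sample counts. Common loci are excluded from the rare burden but
retained for per-locus association, which deliberately covers common
genic CNVs.

Reference carrier tables (DGV-style catalogues) are matched by state and
reciprocal overlap ≥ 50%; matched record counts are summed and capped at
the cohort size.

## Burden testing

Per-sample metrics within a stratum: rate (call count), carrier indicator,
total size (kb), average size (kb), and genes hit (union of genes
overlapped by the sample's calls — a gene hit by two calls counts once,
and any-base overlap is used for "genes hit"; breakpoint-inside-span
("disrupted") and exon-overlap sets are computed for the candidate
reports instead). Samples with no calls in a stratum are excluded from
the average-size group mean (otherwise the average-size cell would just
replicate the rate signal); a configurable alternative counts them as 0.

Strata: type ∈ {all, deletions, duplications} × size ∈ {all, 100–500 kb,
≥ 500 kb, ≥ 1 Mb}, the ≥-classes being cumulative (≥ 1 Mb ⊆ ≥ 500 kb, and
|100–500 kb| + |≥ 500 kb| = |all|).

The test statistic per cell is the case/control ratio of group means; the
one-sided empirical p toward case enrichment is (1 + #{permuted ratio ≥
observed}) / (B + 1), which can never be 0 and has floor 1/(B+1) — the
standard permutation estimator. Labels are permuted preserving group
sizes; the permutation engine is vectorized (boolean assignment matrices
in chunks) and bit-reproducible given a seed; observed statistics never
depend on B or the seed. A zero control mean makes the ratio NA and the
cell is reported without a p rather than failing the grid; an (almost)
constant metric short-circuits to p = 1 with a warning, using a
numerical tolerance so that residualized metrics that are constant up to
rounding are treated as degenerate.

**Corrected gene-count p.** To remove global case-control differences in
CNV rate and size, each sample's gene count is replaced by its residual
from an OLS fit on (rate, total size). The covariates carry no phenotype
information, so the residuals are identical in every permutation and are
computed once. Because residual means can be zero or negative, the
corrected test uses the one-sided mean-difference statistic rather than a
ratio. When the design matrix is singular (constant covariates) the
correction falls back to the uncorrected metric with a warning. An
alternative correction (testing genes-per-CNV directly) was considered
and rejected because it changes the estimand rather than adjusting it.

## Per-locus association

Pearson χ² on the 2×2 carrier table *without* Yates continuity
correction — on carrier counts 10/382 vs 3/354 the uncorrected statistic
is 3.206 while the corrected one would be ≈ 2.28, and the uncorrected
form is the compatibility choice for this analysis style. One-tailed p is
half the 1-df chi-square tail when the observed direction is case
enrichment, 1 − half otherwise; χ² = 0 gives exactly 0.5. No
multiple-testing correction is applied across loci by default (locus p
values are nominal); a Benjamini–Hochberg column is available behind a
flag. Fisher's exact test is deliberately not the primary statistic.

Candidate screens: (1) loci ≥ 1 Mb with ≥ 1 case carrier, 0 control
carriers, and frequency 0 (or below a configurable bound) in every
reference set; (2) genes overlapped by calls in ≥ 2 *distinct* case
samples, 0 controls, absent/rare in references, reported with carrier
samples, coordinates and disruption status. "Disrupted" means a call
breakpoint falls strictly inside the gene span — a guess at a standard
but undefined term, chosen because it separates truncation from
engulfment; exon-overlap is reported separately.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes on
a toy genome of 2 × 25 Mb with evenly spaced probes (10,000 by default,
5 kb spacing), chosen so the absolute thresholds (100 kb, 500 kb, 1 Mb,
7.5 Mb) remain meaningful at desk-scale runtime. Defaults mirror the
study conditions: 392 cases / 357 controls; ~0.98 rare background CNVs
per sample (Poisson), log-normal sizes (log-mean log 180 kb, log-SD 0.8,
truncated to [100 kb, 5 Mb]) calibrated so roughly 88% of rare calls fall
in 100–500 kb; 38% deletions; one spiked ~470 kb duplication carried by
2.6% of cases and 0.8% of controls, overlapping five tiled genes, with a
matching reference record of 24 carriers in 5056. Caller sensitivities
default to 0.95 (iPattern) and 0.85 (PennCNV, QuantiSNP) — values in the
range reported for large CNVs on arrays of this resolution — with
Gaussian boundary jitter (SD 5 kb) snapped to probe positions so the
union-boundary merge is exercised with non-identical supporting calls.
5% of samples are drawn to fail at least one QC metric, and two outlier
samples receive 50 junk calls per caller, placing them above the
Q3 + 3·IQR cutoff by construction. Same config + seed gives
byte-identical outputs.

What the generator does *not* emulate: raw LRR/BAF tracks, probe-density
variation, caller-specific boundary biases, linkage disequilibrium,
population structure, batch effects, and genuinely multiallelic or
complex loci. Passing tests therefore demonstrate the correctness and
calibration of the post-calling analysis under its own assumptions, not
the behaviour of the upstream callers on real intensity data.

`truth_eval` scores any pipeline stage against the planted truth by
sample, state and reciprocal 50% overlap, yielding per-stage recall and
precision; in the noiseless limit (sensitivities 1, jitter 0) consensus
equals truth exactly, and with support sensitivities s the expected
consensus recall is sens_iPattern · (1 − (1 − s)²).

## Numerical choices and problem sizes

Permutation p values in the shipped tests and the acceptance script use
B between 500 and 2,000 and cohorts of 150–750 samples; these sizes give
Monte-Carlo error well below the effects being checked while keeping any
run in seconds. Null calibration is checked on 200 independent cohorts
against the exact binomial 99% interval for the rejection rate at 0.05,
plus a Kolmogorov–Smirnov uniformity sanity check (approximate, since
permutation p values live on a (B+1)-point grid). Spiked-locus recovery
is checked both at study scale (392/357) and at 4,000/4,000, where the
planted frequencies are detected at p < 0.001 in essentially every seed.
Note that under binomial carrier sampling at frequencies 2.6% vs 0.8%
the *expectation* of the Pearson statistic is ≈ 1 + noncentrality ≈ 4.2,
which is higher than any single observed realization near 3.2; tests
anchored on one realization rather than the resampling mean will sit
below the simulated average.

## Known limitations

* Boundary accuracy is limited to the probe grid; no intensity-level
  refinement is attempted.
* Chromosome X association ignores sex composition; a sex-stratified
  carrier test is future work.
* The burden grid reports uncorrected cell p values (matching the
  analysis style it implements); family-wise control across the grid is
  out of scope.
* The locus test iterates all loci; no prioritization or region
  restriction is applied.
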