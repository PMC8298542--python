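# Methods

## Problem and scope

`mcascreen` re-implements, as a tested pipeline, the analysis of mosaic
chromosomal alterations (mCAs) in pre-transplant blood of AML patients:
detect copy-gain, copy-loss and copy-neutral loss-of-heterozygosity (CNLOH)
events from SNP-array log R ratio (LRR) and B-allele frequency (BAF)
tracks, estimate the clonal cell fraction of each event, aggregate calls to
chromosome-arm region indicators per patient, and screen those indicators
for association with overall survival and relapse, separately by remission
status, using Kaplan–Meier / log-rank screening, stepwise-built
multivariable Cox models with Schoenfeld diagnostics, and cause-specific
relapse analysis with transplant-related mortality as the competing event.

The registry data this style of analysis is run on is not publicly
deposited, so the package ships a first-class synthetic-data module that
generates array signal and cohort outcomes with known truth; every stage is
validated against that truth or against independent oracles.

## Signal model

At a biallelic SNP, BAF is the fraction of signal from the B allele and LRR
is log2 of observed over expected total intensity. A clone of cell fraction
`f` carrying an event changes the expected allelic dosage at heterozygous
(AB) probes; averaging over the cell mixture gives the expected BAF bands
and LRR:

| event | AB-probe BAF (affected haplotype B / A) | LRR |
|---|---|---|
| CNLOH | (1+f)/2, (1−f)/2 | 0 |
| loss  | 1/(2−f), (1−f)/(2−f) | log2((2−f)/2) |
| gain  | (1+f)/(2+f), 1/(2+f) | log2((2+f)/2) |

The generator draws which haplotype is affected independently per probe (no
phasing); detection uses the mirrored deviation Δ = |BAF − 0.5| and is
invariant to that sign. The noiseless mean deviation of in-event AB probes
has the closed forms Δ = f/2 (CNLOH), f/(2(2−f)) (loss), f/(2(2+f)) (gain),
which the cell-fraction estimator inverts:

    f = 2Δ (CNLOH)    f = 4Δ/(1+2Δ) (loss)    f = 4Δ/(1−2Δ) (gain)

clipped to (0, 1]. For loss segments without heterozygous support (a
near-complete clone suppresses AB calls) f is inverted from the LRR level,
f = 2(1 − 2^LRR). An optional LRR attenuation factor exists (default 1.0,
i.e. unattenuated response); real arrays compress LRR somewhat, which would
bias LRR-derived (not BAF-derived) fractions.

## Detection chain

1. **Quantile normalization** of LRR across samples: each sample is
   rank-mapped to the across-sample mean order statistics (identity for a
   single sample).
2. **GC-wave correction**: corrected = LRR − ĝ(gc), with ĝ a LOWESS
   (local-linear) smoother of LRR on local GC content, default window 1001
   probes; a global linear fit is available, and constant GC degenerates to
   mean-centering. With a planted wave of slope 0.8 the residual
   correlation with GC is below 0.05, and an in-event LRR offset is
   preserved to within 0.03 provided the event is a realistically small
   fraction of the genome (a single event spanning a third of a toy
   two-chromosome genome drags the smoother; at 22 chromosomes this is
   negligible).
3. **Deviation series**: Δ at AB probes (genotype column by default; a BAF
   ∈ [0.25, 0.75] fallback exists but is unreliable for f > 0.5 events).
   Chromosomes with fewer than `min_het` = 10 AB probes are flagged
   low-information and skip BAF segmentation (LRR-only rules still apply).
4. **Segmentation**: recursive binary segmentation of the per-chromosome Δ
   series. A candidate split maximizes the pooled two-sample t statistic
   over all admissible positions; it is accepted iff its permutation
   p-value < `alpha` = 0.01 (1000 permutations) and both children keep
   ≥ `min_points` = 10 AB probes. Permutations run in blocks with an early
   stop that triggers only when the exceedance count already forces
   p ≥ alpha, so the accept/reject decision is identical to the full run.
   Deterministic given the seed (per-sample, per-chromosome sub-seeds are
   derived by hashing).
5. **Classification**, in order: Δ ≥ δ_min (0.05) with |median LRR| ≤
   λ_neutral (0.05) → CNLOH; Δ ≥ δ_min with median LRR ≥ λ_gain (0.05) →
   gain; median LRR ≤ −λ_loss (0.10) → loss (no BAF support required);
   otherwise normal. δ_min = 0.05 corresponds to f ≈ 0.10 for CNLOH, so the
   noiseless model is always called across the observed cell-fraction range
   (IQR ≈ 29–79%); a gain needs f ≳ 0.22 to clear δ_min, which is the main
   sensitivity limit at low fractions.
6. **Filtering**: calls shorter than 2 Mb are removed (the size threshold
   that controls false discovery), plus deterministic QC surrogates for the
   original manual review: BAF-supported calls need ≥ 10 AB probes
   ("low_het_support"), LRR-only losses need ≥ 30 spanned probes
   ("low_probe_support"). Every removal is logged with its reason so a
   human can audit the decisions.
7. **Arm annotation**: a call entirely below the centromere is `p`, above
   is `q`; a centromere-spanning call carries both labels and counts toward
   both arm indicators downstream.

Runs of homozygosity with normal LRR (possible f → 1 CNLOH, but equally
constitutive autozygosity) are *not* auto-called CNLOH: with no AB probes
the segment is low-information and only LRR rules apply. This is a known
limitation; distinguishing the two requires population haplotype data that
is out of scope.

## Cohort aggregation and characteristic tables

Patient × region indicators are binary: a region is an (arm, event-type)
pair and an entry is set iff the patient has ≥ 1 filtered call of that type
touching that arm. Regions carried by ≥ 10 patients in the full cohort
(pooled across strata by default; per-stratum by config) are eligible for
the survival screen. Event-count bins {1, 2–4, ≥5} are reported as
fractions of aberration-positive patients. Characteristic comparisons use
Pearson chi-square without continuity correction, switching to Fisher's
exact test when any expected cell is below 5 (the textbook rule; the R×C
exact test is resampled with a fixed seed for reproducible reports);
"missing" is a reportable category and is included in test statistics by
default.

## Survival screening

Per remission stratum (CR vs advanced):

1. every eligible region is screened with a two-group log-rank test on
   overall survival (univariate Cox by config), significance at p < 0.05;
2. significant regions enter one joint Cox model together with clinical
   covariates chosen by bidirectional stepwise selection on Wald p-values
   (entry p < 0.25, stay p < 0.15; region indicators are forced terms and
   never dropped; ties broken by smallest p then input order; selection
   stops when a selection state repeats, which also terminates the classic
   enter/drop oscillation of a covariate with p between the two
   thresholds);
3. regions still significant in the joint model get final overall-survival
   and cause-specific relapse models. Proportional hazards is checked per
   covariate with the score test on scaled Schoenfeld residuals (rank
   transform); flagged covariates move to the stratification set
   (continuous ones binned into quartiles) and the model is refit once.
   The region indicator itself is protected from stratification — it is
   the exposure whose hazard ratio the model exists to estimate.

Cause-specific relapse treats relapse as the event and censors death
without prior relapse at the death time. Ties use Efron's method (the
method lifelines implements; appropriate for moderately tied registry
times). No multiple-testing correction is applied across regions, matching
the screening procedure being emulated; a Bonferroni flag could be added by
config but is deliberately absent from the default path.

lifelines provides the product-limit estimator, log-rank test, Cox partial
likelihood and the Schoenfeld score test; the test suite cross-checks them
against independent oracles (hand product-limit computation, hand O−E/V
accumulation, a 1-D grid search of the Breslow partial likelihood, and the
classical identity between the log-rank statistic and the Cox score test at
β = 0 on untied data).

## Synthetic cohort generator

Indicators are drawn Bernoulli per region prevalence; events are placed
uniformly inside the named arm (5 Mb up to 80% of the arm) with cell
fractions drawn from an empirical-quantile distribution anchored at
(q25, q50, q75) = (0.29, 0.49, 0.79) on [0.20, 0.95], matching the reported
cell-fraction summaries of this patient population. Death and relapse times
come from two independent cause-specific exponential hazards scaled by
exp(linear predictor); relapse is observed only when it precedes death and
censoring, so overall survival is exactly proportional-hazards and the
cause-specific relapse hazard is exactly exponential — which is what makes
parameter recovery a meaningful check. Default clinical covariates emulate
an adult AML transplant registry mix (median age ≈ 48, 53% male, 27%
advanced disease, 69% peripheral-blood grafts, ~30% reduced-intensity
conditioning); baseline death hazard 0.022/month and relapse hazard
0.018/month put 3-year survival near 45% for a baseline CR patient;
censoring is uniform on 60–220 months (long registry follow-up).

What the generator does **not** emulate: raw probe intensities and
genotype-clustering artifacts, plate/batch effects, LRR attenuation, probe
density variation along the genome, sex chromosomes, sub-2 Mb events, and
correlation between aberration burden and clinical covariates. Passing
tests therefore demonstrate correctness of the pipeline's inference under
the stated signal model, not field performance on any particular array
product.

## Default noise and array geometry

Per-probe noise defaults are lrr_sd = 0.15, baf_sd = 0.03 and het_rate =
0.30 — conventional magnitudes for Illumina-style genotyping arrays (not
derived from any specific dataset). The default synthetic scaffold is 22
autosomes × 2,000 probes over 100 Mb each (≈ 6 AB probes/Mb), so a 10 Mb
event carries ~60 AB probes.

## Numerical choices

* Quantile normalization uses stable argsort; ties map to the same
  reference value by rank order.
* LOWESS runs one robustness iteration with a delta of 0.5% of the GC
  range for near-linear runtime at array scale.
* The segmentation t statistic uses the pooled variance with an 1e-300
  floor; constant segments yield t = 0 and never split.
* Cell-fraction estimates clip to (0, 1]; a gain with Δ ≥ 1/6 is a full
  clone (the closed form diverges there); Δ = 0 is an error — an event
  cannot be called with no deviation.
* Cox non-convergence (monotone likelihood) is retried once with a small
  ridge penalty (0.1) and a warning, capping the estimate.
* 3-year survival is read off the Kaplan–Meier step function at t = 36
  months.
* Every stochastic component takes an explicit seed; sub-seeds are derived
  by SHA-256 hashing of (seed, labels) and stay below 2^31.

## Study sizes used in validation

The simulation studies (in `mcascreen.studies`) use: detection — 100
samples at full array geometry in the test suite, 48 in the acceptance
script; end-to-end survival recovery — 100 replicates of n = 1000
single-stratum cohorts (one region at 5% prevalence, true HR e) in the test
suite, 80 in the script; null-screen calibration — 100/80 replicates of
n = 500 with four null regions; PH calibration — 200/150 replicates of
n = 200. These sizes give binomial standard errors of ~1–3 percentage
points on the reported rates. The end-to-end study uses a single remission
stratum so each replicate contributes exactly one report row and "CI covers
truth" has an unambiguous meaning.

## Known limitations

* Sensitivity for copy-gains fades below f ≈ 0.22 (the Δ threshold);
  losses and CNLOH remain callable to f ≈ 0.10–0.20.
* The ≥ 2 Mb filter and arm-level aggregation are faithful to the emulated
  procedure but discard focal events entirely.
* The Schoenfeld rank-transform score test is mildly conservative at
  moderate sample sizes (observed flag rate ~0.02–0.05 at nominal 0.05,
  n = 200), which the calibration study documents rather than corrects.
* Stepwise selection inherits the usual caveats of data-driven covariate
  selection; the package reproduces the procedure, it does not endorse it
  for causal interpretation.
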