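# Methods

This note documents the models and procedures implemented in `httrpod`,
the choices made where the underlying methodology left the design open,
and what the synthetic-data tests do and do not demonstrate.

## Scope and data model

The pipeline starts from a probe-by-sample matrix of non-negative
integer counts (TempO-Seq-style targeted RNA counting) with per-sample
metadata: chemical, exposure concentration in µM, plate, replicate, and
role (treated or plate-matched solvent control). Everything upstream of
the count matrix — library chemistry, sequencing, trimming, alignment,
counting — is out of scope; QC quantities that require alignment
provenance (e.g. mapped-read fraction) are consumed from metadata, not
computed.

## Synthetic data generator

The generator exists so that every downstream stage can be tested for
parameter recovery with known ground truth.

**Generative model.** For probe *i* in sample *j* at concentration
*c<sub>j</sub>*, counts are negative binomial:
*y<sub>ij</sub>* ~ NB(µ = *m<sub>i</sub>*(*c<sub>j</sub>*)·*s<sub>j</sub>*, size *k<sub>i</sub>*),
where *s<sub>j</sub>* is a log-normal per-sample size factor
(σ = 0.05 by default; an optional per-plate factor, off by default,
exercises plate-matched contrasts). The mean follows a saturating Hill
curve,

m(c) = µ₀ · (1 + (F − 1) · cʰ / (AC₅₀ʰ + cʰ))   (up-regulation),

with down-regulation dividing µ₀ by the same fold-change curve so fold
changes are symmetric on the log scale. NB with probe-specific
dispersion is the standard count model assumed by the differential-
expression machinery this pipeline feeds; dispersions are drawn
log-normally (median size 20, log-SD 0.4), baselines log-normally
(median 100 counts, log-SD 1, floored at 5 so probes clear the CPM
filter), maximal fold changes uniform on [2.5, 6], AC₅₀ log-uniform
over roughly the middle decades of the concentration range, and Hill
coefficients uniform on [1, 2]. These are one-time choices intended to
be typical of a responsive transcript in a concentration series; none
is tuned per test.

**Design defaults.** Eight concentrations (0.001, 0.01, 0.1, 0.5, 1,
5, 10, 50 µM), four replicates per concentration, four plate-matched
solvent controls, one plate. The default test scale is 1,000 probes
with 100 responsive — small enough for a single CPU, large enough for
rank-ordered tPODs.

**Analytic BMC.** For a responsive probe the concentration at which
|log₂ response − log₂ baseline| reaches a benchmark response *b* has
the closed form AC₅₀·(r/(F−1−r))^(1/h) with r = 2ᵇ − 1, unique by
monotonicity and undefined when the curve saturates below *b*. The
ground-truth benchmark uses the delta-method control SD of log₂ counts,
√(1/µ₀ + 1/k)/ln 2, matching the 1-SD benchmark applied during
estimation.

**What the generator does not emulate:** probe-level sequence biases,
attenuator scaling, batch structure beyond a single multiplicative
plate factor, cytotoxicity, and correlation between probes (genes are
generated independently). Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the stated noise model,
not robustness to every artefact of real TempO-Seq data.

## Sample QC

Four rules, each evaluated independently so failure reasons are
enumerable:

- **mapped reads**: library size below 10% of the declared target depth
  (the target must be given explicitly; there is no silent default);
- **Gini**: Gini coefficient of the per-probe count distribution
  > 0.95 (formula Σᵢ(2i − n − 1)x₍ᵢ₎/(nΣx) over ascending sorted
  values);
- **Spearman**: the sample's minimum 1 − ρ distance to every other
  sample exceeds 0.1. The nearest-neighbour aggregation is this
  package's reading (a sample fails only if it is far from *all*
  others); rank correlation is invariant under the log transform, so it
  is computed on raw counts. Distances are computed study-wide.
- **outer fence**: detected probes (≥ 5 reads) or probes capturing the
  top 80% of signal outside the inclusive Tukey outer fences
  [Q1 − 3·IQR, Q3 + 3·IQR], with linear-interpolation quartiles. When
  the IQR is exactly zero (plausible only on small synthetic panels
  where every probe is detected everywhere) there is no spread to
  define outliers from and the rule is inert.

## Probe filters

- **Relevance**: keep a probe when at least 75% of the samples of at
  least one experimental group exceed 0.5 CPM (strict inequality on
  CPM, inclusive on the fraction).
- **Spike**: within each group a probe is a spurious spike when
  max − median ≥ sum/(n_replicates + 1). The source sentence for this
  rule reads inverted; the implemented polarity (remove when the
  inequality holds) matches the rule's evident intent and is
  configurable.

Both filters are idempotent and verified against brute-force
re-evaluation of the formulas on randomized tables.

## Contrast statistics

Counts are normalized by median-of-ratios size factors (the DESeq
estimator: factor = median over all-positive probes of the ratio to the
probe's geometric mean). Per probe, log₂ fold change is the difference
of group means of log₂(normalized + 0.5) and the unadjusted p-value
comes from a Welch t-test on the same scale. This deliberately simple
estimator replaces a shrinkage-based differential-expression fit; it is
adequate here because downstream consumers use unadjusted p-values and
a 1.2-fold threshold, both robust to the absence of shrinkage at n ≥ 4
replicates. The pseudocount 0.5 keeps fold changes finite for zero
groups and is symmetric on the log scale.

## Williams trend prefilter

Group means over the ordered series are amalgamated under a
monotonicity constraint by pool-adjacent-violators; the statistic is
(amalgamated highest-dose mean − control mean)/SE with the pooled
within-group variance and SE = √(s²(1/n_top + 1/n₀)). Both trend
directions are evaluated and the larger-|contrast| direction reported.
Implementation note: only the amalgamated value at the highest dose is
needed, and the last fitted value of PAVA equals the extremal weighted
suffix mean, which vectorizes over thousands of probes and permutation
draws.

P-values come from a two-direction group-label permutation test
(default 1,000 permutations, seeded, add-one correction) rather than
lookup tables — exact small-sample behaviour with no table
interpolation. Degenerate cases: zero pooled variance with equal means
gives statistic 0 and p = 1; with unequal means the p-value floors at
1/(n_perm + 1). A probe passes the prefilter at p < 0.05 and maximum
absolute fold change ≥ 1.5, the fold change taken as the largest
|group mean − control mean| on the log₂ scale across concentrations
(not only at the top dose; configurable).

## Curve fitting and BMC estimation

Responses are per-sample log₂ normalized expression; concentrations are
fit on their natural µM scale (the design spans 4.7 decades, and root
finding below brackets on a log-spaced grid). Five candidate models:

| model  | form                              | curve params |
|--------|-----------------------------------|--------------|
| linear | a + b·c                           | 2 |
| poly2  | a + b₁c + b₂c²                    | 3 |
| power  | a + b·cᵖ, p ∈ [1, 18]             | 3 |
| exp3   | a·exp(±(b·c)ᵈ), d ∈ [1, 18]       | 3 |
| exp5   | a·(r − (r−1)·exp(−(b·c)ᵈ))        | 4 |

Linear and quadratic are closed-form least squares; the power exponent
is profiled (the model is linear in (a, b) for fixed p); the
exponentials use bounded trust-region least squares with two starts
(d = 1 and a steeper start), the exp3 sign and the exp5 asymptote ratio
r fixed to the observed trend direction. Gaussian likelihood with
σ̂² = SS/n gives AIC = 2k − 2·logL with k counting curve parameters
plus one for the variance; the lowest-AIC converged fit wins, ties
broken by fewer parameters then a fixed model order. The variance in
the likelihood is floored at 10⁻¹² so numerically perfect fits tie and
the parsimony tie-break decides.

**BMC.** Benchmark response = 1 SD of the plate-matched control
replicates on the modeling scale (bmr_sd configurable). The BMC is the
smallest c > 0 with |f(c) − f(0)| equal to the benchmark, found by
scanning a 200-point log-spaced grid on (0, c_max] and bisecting the
first bracketing interval — robust to the non-monotone quadratic.

**BMCL/BMCU.** 95% two-sided profile likelihood on the BMC
reparameterization. For each family the benchmark constraint
f(B) − f(0) = ±BMR eliminates the scale parameter in closed form
(e.g. b = Δ/B for linear, (bB)ᵈ = ±ln(1 + Δ/a) for exp3), the
remaining parameters are re-optimized at fixed B, and the bound is
where n·ln(SS(B)/SS_hat) crosses χ²₁(0.95), located by stepping
outward on a 0.25-decade grid and Brent bisection. The upper search is
capped at 10× the highest concentration; an effectively unbounded BMCU
is reported at the cap. Bounds are clipped to bracket the point
estimate.

**Lack-of-fit p.** Likelihood ratio of the selected model against the
per-group-means (saturated) model, df = #groups − #curve parameters,
χ² reference. Which saturated/reduced comparison the original tooling
uses is not published; this LRT is the declared stand-in. High p means
adequate fit; probes with p < 0.1 are removed.

**Post-filters.** Probes are removed when (1) the BMC is undefined or
above the highest analyzed concentration (after stress-flagged
concentrations are excluded), (2) the probe maps to zero or several
genes, (3) lack-of-fit p < 0.1, (4) BMC/BMCL > 20, or
(5) BMCU/BMCL > 40. Survivors collapse to genes keeping the
lowest-BMC probe per gene — the conservative choice where the original
method states only a conversion to gene identifiers.

## tPODs

- **gene25**: BMC of the 25th gene on the ascending curve; its CI
  borrows that gene's BMCL/BMCU. Ties break by (BMC, BMCL, gene id).
  Undefined below 25 surviving genes — no silent fallback.
- **pathway5pct**: minimum over eligible gene sets of the 5th
  percentile of member BMCs; eligibility needs ≥ 3 fitted members,
  ≥ 5% of the annotated set fitted, and ≥ 40 annotated genes.
  Gene-level (post-collapse) BMCs are used, consistent with the
  collapse step.
- **lcrd**: the cited procedure identifies where consistent activity
  begins on the accumulation curve; the concrete rule here — the first
  gene starting a run of 5 genes whose consecutive log₁₀-BMC gaps are
  each ≤ 0.5 — is this package's stand-in, with both parameters
  configurable.
- **er_5pct / er_median**: 5th percentile / median of the ERα
  biomarker members' BMCs; require ≥ 3 fitted members and (by default)
  that the biomarker was called activated at at least one
  concentration.

Percentiles use linear interpolation between order statistics (type-7)
throughout. All methods are invariant to input row order and
equivariant under rescaling of concentration units.

**Bootstrap CI.** Parametric residual bootstrap per member gene:
resample Normal(0, σ̂) residuals around the fitted curve, refit the
originally selected family (no per-resample reselection — model
selection dominates the cost and reselection is not part of the
described procedure), and repeat the BMC analysis, recomputing the
benchmark response from the resampled control replicates so the
sampling noise of a 4-replicate control SD propagates into the
interval. The fraction of the 100 resamples yielding a BMC is the
gene's inclusion probability. Each of the 10,000 simulated experiments
includes gene *g* when a uniform draw falls below that probability and
samples one of its bootstrap BMCs; the tPOD statistic per experiment
gives a distribution whose median is the point estimate and whose
2.5th/97.5th percentiles the CI. Fully seeded; at zero residual noise
the interval collapses to the point statistic.

## Biomarker scoring and stress flagging

DEG lists use unadjusted p < 0.05 and |linear fold change| ≥ 1.2.
The proprietary rank-partitioned correlation service used by the
original analysis is replaced by a directional hypergeometric score:
upper-tail p-values for the concordant and discordant overlaps between
the signed DEG list and the directional marker against the universe of
probes passing the relevance filter, combined as
−log₁₀(p_con) + log₁₀(p_dis). The score is antisymmetric under
direction inversion and keeps the published call semantics: activated
at ≥ +4, suppressed at ≤ −4 (−log p is read as base 10). The
rank-partitioned "running" refinement is intentionally omitted.

A condition is overtly stressed when ≥ 2 stress biomarkers are called
activated; suppression does not count, and cell proliferation (CP) is
excluded from the count by default since widespread CP activation is
not by itself cytotoxic (both configurable). Stressed concentrations
are removed before BMC modeling by capping the highest analyzed
concentration.

## Mixtures

Concentration addition: BMC_pred = (Σ pᵢ/BMCᵢ)⁻¹ over molar fractions
pᵢ. Components lacking a BMC for an endpoint are excluded from the sum
with the remaining fractions kept as-is (equivalent to BMCᵢ = ∞);
renormalization over the active components is available as an option
since the original handling is not stated. Predictions use unrounded
component BMCs; rounding to two decimals happens only at reporting.
The synthetic additivity test builds components sharing one mechanism
with potency ratio ρ (component AC₅₀s scaled by ρ), for which
concentration addition is exact within the Hill family, so the mixture
ground truth is again Hill with AC₅₀ scaled by 1/Σ(pᵢ/ρᵢ).

## Pipeline

Stages communicate only via persisted TSV artifacts so each is
independently re-runnable; the run report records per-stage counts,
the package version, and a configuration hash. Unknown configuration
keys are rejected before any stage runs. Every threshold defaults to
the values above.

## Problem sizes used in the automated checks

Chosen once as the package's standard verification scale: BMC recovery
on 1,000 probes / 100 responsive (8 × 4 design); Williams null
calibration on 2,000 null probes with 1,000 permutations; bootstrap
coverage over 50 replications of an 8-gene set with 100 resamples per
gene and 2,000 simulated experiments (the statistic's distribution is
stable well before the 10,000 used as the production default);
end-to-end additivity on 400 probes / 60 responsive per arm.

## Known limitations

- The Welch-on-log-counts contrast statistic has no dispersion
  shrinkage; at fewer than 4 replicates its p-values are noisier than
  a negative-binomial shrinkage fit would give.
- Profile-likelihood bounds assume the χ²₁ asymptotics of the Gaussian
  working likelihood on log₂ expression.
- The LCRD rule and the lack-of-fit comparison are declared stand-ins
  for procedures whose exact definitions are not published.
- The hypergeometric biomarker score matches the sign/threshold
  semantics of the original correlation service but not its
  rank-partitioned refinement; scores are comparable within this
  pipeline, not numerically interchangeable with the service's.
- Genes are simulated independently; coverage and error-rate results
  do not speak to correlated-gene effects on set-level tPODs.
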