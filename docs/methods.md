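# Methods

## Data model and scales

A cohort is a CpG-by-sample matrix of methylation β values in [0, 1] with a
matching detection-p matrix, a sample sheet (sex, age, twin pair, zygosity,
array chip "sentrix ID", chip slot "sentrix position", six blood cell-type
proportions: CD8T, CD4T, NK, B cell, monocyte, granulocyte) and a probe
annotation (chromosome, position, one of seven gene-region categories,
cross-reactive/polymorphic flags). All regression works on the M scale,
M = log₂(β/(1 − β)), with β clipped to [1e−6, 1 − 1e−6] before the
transform; the inverse is β = 2^M/(1 + 2^M). Missing β calls are excluded
pairwise per CpG (complete case per probe) in every fit.

## Quality control

Order: caller-supplied blacklist (cross-reactive or polymorphic probes)
first, then detection-p masking (calls with p > 0.01 become missing), then
the missingness filter, which removes probes with *strictly more than* 5%
missing calls. The QC report tallies each action; QC is idempotent.
Chromosome selection is an annotation filter, so an X-versus-autosome
comparison (e.g. chromosome 20) is configuration, not code.

Within-sex normalization is full quantile normalization applied separately
to male and female columns: each sample's values are replaced by reference
quantiles (the across-sample mean of sorted values, interpolated onto a
common grid, NaN-aware), preserving within-sample ranks. This is a
deliberate stand-in for array-specific normalization (e.g. subset-quantile
within-array methods), which needs probe-chemistry information that the
data model does not carry; a `--no-normalize` path accepts pre-normalized
input.

Sex balancing reduces the larger sex to the smaller sex's sample count at
whole-twin-pair granularity: pairs are taken in order of |pair mean age −
target| where the target is the smaller sex's mean age (fixed once), ties
broken by lexicographic pair id. A pair that would overshoot the remaining
quota is skipped so a trailing singleton can fill an odd slot; if only full
pairs remain the result can fall one short of the quota, which is logged.
Pairs are never split and the smaller sex is never touched.

## Sex-difference model and permutation FWER

The per-CpG model is M ~ sex with a random intercept per twin pair. All
pairs are like-sex, so sex is constant within pairs and the ML estimate of
the sex coefficient reduces *exactly* to ordinary least squares on
pair-mean M values; the implementation is the pooled-variance two-sample
t-test comparing female-pair means with male-pair means (df = #pairs − 2).
This closed form is what makes the permutation FWER affordable: each of
the K replicates permutes the pair-level sex labels (preserving the
male:female pair ratio — a label shuffle, not Bernoulli resampling), reruns
the identical vectorised test for all CpGs, and records the minimum
p-value. FWER(c) = #{replicate minima strictly below p_obs(c)}/K, with no
+1 correction. The statsmodels `MixedLM` fit of the same model serves as an
independent oracle in the tests (coefficients agree to ~1e−14; p-values to
well under 10%). Degenerate cases (zero pooled variance) yield p = 1 for a
zero effect and p = 0 otherwise; pairs reduced to singletons by
missingness simply contribute single-sample "pair means" (the mild variance
heterogeneity this causes is ignored).

Pattern classification applies the first matching rule per probe, at
α = 0.05 on the FWER and β cut-offs 0.25/0.75 evaluated on all four
sex-by-cohort mean β values: A (significant, female-higher in both
cohorts), D (significant, male-higher in both), ONE_COHORT (significant in
exactly one cohort, either one), B (no sex difference, all means < 0.25),
C (no sex difference, all means > 0.75), REST otherwise; significance in
both cohorts with discordant directions lands in REST and is logged. For
the region-by-pattern contingency (7 gene regions × 5 patterns, df = 24),
ONE_COHORT merges into REST; chi-squared tests use the Pearson statistic
without continuity correction.

## Age-association model

Per sex and per CpG: M ~ age (centred) + six cell proportions, with
crossed random intercepts for sentrix ID, sentrix position and — in twin
cohorts — twin pair, fitted as variance components (single-group mixed
model, REML, an lbfgs→bfgs→powell optimizer cascade). Grouping factors
with one observed level are dropped; when a fit fails the random structure
is sequentially reduced (position first, then chip, then pair) and the last
resort is OLS, flagged per probe. p-values use a t reference with
df = n − #fixed-effects so the zero-variance limit agrees exactly with
OLS. Constant covariate columns (e.g. a cell type with no variation) are
dropped per probe. BH-FDR is computed per (cohort, sex) analysis over all
tested CpGs; missing p propagate missing q. Direction is the sign of the
age slope (hyper if ≥ 0; exactly-zero slopes — measure zero in practice —
count as hyper and are logged).

Replication between two discovery cohorts is scored per age class (both
sexes / male-only / female-only) by k = |set₁ ∩ set₂| with the exact
hypergeometric upper tail P(X ≥ k) for a universe of N post-QC CpGs,
evaluated by log-gamma summation with `logsumexp` (accurate far below
double underflow; a log10 variant is exposed). The observed overlap is
included in the tail — the standard enrichment convention. Validation in a
third cohort requires q < α there, with q computed over *all* the third
cohort's tested CpGs; for the sex-independent class both sexes must pass
(a flag relaxes this to either sex). Sign consistency with both discovery
cohorts is reported as a separate subset.

## Synthetic data generator

The generator is the inverse of the fitted models. Per CpG and sample:

    M = base(pattern, sex) + slope(pattern, sex)·(age − midpoint)
        + pair intercept + chip intercept + slot intercept
        + cell coefficients·(proportions − expected proportions)
        + residual,     β = 2^M/(1 + 2^M).

Defaults (one value each, chosen as realistic for whole-blood 450K data):

| parameter | default | note |
|---|---|---|
| pairs per sex | 36 (older cohort); 113 / 190 in the default study | 72 / 226 / 380 samples |
| age range | 74–88; 56–79 and 78–91 in the default study | co-twins share age exactly |
| base β (A) | ♀ 0.45, ♂ 0.05 | XCI-subject: female near half-methylated |
| base β (B / C) | 0.10 / 0.90 both sexes | escape / high-methylation |
| base β (D) | ♂ 0.60, ♀ 0.30 | male-hypermethylated minority class |
| base β (REST) | 0.50 both | no sex effect |
| age slope | B: −0.02, C: +0.02 M/yr, both sexes; 0 elsewhere | escape sites demethylate, high sites methylate further |
| pair intercept SD | 0.5 M | twin-shared |
| chip SD / slot SD | 0.2 / 0.1 M | slot fixed at half the chip SD |
| residual SD | 0.5 M | equal in both sexes |
| cell Dirichlet α | (4, 7.5, 2.5, 3.5, 3.5, 29) | granulocyte-dominated blood, realistic dispersion |
| cell-effect SD | 0.3 M per unit proportion | per-CpG coefficients |
| detection failure rate | 0.002 | missing completely at random |
| MZ fraction | 0.95 | metadata only; the model conditions on pairing, not zygosity |

CpG counts per pattern default to a 520-site scaled-down X-chromosome
composition (A 200, B 30, C 140, D 10, REST 120, plus 20 ONE_COHORT sites
in the default study) — proportions chosen to mirror the A-dominated,
small-D composition of the real array at roughly 1/20 scale, which keeps
the default test and acceptance runs within interactive runtimes. Gene
regions are assigned with pattern-specific weights (A/B promoter-enriched,
C body-enriched). Samples fill 12-slot chips in random order, one sample
per slot, with the chip count sized to the cohort (overridable). The probe
universe is a deterministic function of the pattern-count map alone, so
cohorts configured with the same map share probe ids and annotation, like
samples run on the same array product. All draws flow from a single root
generator per cohort seed; the study builder derives three child seeds from
one study seed.

Base β levels parametrize the *location* of the logit-normal (the β value
at the centre M). Because the logit-normal mean differs from its location
by a Jensen term, the expected mean β sits slightly off the configured
level (≈ +0.003 at 0.45 under default noise) — well inside the tolerances
used anywhere. ONE_COHORT sites take their sex effect only in cohorts
generated with `one_cohort_active=True` (the first discovery cohort);
elsewhere they behave as REST. Validation cohorts set `twin_pairs=False`,
making every "pair" a singleton. Detection failures draw p ~ U(0.011, 1);
passing calls draw p ~ U(0, 0.01].

### What the generator does and does not emulate

It emulates the variance structure the models assume: twin-shared,
chip-level and slot-level intercepts, cell-composition effects, logit-scale
noise, pattern-specific sex contrasts and age slopes. It does not emulate
probe-chemistry artefacts (Infinium I/II, colour channels), SNP-under-probe
effects, non-Gaussian or sex-heteroscedastic noise, nonlinear age
trajectories, or informative missingness. Passing recovery tests therefore
demonstrate correctness of the estimators under the assumed model, not
robustness to those real-data violations.

### A practical consequence of shared random effects

Within one simulated cohort, the pair/chip intercepts are *one draw shared
by every CpG*: if that draw happens to correlate with age, all CpG-level
age slopes shift together. Per-CpG inference remains marginally calibrated
(verified: empirical type-I error 0.047 at nominal 0.05 over independent
cohort draws), but CpGs within a cohort are strongly dependent. All
recovery and calibration checks therefore average over independent cohort
draws rather than over CpGs of a single cohort, and the distributional
uniformity check runs on an unrelated-individuals, residual-noise-only null
where p-values are genuinely independent. At small cohort sizes with a
zero-variance pair factor, REML's truncated-at-zero variance estimates also
make the mixed-model p-values mildly conservative; at the default study
sizes this effect is negligible.

## Numerical choices

- Chi-squared statistics: `scipy.stats.chi2_contingency` without continuity
  correction; empty rows/columns produce a warning and leave df at its
  nominal (r−1)(c−1).
- BH-FDR: statsmodels `multipletests('fdr_bh')` behind a NaN-propagating
  wrapper; an independent brute-force step-up implementation lives in the
  tests.
- Hypergeometric tail: log-gamma + logsumexp; cross-checked against
  `scipy.stats.hypergeom`, exact rational enumeration at small N, and
  60-digit arbitrary-precision sums at study scale (agreement to 6
  significant figures).
- Ties in quantile normalization get average ranks; the reference
  distribution interpolates each sample's sorted values onto a common
  quantile grid, so samples with different missingness remain comparable.
- Permutation FWER uses strict `<` and divides by K (no +1 term); it is a
  step function of p_obs, monotone non-decreasing.
- Age is centred per fit; the slope is unaffected.
- The balancing tie-break (lexicographic pair id) makes results
  reproducible across platforms.

## Problem sizes

Default synthetic studies use 520 CpGs and 72/226/380-sample cohorts with
K = 2000 permutation replicates; calibration checks use up to 500
independent single-CpG cohorts, and slope-recovery averages 36 cohorts of
100 samples. These sizes give every check comfortable statistical margin
(e.g. the pattern-recovery bar of 95% is met at ~99%+) while keeping a full
test-plus-acceptance run within a few minutes.

## Known limitations

- The within-sex quantile normalizer equalizes full distributions; if the
  two sexes genuinely differ in distribution shape within a sex stratum's
  subgroups, that structure is flattened.
- With unequal pair sizes after missingness, the pair-mean sex test ignores
  the resulting variance heterogeneity (exact only for balanced pairs).
- The third-cohort validation treats the discovery classification as fixed
  (no selection-effect correction), matching standard practice.
- The FWER compares each probe's p against minima pooled over all probes'
  permuted tests (one null distribution for the family), not per-probe
  permutation distributions.
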