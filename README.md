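# xcimeth

Sex-stratified analysis of X-chromosome DNA methylation from 450K-array β
values: inference of X-inactivation (XCI) methylation patterns, sex-specific
age-association modelling with linear mixed models, and cross-cohort
replication statistics — together with a synthetic twin-cohort generator
that provides ground truth for every stage.

## The problem

In female somatic cells one X chromosome is epigenetically silenced (XCI),
largely via DNA methylation, while ~15% of X-linked genes escape silencing.
This makes the X chromosome awkward for epigenome-wide association studies:
male and female samples differ both in X dosage and in methylation
structure, so X-linked CpGs are usually discarded. The approach implemented
here analyses the sexes separately and uses the male–female methylation
contrast itself to infer each CpG's XCI status before asking how
methylation changes with age in each sex.

For a CpG's methylated fraction β ∈ [0, 1], analysis runs on the M scale,
M = log₂(β / (1 − β)). The pipeline stages are:

1. **QC** (`apply_qc`): drop blacklisted (cross-reactive/polymorphic)
   probes, mask calls with detection p > 0.01, drop CpGs with > 5% missing
   calls. Within-sex quantile normalization (`normalize_within_sex`) and
   pair-level sex balancing (`balance_sexes`) equalize the two sex strata.
2. **Sex difference** (`fit_sex_difference`): per CpG, a mixed model of M
   on sex with a random intercept per twin pair; because sex is constant
   within like-sex pairs this is fitted exactly in closed form on pair
   means. Family-wise error (`permutation_fwer`): sex labels are permuted
   across pairs K times, the minimum p of each replicate recorded, and
   FWER(c) = #{replicate minima < p_obs(c)} / K.
3. **Pattern classification** (`classify_patterns`), from two cohorts:
   - **A** — female-hypermethylated in both cohorts (FWER < 0.05): subject
     to XCI;
   - **B** — no sex difference, all four sex-by-cohort mean β < 0.25:
     escaping XCI;
   - **C** — no sex difference, all four mean β > 0.75;
   - **D** — male-hypermethylated in both cohorts;
   - **ONE_COHORT** / **REST** — significant in exactly one cohort /
     everything else.
4. **Age association** (`fit_age_model`), per sex: M ~ age + six blood
   cell-type proportions, with crossed random intercepts for array chip
   (sentrix ID), chip slot (sentrix position) and twin pair;
   Benjamini–Hochberg FDR (`bh_fdr`) per analysis; CpGs classified as
   significant in both sexes / male-only / female-only
   (`classify_age_sites`).
5. **Replication and validation** (`replicate_across_cohorts`,
   `validate_in_third_cohort`): overlap k of two cohorts' significant
   lists (sizes m, n) in a universe of N CpGs is scored with the exact
   upper-tail hypergeometric probability P(X ≥ k), computed in log space;
   replicated CpGs are validated against a third cohort's FDR.

The synthetic generator (`generate_cohort`, `generate_study`) is the exact
inverse of the fitted models: M values are built from pattern- and
sex-specific baselines, per-year age slopes, twin-shared, chip and slot
random intercepts, Dirichlet cell compositions with per-CpG effects, and
Gaussian residuals, then mapped through β = 2^M / (1 + 2^M).

## Worked example

```python
import xcimeth as x

cfg1, cfg2, _ = x.default_study_configs(seed=42)
c1, truth1 = x.generate_cohort(cfg1, "older", one_cohort_active=True)
c2, _ = x.generate_cohort(cfg2, "younger", one_cohort_active=False)

q1, report = x.apply_qc(c1)
q2, _ = x.apply_qc(c2)

r1 = x.sex_difference_with_fwer(x.normalize_within_sex(q1), K=2000, seed=1)
r2 = x.sex_difference_with_fwer(x.normalize_within_sex(q2), K=2000, seed=2)
calls = x.classify_patterns(r1, r2)
print(calls["pattern"].value_counts().to_string())

table, chi2, df, p = x.region_contingency(calls, q1.probes)
print(f"region x pattern chi-squared = {chi2:.1f}, df = {df}, p = {p:.3g}")
```

prints

```
A             200
C             140
REST          120
B              30
ONE_COHORT     20
D              10
region x pattern chi-squared = 87.4, df = 24, p = 3.82e-09
```

Here the two simulated twin cohorts (72 and 226 samples, ages 74–88 and
56–79) contain 520 shared CpGs; the classification recovers every true
A/B/C/D label (the 20 ONE_COHORT sites carry a sex effect only in the first
cohort, by construction), and the chi-squared shows the patterns are not
distributed uniformly over gene regions — the generator places XCI-subject
and XCI-escape sites preferentially at promoters and high-methylation sites
at gene bodies, as observed on real arrays.

The exact overlap probability for, e.g., 55 shared CpGs between significant
lists of 159 and 415 in a universe of 10,096:

```python
>>> x.hypergeometric_tail(10096, 159, 415, 55)
8.471089044080518e-37
```

A command-line interface mirrors the stages:

```sh
xcimeth simulate --config cfg.yaml --outdir sim/ --seed 1
xcimeth qc --beta beta.tsv --detp detp.tsv --samples samples.tsv \
           --annot annot.tsv --chrom X --out qc/
xcimeth xci-patterns --cohort1 qc1/ --cohort2 qc2/ --k 10000 --seed 1 --out pat/
xcimeth age-assoc --cohort qc1/ --sex both --out age1/
xcimeth replicate --class1 age1/age_classes.tsv --class2 age2/age_classes.tsv \
                  --validate age3/ --out rep/
```

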