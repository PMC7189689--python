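"""Per-CpG sex-difference testing and XCI methylation-pattern inference.

The sex model regresses M values on sex (male 0, female 1) with a random
intercept per twin pair.  Because sex is constant within like-sex pairs,
the maximum-likelihood estimate of the sex coefficient reduces exactly to
ordinary least squares on pair-mean M values; the test implemented here is
therefore the pooled-variance two-sample t-test comparing female-pair means
with male-pair means, which makes the K-replicate permutation family-wise
error rate tractable (every replicate is a vectorised group-mean update).

Family-wise error: sex labels are permuted across pairs (preserving the
male:female pair ratio), the full per-CpG test is rerun, and the minimum
p-value of each replicate is recorded.  A CpG's FWER is the fraction of
replicate minima strictly below its observed p-value.

Pattern classification over two cohorts:

* ``A``          — female-hypermethylated in both cohorts (FWER < α), under XCI;
* ``D``          — male-hypermethylated in both cohorts (FWER < α);
* ``ONE_COHORT`` — sex difference significant in exactly one cohort;
* ``B``          — no sex difference and all four sex-by-cohort mean β < 0.25
                   (escaping XCI);
* ``C``          — no sex difference and all four mean β > 0.75;
* ``REST``       — everything else.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GENE_REGIONS, MethylationCohort

logger = logging.getLogger("xcimeth")

PATTERN_ORDER = ["A", "B", "C", "D", "ONE_COHORT", "REST"]
CONTINGENCY_PATTERNS = ["A", "B", "C", "D", "REST"]


# ---------------------------------------------------------------------------
# pair-mean reduction
# ---------------------------------------------------------------------------

def _pair_mean_design(cohort: MethylationCohort):
    """Collapse the M matrix to pair means.

    Returns ``(pm, mask, is_female)``: pair-mean matrix (CpGs x pairs, NaN
    where a pair has no usable call), its finiteness mask, and the boolean
    sex vector per pair.  Missing β calls are excluded pairwise per CpG.
    """
    M = cohort.m_values().to_numpy()
    pair_ids = cohort.samples["twin_pair_id"].to_numpy()
    codes, uniq = pd.factorize(pair_ids)
    n_pairs = len(uniq)
    ind = np.zeros((M.shape[1], n_pairs))
    ind[np.arange(M.shape[1]), codes] = 1.0

    fin = np.isfinite(M)
    counts = fin @ ind                              # CpG x pair call counts
    sums = np.where(fin, M, 0.0) @ ind
    with np.errstate(invalid="ignore", divide="ignore"):
        pm = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    sex_per_pair = pd.Series(
        cohort.samples["sex"].to_numpy(), index=pair_ids
    ).groupby(level=0).agg(lambda s: s.iloc[0]).loc[uniq]
    mixed = (
        pd.Series(cohort.samples["sex"].to_numpy(), index=pair_ids)
        .groupby(level=0).nunique() > 1
    )
    if mixed.any():
        raise ValueError("sex differs within twin pair(s): "
                         f"{list(mixed.index[mixed])[:5]}")
    return pm, counts > 0, (sex_per_pair == "female").to_numpy()


def _two_sample_on_pairs(pm, mask, is_female):
    """Vectorised pooled-variance two-sample t over pair means.

    Returns (effect, p, n_female, n_male) per CpG, effect = female − male.
    Zero pooled variance degenerates to p=1 (no effect) or p=0.
    """
    g = is_female.astype(float)
    h = 1.0 - g
    a = np.where(mask, pm, 0.0)
    a2 = a * a
    n1 = mask @ g
    n0 = mask @ h
    s1 = a @ g
    s0 = a @ h
    q1 = a2 @ g
    q0 = a2 @ h
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = s1 / n1
        m0 = s0 / n0
        ss = (q1 - n1 * m1 ** 2) + (q0 - n0 * m0 ** 2)
        df = n1 + n0 - 2
        var = ss / df
        effect = m1 - m0
        t = effect / np.sqrt(var * (1 / n1 + 1 / n0))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    invalid = (n1 < 2) | (n0 < 2) | (df < 1)
    degen = ~invalid & ~np.isfinite(t)
    if degen.any():
        p[degen] = np.where(effect[degen] == 0, 1.0, 0.0)
    p[invalid] = np.nan
    effect[invalid] = np.nan
    return effect, p, n1, n0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fit_sex_difference(cohort: MethylationCohort) -> pd.DataFrame:
    """Per-CpG sex effect (female − male, M scale) and two-sided p-value.

    Output columns: ``sex_effect``, ``p_obs``, ``fwer`` (NaN until
    :func:`permutation_fwer` fills it), ``mean_beta_male``,
    ``mean_beta_female``.
    """
    pm, mask, is_female = _pair_mean_design(cohort)
    if is_female.sum() < 2 or (~is_female).sum() < 2:
        raise ValueError("need at least 2 twin pairs of each sex")
    effect, p, _, _ = _two_sample_on_pairs(pm, mask, is_female)

    beta = cohort.beta.to_numpy(float)
    female_cols = (cohort.samples["sex"] == "female").to_numpy()
    with np.errstate(invalid="ignore"):
        mean_f = np.nanmean(beta[:, female_cols], axis=1)
        mean_m = np.nanmean(beta[:, ~female_cols], axis=1)
    return pd.DataFrame({
        "sex_effect": effect,
        "p_obs": p,
        "fwer": np.nan,
        "mean_beta_male": mean_m,
        "mean_beta_female": mean_f,
    }, index=cohort.beta.index.rename("probe_id"))


def fwer_from_minima(minima, p_obs) -> np.ndarray:
    """FWER(c) = #{replicate minima strictly below p_obs(c)} / K.

    ``minima`` is the list of per-replicate minimum p-values; no +1
    correction is applied.
    """
    minima = np.asarray(minima, float)
    if minima.size == 0:
        raise ValueError("need at least one permutation replicate")
    p_obs = np.atleast_1d(np.asarray(p_obs, float))
    fwer = (minima[None, :] < p_obs[:, None]).sum(axis=1) / minima.size
    fwer[~np.isfinite(p_obs)] = np.nan
    return fwer


def permutation_fwer(
    cohort: MethylationCohort,
    p_obs: pd.Series | np.ndarray,
    K: int = 10_000,
    seed: int = 0,
) -> pd.Series:
    """Permutation family-wise error rate for the per-CpG sex test.

    FWER(c) = #{replicates whose minimum p-value < p_obs(c)} / K, with sex
    labels permuted at twin-pair level (singleton pairs degrade to a
    sample-level shuffle, which is logged).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    p_obs = np.asarray(p_obs, float)
    pm, mask, is_female = _pair_mean_design(cohort)
    if pm.shape[1] == cohort.n_samples and cohort.samples[
            "twin_pair_id"].nunique() == cohort.n_samples:
        logger.info("no twin structure: permuting sample-level sex labels")
    rng = np.random.default_rng(seed)
    labels = is_female.copy()
    minima = np.empty(K)
    for i in range(K):
        rng.shuffle(labels)           # preserves the female:male pair ratio
        _, p, _, _ = _two_sample_on_pairs(pm, mask, labels)
        minima[i] = np.nanmin(p)
    fwer = fwer_from_minima(minima, p_obs)
    index = (p_obs.index if isinstance(p_obs, pd.Series)
             else cohort.beta.index)
    return pd.Series(fwer, index=index, name="fwer")


def sex_difference_with_fwer(
    cohort: MethylationCohort, K: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Convenience: fit the sex model and fill in the permutation FWER."""
    res = fit_sex_difference(cohort)
    res["fwer"] = permutation_fwer(cohort, res["p_obs"], K=K, seed=seed)
    return res


def classify_patterns(
    results_c1: pd.DataFrame,
    results_c2: pd.DataFrame,
    alpha_fwer: float = 0.05,
    low_cut: float = 0.25,
    high_cut: float = 0.75,
) -> pd.DataFrame:
    """Assign each CpG an XCI pattern from two cohorts' sex-test results.

    Rule order: A, D, ONE_COHORT, B, C, REST (first match wins); CpGs
    significant in both cohorts with discordant directions land in REST.
    """
    if not results_c1.index.equals(results_c2.index):
        if set(results_c1.index) != set(results_c2.index):
            raise ValueError("cohorts test different probe sets")
        results_c2 = results_c2.loc[results_c1.index]

    sig1 = (results_c1["fwer"] < alpha_fwer).to_numpy()
    sig2 = (results_c2["fwer"] < alpha_fwer).to_numpy()
    up1 = (results_c1["sex_effect"] > 0).to_numpy()
    up2 = (results_c2["sex_effect"] > 0).to_numpy()
    means = np.column_stack([
        results_c1["mean_beta_male"], results_c1["mean_beta_female"],
        results_c2["mean_beta_male"], results_c2["mean_beta_female"],
    ])

    pattern = np.full(len(results_c1), "REST", dtype=object)
    both = sig1 & sig2
    pattern[both & up1 & up2] = "A"
    pattern[both & ~up1 & ~up2] = "D"
    discordant = both & (up1 != up2)
    if discordant.any():
        logger.warning(
            "%d CpG(s) significant in both cohorts with discordant "
            "directions -> REST", int(discordant.sum()),
        )
    pattern[sig1 ^ sig2] = "ONE_COHORT"
    nonsig = ~sig1 & ~sig2
    pattern[nonsig & (means < low_cut).all(axis=1)] = "B"
    pattern[nonsig & (means > high_cut).all(axis=1)] = "C"

    out = pd.DataFrame({"pattern": pattern}, index=results_c1.index)
    for tag, res in (("c1", results_c1), ("c2", results_c2)):
        out[f"fwer_{tag}"] = res["fwer"].to_numpy()
        out[f"sign_{tag}"] = np.sign(res["sex_effect"].to_numpy())
        out[f"mean_beta_male_{tag}"] = res["mean_beta_male"].to_numpy()
        out[f"mean_beta_female_{tag}"] = res["mean_beta_female"].to_numpy()
    return out


def chi2_independence(table: np.ndarray | pd.DataFrame):
    """Pearson chi-squared test of independence (no continuity correction)."""
    arr = np.asarray(table, float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        logger.warning("contingency table has empty row(s)/column(s); "
                       "df left unadjusted")
        arr = arr + 0.0
        keep_r = arr.sum(axis=1) > 0
        keep_c = arr.sum(axis=0) > 0
        stat, _, _, _ = stats.chi2_contingency(
            arr[np.ix_(keep_r, keep_c)], correction=False
        )
        df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
        return stat, df, stats.chi2.sf(stat, df)
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    # keep the nominal df even if scipy ever adjusted it
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    return stat, df, p


def region_contingency(
    calls: pd.DataFrame, probes: pd.DataFrame
) -> tuple[pd.DataFrame, float, int, float]:
    """Gene-region x pattern contingency table with a chi-squared test.

    ONE_COHORT calls are merged into REST, giving a 7-region x 5-pattern
    table.  Returns ``(table_with_margins, chi2, df, p)``.
    """
    missing = calls.index.difference(probes.index)
    if len(missing):
        raise ValueError(f"unannotated probes: {list(missing[:5])}")
    pattern = calls["pattern"].replace({"ONE_COHORT": "REST"})
    region = probes.loc[calls.index, "gene_region"]
    table = (
        pd.crosstab(region, pattern)
        .reindex(index=GENE_REGIONS, columns=CONTINGENCY_PATTERNS,
                 fill_value=0)
        .rename_axis(index="gene_region", columns="pattern")
    )
    stat, df, p = chi2_independence(table)
    with_margins = table.copy()
    with_margins["Total"] = table.sum(axis=1)
    with_margins.loc["Total"] = with_margins.sum(axis=0)
    return with_margins, float(stat), int(df), float(p)
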