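"""Sex-stratified age-association models, FDR, and summary statistics.

For each CpG within one sex, methylation M is regressed on age plus the six
blood cell-type proportions (CD8T, CD4T, NK, Bcell, Mono, Gran), with
crossed random intercepts for array chip (sentrix ID), chip slot (sentrix
position) and — in twin cohorts — twin pair.  The quantity of interest is
the age slope β1 (M units per year): β1 > 0 is an age-associated methylation
increase (hyper), β1 < 0 a decrease (hypo).  Significance is controlled per
analysis with the Benjamini–Hochberg FDR.

Random effects are fitted as variance components in a single-group mixed
model.  Grouping factors with one observed level are dropped; if a fit
fails it is retried with the random structure sequentially reduced
(position first, then chip, then pair), ending at ordinary least squares.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .cohort import CELL_TYPES, MethylationCohort
from .sexdiff import chi2_independence

logger = logging.getLogger("xcimeth")

AGE_ENRICH_PATTERNS = ["A", "B", "C", "D", "REST"]

_RE_FACTORS = ["sentrix_position", "sentrix_id", "twin_pair_id"]
#: reduction order when a mixed fit fails (drop from the left)
_REDUCTIONS = [_RE_FACTORS, _RE_FACTORS[1:], _RE_FACTORS[2:], []]


def _dummies(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series.astype(str), dtype=float).to_numpy()


def _fit_one_probe(y, X, groups: dict[str, pd.Series], df_resid: int):
    """Fit one CpG's model; returns (slope, se, p, used_ols).

    ``X`` has the age column first (after the constant).  p-values use a
    t reference with the OLS residual df, so the zero-variance limit of the
    mixed model agrees with ordinary least squares.
    """
    for factors in _REDUCTIONS:
        usable = {
            f: g for f, g in groups.items()
            if f in factors and g.nunique() > 1
        }
        if not usable:
            break
        names = list(usable)
        mats = [[_dummies(usable[f])] for f in names]
        cols = [[[str(c) for c in range(m[0].shape[1])]] for m in mats]
        vc = VCSpec(names=names, colnames=cols, mats=mats)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = MixedLM(y, X, groups=np.ones(len(y)), exog_vc=vc)
                fit = model.fit(reml=True, method="lbfgs", maxiter=200)
                slope = float(np.asarray(fit.fe_params)[1])
                se = float(np.asarray(fit.bse_fe)[1])
            if not (np.isfinite(slope) and np.isfinite(se) and se > 0):
                raise ValueError("degenerate mixed fit")
            t = slope / se
            p = 2.0 * stats.t.sf(abs(t), df_resid)
            return slope, se, p, False
        except Exception:
            continue
    ols = sm.OLS(y, X).fit()
    return (float(ols.params[1]), float(ols.bse[1]),
            float(ols.pvalues[1]), True)


def fit_age_model(cohort: MethylationCohort, sex: str) -> pd.DataFrame:
    """Per-CpG age slope, SE and p-value within one sex.

    Output columns: ``sex``, ``slope``, ``se``, ``p_value``, ``direction``
    (hyper/hypo), ``used_ols`` (fallback flag); ``q_value`` is left unset
    (see :func:`bh_fdr`).  Complete-case per probe.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    missing = [c for c in CELL_TYPES + ["age"] if c not in cohort.samples]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    sub = cohort.subset_samples(
        cohort.samples.index[cohort.samples["sex"] == sex]
    )
    if sub.n_samples < 10:
        raise ValueError(f"need >= 10 {sex} samples, have {sub.n_samples}")

    M = sub.m_values().to_numpy()
    meta = sub.samples
    age_c = meta["age"].to_numpy(float)
    age_c = age_c - age_c.mean()           # centred for numerical stability
    cells = meta[CELL_TYPES].to_numpy(float)
    X_full = np.column_stack([np.ones(sub.n_samples), age_c, cells])

    rows = []
    n_ols = 0
    for i, probe in enumerate(sub.beta.index):
        y = M[i]
        keep = np.isfinite(y)
        y = y[keep]
        X = X_full[keep]
        # drop constant covariate columns (keep intercept and age)
        var = X.var(axis=0)
        col_keep = np.ones(X.shape[1], bool)
        col_keep[2:] = var[2:] > 0
        X = X[:, col_keep]
        if len(y) <= X.shape[1] + 1 or var[1] == 0:
            rows.append((np.nan, np.nan, np.nan, True))
            n_ols += 1
            continue
        groups = {
            f: meta.loc[keep, f] for f in _RE_FACTORS
            if f in meta and meta.loc[keep, f].notna().all()
        }
        if not cohort.samples["twin_pair_id"].duplicated().any():
            groups.pop("twin_pair_id", None)   # validation cohort: singletons
        slope, se, p, used_ols = _fit_one_probe(
            y, X, groups, df_resid=len(y) - X.shape[1]
        )
        n_ols += used_ols
        rows.append((slope, se, p, used_ols))
    if n_ols:
        logger.info("fit_age_model(%s, %s): %d/%d probes fell back to OLS",
                    cohort.cohort_label, sex, n_ols, sub.n_probes)

    out = pd.DataFrame(
        rows, columns=["slope", "se", "p_value", "used_ols"],
        index=sub.beta.index.rename("probe_id"),
    )
    out.insert(0, "sex", sex)
    out["direction"] = np.where(out["slope"] < 0, "hypo", "hyper")
    out.loc[out["slope"].isna(), "direction"] = pd.NA
    return out


# ---------------------------------------------------------------------------
# FDR and site classification
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up q-values; NaN p-values propagate NaN."""
    arr = np.asarray(p_values, float)
    out = np.full(arr.shape, np.nan)
    fin = np.isfinite(arr)
    if ((arr[fin] < 0) | (arr[fin] > 1)).any():
        raise ValueError("p-values outside [0,1]")
    if fin.any():
        out[fin] = multipletests(arr[fin], method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(out, index=p_values.index, name="q_value")
    return out


def add_q_values(results: pd.DataFrame) -> pd.DataFrame:
    """Attach BH q-values over all tested CpGs of one analysis."""
    results = results.copy()
    results["q_value"] = bh_fdr(results["p_value"])
    return results


def classify_age_sites(
    male_results: pd.DataFrame,
    female_results: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-CpG class by which sexes reach q < alpha, with directions.

    Classes: ``both``, ``male_only``, ``female_only``, ``neither``.
    """
    if set(male_results.index) != set(female_results.index):
        raise ValueError("male and female results cover different probes")
    female_results = female_results.loc[male_results.index]
    sig_m = (male_results["q_value"] < alpha).to_numpy()
    sig_f = (female_results["q_value"] < alpha).to_numpy()
    cls = np.select(
        [sig_m & sig_f, sig_m & ~sig_f, ~sig_m & sig_f],
        ["both", "male_only", "female_only"],
        default="neither",
    )
    return pd.DataFrame({
        "age_class": cls,
        "direction_male": male_results["direction"].to_numpy(),
        "direction_female": female_results["direction"].to_numpy(),
        "q_male": male_results["q_value"].to_numpy(),
        "q_female": female_results["q_value"].to_numpy(),
        "slope_male": male_results["slope"].to_numpy(),
        "slope_female": female_results["slope"].to_numpy(),
    }, index=male_results.index)


def percent_hypermethylated(results: pd.DataFrame) -> float:
    """100 x hyper / (hyper + hypo) over a (significant) result subset.

    Exactly-zero slopes count as hyper (logged); an empty subset returns NaN.
    """
    slopes = results["slope"].dropna()
    if slopes.empty:
        logger.warning("percent_hypermethylated: empty subset")
        return float("nan")
    n_zero = int((slopes == 0).sum())
    if n_zero:
        logger.info("%d zero slope(s) counted as hypermethylated", n_zero)
    return 100.0 * float((slopes >= 0).sum()) / len(slopes)


def pattern_age_enrichment(
    calls: pd.DataFrame,
    results: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float, int, float]:
    """Significance-by-pattern contingency (q <= alpha vs q > alpha).

    ONE_COHORT calls merge into REST, giving a 2 x 5 table (df = 4).
    Returns ``(table with a "% sig" row, chi2, df, p)``.
    """
    common = calls.index.intersection(results.index)
    pattern = calls.loc[common, "pattern"].replace({"ONE_COHORT": "REST"})
    q = results.loc[common, "q_value"]
    sig = pd.Series(np.where(q <= alpha, "significant", "insignificant"),
                    index=common)
    table = (
        pd.crosstab(sig, pattern)
        .reindex(index=["insignificant", "significant"],
                 columns=AGE_ENRICH_PATTERNS, fill_value=0)
        .rename_axis(index="age_association", columns="pattern")
    )
    stat, df, p = chi2_independence(table)
    out = table.astype(float).copy()
    out.loc["% sig"] = 100.0 * table.loc["significant"] / table.sum(axis=0)
    return out, float(stat), int(df), float(p)
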