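"""Cross-cohort replication and third-cohort validation statistics.

Replication between two discovery cohorts is scored per age-association
class (both sexes / male-only / female-only) by the overlap of significant
CpG lists, with an exact upper-tail hypergeometric probability: drawing n
of N CpGs when m are marked, the p-value is P(X >= k) for the observed
overlap k.  The tail is evaluated in log space (log-gamma + logsumexp) so
probabilities at magnitudes far below double underflow of individual terms
remain accurate.

Validation in a third, unrelated cohort requires the replicated CpG to
reach q < alpha there (q-values computed over all the third cohort's tested
CpGs, not just the replicated subset); sign consistency with the discovery
slopes is reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger("xcimeth")

AGE_CLASSES = ["both", "male_only", "female_only"]


# ---------------------------------------------------------------------------
# hypergeometric tail
# ---------------------------------------------------------------------------

def hypergeometric_tail(N: int, m: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, m, n), evaluated in log space.

    N: universe size; m, n: the two marked-set sizes; k: observed overlap.
    """
    N, m, n, k = int(N), int(m), int(n), int(k)
    if m < 0 or n < 0 or m > N or n > N:
        raise ValueError("require 0 <= m, n <= N")
    if k < 0 or k > min(m, n):
        raise ValueError("require 0 <= k <= min(m, n)")
    if k <= max(0, m + n - N):
        return 1.0
    i = np.arange(k, min(m, n) + 1)
    log_pmf = (
        gammaln(m + 1) - gammaln(i + 1) - gammaln(m - i + 1)
        + gammaln(N - m + 1) - gammaln(n - i + 1)
        - gammaln(N - m - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def log10_hypergeometric_tail(N: int, m: int, n: int, k: int) -> float:
    """log10 of :func:`hypergeometric_tail` (usable below double underflow)."""
    N, m, n, k = int(N), int(m), int(n), int(k)
    if k < 0 or k > min(m, n) or m > N or n > N:
        raise ValueError("invalid (N, m, n, k)")
    if k <= max(0, m + n - N):
        return 0.0
    i = np.arange(k, min(m, n) + 1)
    log_pmf = (
        gammaln(m + 1) - gammaln(i + 1) - gammaln(m - i + 1)
        + gammaln(N - m + 1) - gammaln(n - i + 1)
        - gammaln(N - m - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(0.0, logsumexp(log_pmf) / np.log(10.0)))


@dataclass
class OverlapTest:
    """Overlap of two significant-CpG lists within a universe of N CpGs."""

    N: int
    m: int
    n: int
    k: int
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.p_value = hypergeometric_tail(self.N, self.m, self.n, self.k)

    @property
    def pct_in_first(self) -> float:
        return 100.0 * self.k / self.m if self.m else float("nan")

    @property
    def pct_in_second(self) -> float:
        return 100.0 * self.k / self.n if self.n else float("nan")


# ---------------------------------------------------------------------------
# replication across two cohorts
# ---------------------------------------------------------------------------

def replicate_across_cohorts(
    class_c1: pd.DataFrame,
    class_c2: pd.DataFrame,
    universe_size: int | None = None,
) -> dict[str, dict]:
    """Overlap tests per age-association class between two cohorts.

    ``class_c1``/``class_c2`` are :func:`~xcimeth.ageassoc.classify_age_sites`
    outputs on a shared probe universe.  Returns, per class, the
    :class:`OverlapTest` and the replicated probe list.
    """
    if set(class_c1.index) != set(class_c2.index):
        raise ValueError("cohorts classified different probe universes")
    class_c2 = class_c2.loc[class_c1.index]
    N = len(class_c1) if universe_size is None else int(universe_size)
    out = {}
    for cls in AGE_CLASSES:
        set1 = set(class_c1.index[class_c1["age_class"] == cls])
        set2 = set(class_c2.index[class_c2["age_class"] == cls])
        shared = sorted(set1 & set2)
        test = OverlapTest(N=N, m=len(set1), n=len(set2), k=len(shared))
        out[cls] = {"test": test, "replicated": shared}
    return out


# ---------------------------------------------------------------------------
# third-cohort validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    replicated: list[str]
    validated: list[str]
    sign_consistent: list[str]

    @property
    def validation_rate(self) -> float:
        """Percent of replicated CpGs reaching significance in the third
        cohort (NaN when nothing replicated)."""
        if not self.replicated:
            return float("nan")
        return 100.0 * len(self.validated) / len(self.replicated)


def validate_in_third_cohort(
    replicated: dict[str, dict] | dict[str, list],
    third_male: pd.DataFrame,
    third_female: pd.DataFrame,
    discovery_class_c1: pd.DataFrame | None = None,
    discovery_class_c2: pd.DataFrame | None = None,
    alpha: float = 0.05,
    both_requires_both_sexes: bool = True,
) -> dict[str, ValidationResult]:
    """Validate replicated CpGs in an independent cohort.

    ``third_male``/``third_female`` are per-sex age results of the third
    cohort with ``q_value`` computed over all its tested CpGs.  A male_only
    (female_only) CpG validates if q < alpha in the third cohort's male
    (female) stratum; a "both" CpG requires q < alpha in both sexes (or in
    either, with ``both_requires_both_sexes=False``).  When the discovery
    classifications are supplied, the sign-consistent subset additionally
    requires the third-cohort slope to match the direction seen in both
    discovery cohorts.
    """
    out = {}
    for cls in AGE_CLASSES:
        entry = replicated.get(cls, {})
        probes = entry["replicated"] if isinstance(entry, dict) else entry
        probes = list(probes)
        present = [p for p in probes
                   if p in third_male.index and p in third_female.index]
        dropped = len(probes) - len(present)
        if dropped:
            logger.warning(
                "%s: %d replicated CpG(s) absent from the validation cohort "
                "excluded from the denominator", cls, dropped,
            )
        qm = third_male.loc[present, "q_value"]
        qf = third_female.loc[present, "q_value"]
        if cls == "male_only":
            ok = qm < alpha
        elif cls == "female_only":
            ok = qf < alpha
        elif both_requires_both_sexes:
            ok = (qm < alpha) & (qf < alpha)
        else:
            ok = (qm < alpha) | (qf < alpha)
        validated = list(pd.Index(present)[ok.to_numpy()])

        sign_consistent = validated
        if discovery_class_c1 is not None and discovery_class_c2 is not None:
            strata = {"male_only": ["slope_male"],
                      "female_only": ["slope_female"],
                      "both": ["slope_male", "slope_female"]}[cls]
            keep = []
            for probe in validated:
                good = True
                for col in strata:
                    third = third_male if col == "slope_male" else third_female
                    s3 = np.sign(third.loc[probe, "slope"])
                    s1 = np.sign(discovery_class_c1.loc[probe, col])
                    s2 = np.sign(discovery_class_c2.loc[probe, col])
                    good &= (s1 == s2 == s3)
                if good:
                    keep.append(probe)
            sign_consistent = keep
        out[cls] = ValidationResult(
            replicated=present, validated=validated,
            sign_consistent=list(sign_consistent),
        )
    return out


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def replication_summary(
    results_c1: dict[str, pd.DataFrame],
    results_c2: dict[str, pd.DataFrame],
    class_c1: pd.DataFrame,
    class_c2: pd.DataFrame,
    replicated: dict[str, dict],
    validation: dict[str, ValidationResult] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-class summary: hyper/hypo counts, replication and validation rates.

    ``results_c1``/``results_c2`` map sex -> per-sex age results (with
    q-values) for the two discovery cohorts.
    """
    from .ageassoc import percent_hypermethylated

    rows = {}
    for label, res_by_sex, cls_df in (
        ("cohort1", results_c1, class_c1),
        ("cohort2", results_c2, class_c2),
    ):
        for cls in AGE_CLASSES:
            probes = cls_df.index[cls_df["age_class"] == cls]
            sexes = {"both": ["male", "female"],
                     "male_only": ["male"],
                     "female_only": ["female"]}[cls]
            # direction within the class, judged in the relevant stratum
            sub = pd.concat(
                [res_by_sex[s].loc[probes] for s in sexes]
            ) if len(probes) else pd.DataFrame(columns=["slope"])
            n_hyper = int((sub["slope"] >= 0).sum())
            n_hypo = int((sub["slope"] < 0).sum())
            rows.setdefault((label, "n_hyper"), {})[cls] = n_hyper
            rows.setdefault((label, "n_hypo"), {})[cls] = n_hypo
            rows.setdefault((label, "pct_hyper"), {})[cls] = (
                percent_hypermethylated(sub) if len(sub) else float("nan")
            )
    for cls in AGE_CLASSES:
        test = replicated[cls]["test"]
        rows.setdefault(("replication", "k"), {})[cls] = test.k
        rows.setdefault(("replication", "pct_cohort1"), {})[cls] = \
            test.pct_in_first
        rows.setdefault(("replication", "pct_cohort2"), {})[cls] = \
            test.pct_in_second
        rows.setdefault(("replication", "hypergeom_p"), {})[cls] = \
            test.p_value
        if validation is not None:
            v = validation[cls]
            rows.setdefault(("validation", "n_validated"), {})[cls] = \
                len(v.validated)
            rows.setdefault(("validation", "pct_validated"), {})[cls] = \
                v.validation_rate
    table = pd.DataFrame(rows).T
    table.index = pd.MultiIndex.from_tuples(table.index)
    return table[AGE_CLASSES]
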