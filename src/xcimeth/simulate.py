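"""Synthetic twin-cohort methylation generator.

Generates like-sex twin-pair cohorts whose β values carry the statistical
structure the analysis pipeline assumes, as the exact inverse of the fitted
models: on the M (log2-logit) scale,

    M = base(pattern, sex) + slope(pattern, sex) * (age - midpoint)
        + pair intercept + chip intercept + position intercept
        + cell-composition term + residual,

then β = 2^M / (1 + 2^M).  Five XCI-related site classes are simulated:

* ``A``    — female-hypermethylated (subject to XCI; β near 0.5 in females,
             near 0 in males),
* ``B``    — low methylation in both sexes (escaping XCI),
* ``C``    — high methylation in both sexes,
* ``D``    — male-hypermethylated,
* ``REST`` — intermediate, no sex effect,

plus optional ``ONE_COHORT`` sites that carry a sex effect only in cohorts
generated with ``one_cohort_active=True`` (used for the first of a pair of
discovery cohorts).

Ground truth (per-CpG pattern and generating effects, per-sample random
intercepts) is returned alongside each cohort for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CELL_TYPES, GENE_REGIONS, MethylationCohort, beta_to_m, m_to_beta,
    write_cohort,
)

PATTERNS = ["A", "B", "C", "D", "REST"]

#: gene-region sampling weights per pattern: XCI-subject (A) and escape (B)
#: sites concentrate at promoters, high-methylation (C) sites at gene bodies.
_REGION_WEIGHTS = {
    #            1stExon 3'UTR 5'UTR Body Intergenic TSS1500 TSS200
    "A":          [0.11, 0.005, 0.17, 0.16, 0.10, 0.20, 0.26],
    "B":          [0.07, 0.005, 0.16, 0.14, 0.18, 0.19, 0.27],
    "C":          [0.05, 0.095, 0.08, 0.30, 0.19, 0.20, 0.09],
    "D":          [0.05, 0.09,  0.25, 0.22, 0.15, 0.16, 0.07],
    "REST":       [0.06, 0.04,  0.15, 0.20, 0.19, 0.22, 0.14],
    "ONE_COHORT": [0.08, 0.02,  0.16, 0.18, 0.15, 0.20, 0.21],
}

_SENTRIX_POSITIONS = [f"R{r:02d}C{c:02d}" for r in range(1, 7)
                      for c in range(1, 3)]


class SimulationConfigError(ValueError):
    """Invalid generator configuration."""


def _default_base_beta() -> dict:
    return {
        ("A", "female"): 0.45, ("A", "male"): 0.05,
        ("B", "female"): 0.10, ("B", "male"): 0.10,
        ("C", "female"): 0.90, ("C", "male"): 0.90,
        ("D", "female"): 0.30, ("D", "male"): 0.60,
        ("REST", "female"): 0.50, ("REST", "male"): 0.50,
        ("ONE_COHORT", "female"): 0.45, ("ONE_COHORT", "male"): 0.05,
    }


def _default_age_slope() -> dict:
    # M units per year; escape sites demethylate, high-methylation sites
    # methylate further with age, in both sexes
    slopes = {(p, s): 0.0 for p in PATTERNS + ["ONE_COHORT"]
              for s in ("female", "male")}
    slopes[("B", "female")] = slopes[("B", "male")] = -0.02
    slopes[("C", "female")] = slopes[("C", "male")] = +0.02
    return slopes


def _default_cpg_counts() -> dict:
    # scaled-down 450K X-chromosome composition (A-dominated, small D class)
    return {"A": 200, "B": 30, "C": 140, "D": 10, "REST": 120}


@dataclass
class SimulationConfig:
    """Parameters of one simulated cohort (defaults: elderly-twin study)."""

    n_pairs_per_sex: int = 36
    mz_fraction: float = 0.95
    age_range: tuple[float, float] = (74.0, 88.0)
    n_cpgs_per_pattern: dict = field(default_factory=_default_cpg_counts)
    pattern_base_beta: dict = field(default_factory=_default_base_beta)
    age_slope: dict = field(default_factory=_default_age_slope)
    pair_intercept_sd: float = 0.5
    #: number of array chips; None sizes chips realistically (12 slots each)
    batch_count: int | None = None
    batch_sd: float = 0.2
    residual_sd: float = 0.5
    cell_dirichlet_alpha: tuple = (4.0, 7.5, 2.5, 3.5, 3.5, 29.0)
    cell_effect_sd: float = 0.3
    detection_fail_rate: float = 0.002
    seed: int = 0
    #: twin cohorts pair samples; validation cohorts use singleton "pairs"
    twin_pairs: bool = True

    def __post_init__(self) -> None:
        if self.n_pairs_per_sex <= 0:
            raise SimulationConfigError("n_pairs_per_sex must be positive")
        if not all(v >= 0 for v in self.n_cpgs_per_pattern.values()):
            raise SimulationConfigError("CpG counts must be >= 0")
        if sum(self.n_cpgs_per_pattern.values()) <= 0:
            raise SimulationConfigError("at least one CpG must be simulated")
        for p in (self.mz_fraction, self.detection_fail_rate):
            if not 0 <= p <= 1:
                raise SimulationConfigError("proportions must lie in [0,1]")
        for sd in (self.pair_intercept_sd, self.batch_sd, self.residual_sd,
                   self.cell_effect_sd):
            if sd < 0:
                raise SimulationConfigError("SDs must be >= 0")
        if self.batch_count is not None and self.batch_count <= 0:
            raise SimulationConfigError("batch_count must be positive")
        for (pat, sex), b in self.pattern_base_beta.items():
            if not 0 < b < 1:
                raise SimulationConfigError(
                    f"base beta for ({pat},{sex}) outside (0,1)"
                )
        bb = self.pattern_base_beta
        if bb[("A", "female")] <= bb[("A", "male")]:
            raise SimulationConfigError("pattern A needs female mean > male")
        if bb[("D", "male")] <= bb[("D", "female")]:
            raise SimulationConfigError("pattern D needs male mean > female")
        for pat in ("B", "C"):
            lo, hi = (0, 0.25) if pat == "B" else (0.75, 1)
            for sex in ("female", "male"):
                if not lo < bb[(pat, sex)] < hi:
                    raise SimulationConfigError(
                        f"pattern {pat} base beta must lie in ({lo},{hi})"
                    )


@dataclass
class GroundTruth:
    """Generating truth for one simulated cohort."""

    probes: pd.DataFrame   # pattern, sex_effect_m, slope_male, slope_female
    samples: pd.DataFrame  # pair_intercept, sentrix_id


# ---------------------------------------------------------------------------
# probe universe (shared across cohorts with equal pattern-count maps)
# ---------------------------------------------------------------------------

def make_probe_universe(n_cpgs_per_pattern: dict) -> pd.DataFrame:
    """Deterministic probe annotation for a pattern-count map.

    Independent of the cohort seed so that cohorts configured with the same
    map share probe ids and annotation, like samples run on the same array.
    """
    rng = np.random.default_rng(20_0404)  # fixed: annotation is the "array"
    rows = []
    i = 0
    for pat in PATTERNS + ["ONE_COHORT"]:
        n = int(n_cpgs_per_pattern.get(pat, 0))
        w = np.asarray(_REGION_WEIGHTS[pat], float)
        regions = rng.choice(GENE_REGIONS, size=n, p=w / w.sum())
        for r in regions:
            rows.append((f"cgSIM{i:06d}", "X", 100_000 + 997 * i, r,
                         False, False, pat))
            i += 1
    df = pd.DataFrame(rows, columns=[
        "probe_id", "chromosome", "position", "gene_region",
        "is_cross_reactive", "is_polymorphic", "true_pattern",
    ]).set_index("probe_id")
    # interleave patterns along the chromosome
    df = df.sample(frac=1.0, random_state=np.random.RandomState(7)).copy()
    df["position"] = np.sort(df["position"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SimulationConfig,
    cohort_label: str = "sim",
    one_cohort_active: bool = True,
) -> tuple[MethylationCohort, GroundTruth]:
    """Simulate one cohort plus its generating ground truth.

    ``one_cohort_active`` controls whether ONE_COHORT sites carry their sex
    effect in this cohort (True) or behave like REST sites (False).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    universe = make_probe_universe(config.n_cpgs_per_pattern)
    n_cpgs = len(universe)
    patterns = universe["true_pattern"].to_numpy()

    # --- samples: like-sex pairs (or singletons for validation cohorts) ----
    per_pair = 2 if config.twin_pairs else 1
    recs = []
    for sex in ("female", "male"):
        for p in range(config.n_pairs_per_sex):
            pair_id = f"{cohort_label}_{sex[0]}pair{p:04d}"
            age = rng.uniform(*config.age_range)
            zyg = ("MZ" if rng.random() < config.mz_fraction else "DZ") \
                if config.twin_pairs else "NA"
            for t in range(per_pair):
                recs.append((f"{pair_id}_{t}", sex, age, pair_id, zyg))
    samples = pd.DataFrame(
        recs, columns=["sample_id", "sex", "age", "twin_pair_id", "zygosity"]
    ).set_index("sample_id")
    n_samples = len(samples)

    # samples fill 12-slot chips in random order, one sample per slot
    n_chips = config.batch_count
    if n_chips is None:
        n_chips = max(1, int(np.ceil(n_samples / len(_SENTRIX_POSITIONS))))
    chip_ids = [f"{cohort_label}_chip{b:03d}" for b in range(n_chips)]
    slots = [(c, p) for c in chip_ids for p in _SENTRIX_POSITIONS]
    order = rng.permutation(len(slots))[:n_samples]
    if n_samples > len(slots):  # explicit small batch_count: reuse slots
        order = rng.integers(0, len(slots), size=n_samples)
    samples["sentrix_id"] = [slots[i][0] for i in order]
    samples["sentrix_position"] = [slots[i][1] for i in order]

    alpha = np.asarray(config.cell_dirichlet_alpha, float)
    cells = rng.dirichlet(alpha, size=n_samples)
    samples[CELL_TYPES] = cells

    # --- per-CpG generating effects ---------------------------------------
    active = {p: True for p in PATTERNS}
    active["ONE_COHORT"] = one_cohort_active
    eff_pat = np.where(
        [active[p] for p in patterns], patterns,
        "REST",  # inactive ONE_COHORT sites behave like REST
    )
    base_m = {  # per effective pattern and sex, on the M scale
        (pat, sex): beta_to_m(config.pattern_base_beta[(pat, sex)])
        for pat in PATTERNS + ["ONE_COHORT"] for sex in ("female", "male")
    }
    slope = config.age_slope
    mid_age = 0.5 * (config.age_range[0] + config.age_range[1])

    base_mat = np.empty((n_cpgs, n_samples))
    slope_mat = np.empty((n_cpgs, n_samples))
    sex_arr = samples["sex"].to_numpy()
    for j, sex in enumerate(sex_arr):
        base_mat[:, j] = [base_m[(p, sex)] for p in eff_pat]
        slope_mat[:, j] = [slope[(p, sex)] for p in eff_pat]

    age_c = samples["age"].to_numpy() - mid_age

    pair_ids = samples["twin_pair_id"].to_numpy()
    uniq_pairs = pd.unique(pair_ids)
    pair_u = dict(zip(
        uniq_pairs, rng.normal(0, config.pair_intercept_sd, len(uniq_pairs))
    ))
    chip_u = dict(zip(chip_ids, rng.normal(0, config.batch_sd, len(chip_ids))))
    # slot position: second grouping factor at half the chip variability
    pos_u = dict(zip(
        _SENTRIX_POSITIONS,
        rng.normal(0, config.batch_sd / 2, len(_SENTRIX_POSITIONS)),
    ))
    sample_re = (
        np.array([pair_u[p] for p in pair_ids])
        + np.array([chip_u[c] for c in samples["sentrix_id"]])
        + np.array([pos_u[p] for p in samples["sentrix_position"]])
    )

    cell_coef = rng.normal(0, config.cell_effect_sd, size=(n_cpgs, 6))
    cell_term = cell_coef @ (cells - alpha / alpha.sum()).T

    noise = rng.normal(0, config.residual_sd, size=(n_cpgs, n_samples))
    M = base_mat + slope_mat * age_c[None, :] + sample_re[None, :] \
        + cell_term + noise
    beta = m_to_beta(M)

    # --- detection p: a `detection_fail_rate` share of calls fail (>0.01) --
    detp = rng.uniform(0.0, 0.01, size=(n_cpgs, n_samples))
    fail = rng.random(size=(n_cpgs, n_samples)) < config.detection_fail_rate
    detp[fail] = rng.uniform(0.011, 1.0, size=int(fail.sum()))

    probe_ids = universe.index
    cohort = MethylationCohort(
        beta=pd.DataFrame(beta, index=probe_ids, columns=samples.index),
        samples=samples,
        probes=universe.drop(columns="true_pattern"),
        detection_p=pd.DataFrame(detp, index=probe_ids,
                                 columns=samples.index),
        cohort_label=cohort_label,
    )
    truth_probes = pd.DataFrame({
        "pattern": patterns,
        "sex_effect_m": [
            base_m[(p, "female")] - base_m[(p, "male")] for p in eff_pat
        ],
        "slope_female": [slope[(p, "female")] for p in eff_pat],
        "slope_male": [slope[(p, "male")] for p in eff_pat],
    }, index=probe_ids)
    truth_samples = pd.DataFrame({
        "pair_intercept": [pair_u[p] for p in pair_ids],
        "sentrix_id": samples["sentrix_id"].to_numpy(),
    }, index=samples.index)
    return cohort, GroundTruth(probes=truth_probes, samples=truth_samples)


# ---------------------------------------------------------------------------
# study bundles
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Two discovery twin cohorts plus one unrelated validation cohort."""

    cohort1: MethylationCohort
    cohort2: MethylationCohort
    validation: MethylationCohort
    truth1: GroundTruth
    truth2: GroundTruth
    truth_validation: GroundTruth


def generate_study(
    config_c1: SimulationConfig,
    config_c2: SimulationConfig,
    config_validation: SimulationConfig,
    labels: tuple[str, str, str] = ("cohort1", "cohort2", "validation"),
) -> StudyBundle:
    """Simulate the full three-cohort study over a shared probe universe."""
    maps = [config_c1.n_cpgs_per_pattern, config_c2.n_cpgs_per_pattern,
            config_validation.n_cpgs_per_pattern]
    if not (maps[0] == maps[1] == maps[2]):
        raise SimulationConfigError(
            "the three configs must share one CpG universe "
            "(identical n_cpgs_per_pattern maps)"
        )
    c1, t1 = generate_cohort(config_c1, labels[0], one_cohort_active=True)
    c2, t2 = generate_cohort(config_c2, labels[1], one_cohort_active=False)
    cv, tv = generate_cohort(config_validation, labels[2],
                             one_cohort_active=False)
    return StudyBundle(c1, c2, cv, t1, t2, tv)


def default_study_configs(seed: int = 0, scale: float = 1.0) -> tuple[
        SimulationConfig, SimulationConfig, SimulationConfig]:
    """Default three-cohort design: an older and a younger like-sex twin
    cohort (discovery/replication) and an unrelated elderly validation
    cohort, with sample sizes optionally scaled down by ``scale``.
    """
    ss = np.random.SeedSequence(seed).generate_state(3, dtype=np.uint32)
    counts = _default_cpg_counts()
    counts["ONE_COHORT"] = 20
    older = SimulationConfig(
        n_pairs_per_sex=max(4, round(36 * scale)), age_range=(74.0, 88.0),
        n_cpgs_per_pattern=counts, seed=int(ss[0]),
    )
    younger = SimulationConfig(
        n_pairs_per_sex=max(4, round(113 * scale)), age_range=(56.0, 79.0),
        n_cpgs_per_pattern=counts, seed=int(ss[1]),
    )
    validation = SimulationConfig(
        n_pairs_per_sex=max(4, round(190 * scale)), age_range=(78.0, 91.0),
        n_cpgs_per_pattern=counts, seed=int(ss[2]), twin_pairs=False,
    )
    return older, younger, validation


# ---------------------------------------------------------------------------
# config / output files
# ---------------------------------------------------------------------------

def config_to_yaml(config: SimulationConfig, path) -> None:
    d = asdict(config)
    d["age_range"] = list(d["age_range"])
    d["cell_dirichlet_alpha"] = list(d["cell_dirichlet_alpha"])
    d["pattern_base_beta"] = {
        f"{pat}/{sex}": v for (pat, sex), v in d["pattern_base_beta"].items()
    }
    d["age_slope"] = {
        f"{pat}/{sex}": v for (pat, sex), v in d["age_slope"].items()
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["age_range"] = tuple(d["age_range"])
    d["cell_dirichlet_alpha"] = tuple(d["cell_dirichlet_alpha"])
    for key in ("pattern_base_beta", "age_slope"):
        d[key] = {tuple(k.split("/")): v for k, v in d[key].items()}
    return SimulationConfig(**d)


def write_simulated_cohort(cohort: MethylationCohort, truth: GroundTruth,
                           outdir) -> None:
    """Write a cohort plus its ground truth as delimited text."""
    outdir = Path(outdir)
    write_cohort(cohort, outdir)
    truth.probes.rename_axis("probe_id").to_csv(
        outdir / "truth_probes.tsv", sep="\t"
    )
    truth.samples.rename_axis("sample_id").to_csv(
        outdir / "truth_samples.tsv", sep="\t"
    )
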