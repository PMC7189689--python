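"""Cohort data model, file I/O, quality control, and transforms.

A :class:`MethylationCohort` holds a CpG-by-sample matrix of methylation
β values (fraction methylated, in [0,1]) together with the matching
detection-p matrix, a sample sheet, and a probe annotation table.  All
downstream statistics operate on this container.

The quality-control path follows standard 450K array practice: probes on a
caller-supplied blacklist (cross-reactive / polymorphic) are removed first,
individual calls with detection p above a threshold are masked to missing,
and probes with more than a given fraction of missing calls are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("xcimeth")

CELL_TYPES = ["CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran"]

GENE_REGIONS = [
    "1stExon", "3'UTR", "5'UTR", "Body", "Intergenic", "TSS1500", "TSS200",
]

SAMPLE_COLUMNS = [
    "sample_id", "sex", "age", "twin_pair_id", "zygosity",
    "sentrix_id", "sentrix_position", *CELL_TYPES,
]

PROBE_COLUMNS = [
    "probe_id", "chromosome", "position", "gene_region",
    "is_cross_reactive", "is_polymorphic",
]

#: clipping bounds applied to β before the logit transform
BETA_EPS = 1e-6


class CohortError(ValueError):
    """Malformed cohort input (id mismatches, duplicate probes, ...)."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class MethylationCohort:
    """One cohort: β matrix, detection p, sample sheet, probe annotation."""

    beta: pd.DataFrame                       # probes x samples, in [0,1]/NaN
    samples: pd.DataFrame                    # indexed by sample_id
    probes: pd.DataFrame                     # indexed by probe_id
    detection_p: pd.DataFrame | None = None  # same shape as beta
    cohort_label: str = "cohort"

    def __post_init__(self) -> None:
        self.validate()

    # -- consistency -------------------------------------------------------
    def validate(self) -> None:
        if self.beta.index.duplicated().any():
            dups = self.beta.index[self.beta.index.duplicated()].unique()
            raise CohortError(f"duplicate probe ids: {list(dups[:5])}")
        if self.beta.columns.duplicated().any():
            dups = self.beta.columns[self.beta.columns.duplicated()].unique()
            raise CohortError(f"duplicate sample ids: {list(dups[:5])}")
        missing = set(self.beta.columns) ^ set(self.samples.index)
        if missing:
            raise CohortError(
                "sample ids mismatched between beta matrix and sample sheet: "
                f"{sorted(missing)[:10]}"
            )
        extra = set(self.beta.index) - set(self.probes.index)
        if extra:
            raise CohortError(
                f"probes missing from annotation: {sorted(extra)[:10]}"
            )
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise CohortError("detection_p shape differs from beta")
        # align ordering once so numpy views line up everywhere downstream
        self.samples = self.samples.loc[self.beta.columns]
        if self.detection_p is not None:
            self.detection_p = self.detection_p.loc[
                self.beta.index, self.beta.columns
            ]
        has_cells = all(c in self.samples.columns for c in CELL_TYPES)
        cells = (self.samples[CELL_TYPES].to_numpy(float) if has_cells
                 else np.empty((0, 6)))
        if has_cells and np.isfinite(cells).all():
            sums = cells.sum(axis=1)
            if (cells < -1e-9).any() or (np.abs(sums - 1.0) > 1e-6).any():
                raise CohortError("cell proportions must be >=0 and sum to 1")
        with np.errstate(invalid="ignore"):
            b = self.beta.to_numpy(float)
            if np.nanmin(b, initial=0.0) < 0 or np.nanmax(b, initial=1.0) > 1:
                raise CohortError("beta values outside [0,1]")

    # -- convenience -------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, probe_ids) -> "MethylationCohort":
        probe_ids = pd.Index(probe_ids)
        return MethylationCohort(
            beta=self.beta.loc[probe_ids],
            samples=self.samples.copy(),
            probes=self.probes.loc[probe_ids],
            detection_p=(
                None if self.detection_p is None
                else self.detection_p.loc[probe_ids]
            ),
            cohort_label=self.cohort_label,
        )

    def subset_samples(self, sample_ids) -> "MethylationCohort":
        sample_ids = pd.Index(sample_ids)
        return MethylationCohort(
            beta=self.beta[sample_ids],
            samples=self.samples.loc[sample_ids],
            probes=self.probes.copy(),
            detection_p=(
                None if self.detection_p is None
                else self.detection_p[sample_ids]
            ),
            cohort_label=self.cohort_label,
        )

    def select_chromosome(self, chromosome: str) -> "MethylationCohort":
        """Restrict to probes on one chromosome (e.g. ``"X"`` or ``"20"``)."""
        keep = self.probes.index[
            self.probes["chromosome"].astype(str) == str(chromosome)
        ]
        if len(keep) == 0:
            raise CohortError(f"no probes on chromosome {chromosome!r}")
        return self.subset_probes(keep)

    def m_values(self) -> pd.DataFrame:
        """Logit-transformed β matrix (M = log2(β/(1−β)))."""
        return pd.DataFrame(
            beta_to_m(self.beta.to_numpy(float)),
            index=self.beta.index, columns=self.beta.columns,
        )


@dataclass
class QCReport:
    n_probes_in: int
    n_masked_calls: int
    n_dropped_missingness: int
    n_dropped_blacklist: int
    n_probes_out: int

    def __post_init__(self) -> None:
        expected = (
            self.n_probes_in
            - self.n_dropped_missingness
            - self.n_dropped_blacklist
        )
        if self.n_probes_out != expected:
            raise ValueError("QCReport counts are inconsistent")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def beta_to_m(beta):
    """M = log2(β / (1 − β)), with β clipped to [1e-6, 1−1e-6] first.

    Accepts scalars or arrays; NaN passes through.  Values outside [0,1]
    raise ``ValueError``.
    """
    arr = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (arr < 0) | (arr > 1)
    if bad.any():
        raise ValueError("beta values outside [0,1]")
    clipped = np.clip(arr, BETA_EPS, 1.0 - BETA_EPS)
    out = np.log2(clipped / (1.0 - clipped))
    return out.item() if np.isscalar(beta) else out


def m_to_beta(m):
    """Inverse logit: β = 2^M / (1 + 2^M).  NaN passes through."""
    arr = np.asarray(m, dtype=float)
    # expit in base 2, numerically stable on both tails
    out = np.where(arr >= 0,
                   1.0 / (1.0 + np.exp2(-arr)),
                   np.exp2(arr) / (1.0 + np.exp2(arr)))
    out = np.where(np.isnan(arr), np.nan, out)
    return out.item() if np.isscalar(m) else out


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def apply_qc(
    cohort: MethylationCohort,
    detection_threshold: float = 0.01,
    max_missing_fraction: float = 0.05,
) -> tuple[MethylationCohort, QCReport]:
    """Blacklist removal, detection-p masking, and missingness filtering.

    Order: probes flagged cross-reactive or polymorphic are dropped first;
    then calls with detection p > ``detection_threshold`` are set missing;
    finally probes with a missing fraction strictly greater than
    ``max_missing_fraction`` are removed.
    """
    n_in = cohort.n_probes
    flags = cohort.probes.loc[cohort.beta.index]
    black = (
        flags["is_cross_reactive"].astype(bool)
        | flags["is_polymorphic"].astype(bool)
    )
    n_black = int(black.sum())
    kept = cohort.subset_probes(cohort.beta.index[~black.to_numpy()])
    if kept.n_probes == 0:
        raise CohortError("QC removed every probe (blacklist)")

    beta = kept.beta.to_numpy(float).copy()
    n_masked = 0
    if kept.detection_p is not None:
        detp = kept.detection_p.to_numpy(float)
        mask = np.isfinite(detp) & (detp > detection_threshold)
        mask &= np.isfinite(beta)        # don't double-count existing NaN
        n_masked = int(mask.sum())
        beta[mask] = np.nan

    missing_frac = np.isnan(beta).mean(axis=1)
    drop = missing_frac > max_missing_fraction
    n_missing_drop = int(drop.sum())
    keep_idx = kept.beta.index[~drop]
    if len(keep_idx) == 0:
        raise CohortError("QC removed every probe (missingness)")

    out = MethylationCohort(
        beta=pd.DataFrame(
            beta[~drop], index=keep_idx, columns=kept.beta.columns
        ),
        samples=kept.samples.copy(),
        probes=kept.probes.loc[keep_idx],
        detection_p=(
            None if kept.detection_p is None
            else kept.detection_p.loc[keep_idx]
        ),
        cohort_label=kept.cohort_label,
    )
    report = QCReport(
        n_probes_in=n_in,
        n_masked_calls=n_masked,
        n_dropped_missingness=n_missing_drop,
        n_dropped_blacklist=n_black,
        n_probes_out=out.n_probes,
    )
    logger.info(
        "QC %s: %d probes in, %d blacklisted, %d calls masked, "
        "%d dropped for missingness, %d out",
        cohort.cohort_label, n_in, n_black, n_masked,
        n_missing_drop, out.n_probes,
    )
    return out, report


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _quantile_normalize_block(block: np.ndarray) -> np.ndarray:
    """Full quantile normalization of a probes x samples block (NaN-aware).

    The reference distribution is the mean across samples of each sample's
    sorted values, interpolated onto a common quantile grid, so samples with
    different missingness patterns remain comparable.
    """
    n_probes, n_samples = block.shape
    grid = (np.arange(n_probes) + 0.5) / n_probes
    ref = np.zeros(n_probes)
    n_used = 0
    for j in range(n_samples):
        col = block[:, j]
        vals = np.sort(col[np.isfinite(col)])
        if vals.size == 0:
            continue
        q = (np.arange(vals.size) + 0.5) / vals.size
        ref += np.interp(grid, q, vals)
        n_used += 1
    if n_used == 0:
        return block
    ref /= n_used

    out = np.full_like(block, np.nan)
    for j in range(n_samples):
        col = block[:, j]
        fin = np.isfinite(col)
        k = int(fin.sum())
        if k == 0:
            continue
        ranks = rankdata(col[fin], method="average")  # ties -> mean rank
        out[fin, j] = np.interp((ranks - 0.5) / k, grid, ref)
    return out


def normalize_within_sex(cohort: MethylationCohort) -> MethylationCohort:
    """Quantile-normalize the β matrix separately within each sex.

    Stand-in for within-sex array normalization: male and female columns are
    each forced to a common (per-sex) empirical distribution, preserving
    within-sample ranks.  Requires at least two samples of each sex.
    """
    sex = cohort.samples["sex"]
    for s in ("male", "female"):
        if (sex == s).sum() < 2:
            raise CohortError(
                f"fewer than 2 {s} samples: skip normalization for this "
                "cohort (pass it through unnormalized instead)"
            )
    beta = cohort.beta.to_numpy(float).copy()
    for s in ("male", "female"):
        cols = np.flatnonzero((sex == s).to_numpy())
        beta[:, cols] = _quantile_normalize_block(beta[:, cols])
    return MethylationCohort(
        beta=pd.DataFrame(
            beta, index=cohort.beta.index, columns=cohort.beta.columns
        ),
        samples=cohort.samples.copy(),
        probes=cohort.probes.copy(),
        detection_p=(
            None if cohort.detection_p is None else cohort.detection_p.copy()
        ),
        cohort_label=cohort.cohort_label,
    )


# ---------------------------------------------------------------------------
# sex balancing
# ---------------------------------------------------------------------------

def balance_sexes(samples: pd.DataFrame) -> list[str]:
    """Equalize male/female sample counts at twin-pair granularity.

    The smaller sex is retained in full.  From the larger sex, whole twin
    pairs are taken in order of the distance between the pair's mean age and
    the smaller sex's mean age (ties broken by lexicographically smaller
    pair id) until the smaller sex's sample count is reached.  A pair that
    would overshoot the remaining quota is skipped, so a trailing singleton
    can fill an odd slot.  Pairs are never split.
    """
    sex = samples["sex"]
    n_by_sex = sex.value_counts()
    if set(n_by_sex.index) != {"male", "female"}:
        raise CohortError("both sexes must be present to balance")
    small_sex = n_by_sex.idxmin()
    large_sex = "male" if small_sex == "female" else "female"
    quota = int(n_by_sex[small_sex])
    if n_by_sex[large_sex] == quota:
        return list(samples.index)

    target_age = float(samples.loc[sex == small_sex, "age"].mean())
    large = samples[sex == large_sex]
    pairs = (
        large.groupby("twin_pair_id")
        .agg(mean_age=("age", "mean"), size=("age", "size"))
        .reset_index()
    )
    pairs["dist"] = (pairs["mean_age"] - target_age).abs()
    pairs = pairs.sort_values(["dist", "twin_pair_id"], kind="mergesort")

    chosen: list[str] = []
    remaining = quota
    for row in pairs.itertuples():
        if row.size <= remaining:
            chosen.append(row.twin_pair_id)
            remaining -= row.size
        if remaining == 0:
            break
    if remaining:
        logger.warning(
            "balance_sexes: %d slot(s) unfilled (only whole pairs available)",
            remaining,
        )
    keep = samples.index[
        (sex == small_sex)
        | ((sex == large_sex) & samples["twin_pair_id"].isin(chosen))
    ]
    return list(keep)


# ---------------------------------------------------------------------------
# file I/O  (TSV dialect: first column = probe id, header = sample ids)
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    n_bad = 0
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        n_bad += int((coerced.isna() & df[col].notna()
                      & (df[col].astype(str).str.upper() != "NA")).sum())
        df[col] = coerced
    if n_bad:
        logger.warning("%s: %d unparseable numeric cells set missing",
                       path, n_bad)
    return df


def read_cohort(
    beta_path,
    sample_sheet_path,
    annotation_path,
    detection_path=None,
    cohort_label: str | None = None,
) -> MethylationCohort:
    """Load a cohort from the package's TSV dialect."""
    beta = read_matrix(beta_path)
    samples = pd.read_csv(sample_sheet_path, sep="\t", dtype={
        "sample_id": str, "twin_pair_id": str,
        "sentrix_id": str, "sentrix_position": str,
    }).set_index("sample_id")
    probes = pd.read_csv(
        annotation_path, sep="\t", dtype={"probe_id": str, "chromosome": str}
    ).set_index("probe_id")
    for flag in ("is_cross_reactive", "is_polymorphic"):
        probes[flag] = probes[flag].astype(bool)
    detp = None if detection_path is None else read_matrix(detection_path)
    return MethylationCohort(
        beta=beta, samples=samples, probes=probes, detection_p=detp,
        cohort_label=cohort_label or Path(str(beta_path)).stem,
    )


def write_cohort(cohort: MethylationCohort, outdir) -> dict[str, Path]:
    """Write a cohort to ``outdir`` in the same dialect ``read_cohort`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "samples": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
    }
    cohort.beta.rename_axis("probe_id").to_csv(paths["beta"], sep="\t")
    cohort.samples.rename_axis("sample_id").to_csv(paths["samples"], sep="\t")
    cohort.probes.rename_axis("probe_id").to_csv(paths["annotation"], sep="\t")
    if cohort.detection_p is not None:
        paths["detection_p"] = outdir / "detection_p.tsv"
        cohort.detection_p.rename_axis("probe_id").to_csv(
            paths["detection_p"], sep="\t"
        )
    return paths


def load_cohort_dir(path, cohort_label: str | None = None) -> MethylationCohort:
    """Load a cohort directory previously written by :func:`write_cohort`."""
    path = Path(path)
    detp = path / "detection_p.tsv"
    return read_cohort(
        path / "beta.tsv",
        path / "samples.tsv",
        path / "annotation.tsv",
        detection_path=detp if detp.exists() else None,
        cohort_label=cohort_label or path.name,
    )
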