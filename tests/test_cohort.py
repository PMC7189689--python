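"""Data model, I/O, QC, transforms, and sex balancing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, spearmanr

import xcimeth as x
from xcimeth.cohort import CohortError

from conftest import make_cohort


# ---------------------------------------------------------------------------
# beta <-> M transform
# ---------------------------------------------------------------------------

class TestBetaMTransform:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert x.beta_to_m(beta) == pytest.approx(m)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            x.beta_to_m(1.2)
        with pytest.raises(ValueError):
            x.beta_to_m(np.array([0.3, -0.1]))

    def test_nan_passes_through(self):
        out = x.beta_to_m(np.array([0.5, np.nan]))
        assert np.isnan(out[1]) and out[0] == 0.0

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    @settings(deadline=None, max_examples=200)
    def test_round_trip_and_antisymmetry(self, beta):
        m = x.beta_to_m(beta)
        assert np.isfinite(m)
        assert x.m_to_beta(m) == pytest.approx(beta, abs=1e-10)
        assert x.beta_to_m(1 - beta) == pytest.approx(-m, abs=1e-9)

    def test_strictly_increasing(self):
        grid = np.linspace(1e-4, 1 - 1e-4, 500)
        assert np.all(np.diff(x.beta_to_m(grid)) > 0)

    def test_boundary_clipping_keeps_m_finite(self):
        assert np.isfinite(x.beta_to_m(0.0))
        assert np.isfinite(x.beta_to_m(1.0))


# ---------------------------------------------------------------------------
# I/O round trip
# ---------------------------------------------------------------------------

class TestCohortIO:
    def test_round_trip(self, tmp_path, rng):
        beta = rng.uniform(0.05, 0.95, size=(4, 3))
        coh = make_cohort(beta, ["male", "female", "female"],
                          detection_p=rng.uniform(0, 0.009, (4, 3)))
        x.write_cohort(coh, tmp_path)
        back = x.load_cohort_dir(tmp_path)
        pd.testing.assert_frame_equal(back.beta, coh.beta)
        pd.testing.assert_frame_equal(back.detection_p, coh.detection_p)
        assert list(back.samples["sex"]) == list(coh.samples["sex"])
        assert list(back.probes["gene_region"]) == ["Body"] * 4

    def test_mismatched_sample_id_is_named(self, tmp_path, rng):
        coh = make_cohort(rng.uniform(0.1, 0.9, (3, 3)),
                          ["male", "male", "female"])
        x.write_cohort(coh, tmp_path)
        sheet = pd.read_csv(tmp_path / "samples.tsv", sep="\t")
        sheet = sheet[sheet["sample_id"] != "s001"]
        sheet.to_csv(tmp_path / "samples.tsv", sep="\t", index=False)
        with pytest.raises(CohortError, match="s001"):
            x.load_cohort_dir(tmp_path)

    def test_duplicate_probe_ids_rejected(self, rng):
        beta = pd.DataFrame(rng.uniform(0.1, 0.9, (2, 2)),
                            index=["cg1", "cg1"], columns=["a", "b"])
        coh = make_cohort(rng.uniform(0.1, 0.9, (2, 2)), ["male", "female"])
        with pytest.raises(CohortError, match="duplicate"):
            x.MethylationCohort(beta=beta, samples=coh.samples.set_axis(
                ["a", "b"]), probes=coh.probes.set_axis(["cg1", "cg2"]))

    def test_na_cells_become_missing(self, tmp_path, rng):
        coh = make_cohort(rng.uniform(0.1, 0.9, (3, 3)),
                          ["male", "male", "female"])
        x.write_cohort(coh, tmp_path)
        text = (tmp_path / "beta.tsv").read_text().splitlines()
        cells = text[1].split("\t")
        cells[1] = "NA"
        text[1] = "\t".join(cells)
        (tmp_path / "beta.tsv").write_text("\n".join(text) + "\n")
        back = x.load_cohort_dir(tmp_path)
        assert back.beta.isna().sum().sum() == 1


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

class TestApplyQC:
    def _cohort_with_failures(self, fails_per_probe, n_samples=20):
        n_probes = len(fails_per_probe)
        rng = np.random.default_rng(1)
        beta = rng.uniform(0.2, 0.8, (n_probes, n_samples))
        detp = np.full((n_probes, n_samples), 0.001)
        for i, k in enumerate(fails_per_probe):
            detp[i, :k] = 0.5
        return make_cohort(
            beta, ["male", "female"] * (n_samples // 2), detection_p=detp
        )

    def test_five_percent_rule_is_strict(self):
        # 1/20 = 5% missing retained ("more than 5%" drops), 2/20 dropped
        coh = self._cohort_with_failures([0, 1, 2])
        out, report = x.apply_qc(coh)
        assert list(out.beta.index) == ["cg00000", "cg00001"]
        assert report.n_dropped_missingness == 1
        assert report.n_masked_calls == 3
        assert out.beta.loc["cg00001"].isna().sum() == 1

    def test_blacklist_dropped_first(self, rng):
        beta = rng.uniform(0.2, 0.8, (3, 4))
        coh = make_cohort(
            beta, ["male", "male", "female", "female"],
            detection_p=np.full((3, 4), 1e-4),
            probe_flags=(np.array([True, False, False]),
                         np.array([False, True, False])),
        )
        out, report = x.apply_qc(coh)
        assert report.n_dropped_blacklist == 2
        assert list(out.beta.index) == ["cg00002"]

    def test_qc_is_idempotent(self):
        coh = self._cohort_with_failures([0, 1, 2, 3, 0])
        once, _ = x.apply_qc(coh)
        twice, rep2 = x.apply_qc(once)
        pd.testing.assert_frame_equal(once.beta, twice.beta)
        assert rep2.n_dropped_missingness == 0

    def test_all_probes_dropped_is_an_error(self):
        coh = self._cohort_with_failures([20, 20])
        with pytest.raises(CohortError):
            x.apply_qc(coh)

    def test_missingness_drop_rate_matches_binomial_tail(self):
        # MCAR failures at rate r: P(drop) = P(Bin(S, r) > floor(0.05 S))
        n_probes, n_samples, rate = 2000, 100, 0.03
        dropped = []
        for seed in range(12):
            cfg = x.SimulationConfig(
                n_pairs_per_sex=n_samples // 4,
                n_cpgs_per_pattern={"REST": n_probes},
                detection_fail_rate=rate, seed=seed,
            )
            coh, _ = x.generate_cohort(cfg)
            _, report = x.apply_qc(coh)
            dropped.append(report.n_dropped_missingness)
        expected = n_probes * binom(n_samples, rate).sf(5)
        se = np.sqrt(n_probes * binom(n_samples, rate).sf(5) / 12)
        assert np.mean(dropped) == pytest.approx(expected, abs=4 * se + 1)


# ---------------------------------------------------------------------------
# within-sex quantile normalization
# ---------------------------------------------------------------------------

class TestNormalizeWithinSex:
    def test_identical_samples_unchanged(self, rng):
        col = rng.uniform(0.1, 0.9, 50)
        beta = np.column_stack([col, col,
                                rng.uniform(0.1, 0.9, 50),
                                rng.uniform(0.1, 0.9, 50)])
        coh = make_cohort(beta, ["male", "male", "female", "female"])
        out = x.normalize_within_sex(coh)
        np.testing.assert_allclose(out.beta.iloc[:, :2], beta[:, :2])

    def test_sorted_columns_identical_within_sex(self, rng):
        beta = rng.uniform(0, 1, (100, 6))
        coh = make_cohort(beta, ["male"] * 3 + ["female"] * 3)
        out = x.normalize_within_sex(coh).beta.to_numpy()
        male_sorted = np.sort(out[:, :3], axis=0)
        assert np.allclose(male_sorted[:, 0], male_sorted[:, 1])
        assert np.allclose(male_sorted[:, 0], male_sorted[:, 2])
        assert out.min() >= 0 and out.max() <= 1

    def test_ranks_preserved(self, rng):
        beta = rng.uniform(0, 1, (80, 4))
        coh = make_cohort(beta, ["male", "male", "female", "female"])
        out = x.normalize_within_sex(coh).beta.to_numpy()
        for j in range(4):
            rho = spearmanr(beta[:, j], out[:, j]).statistic
            assert rho == pytest.approx(1.0)

    def test_single_sex_is_an_error(self, rng):
        coh = make_cohort(rng.uniform(0.1, 0.9, (10, 3)), ["male"] * 3)
        with pytest.raises(CohortError, match="skip normalization"):
            x.normalize_within_sex(coh)


# ---------------------------------------------------------------------------
# sex balancing
# ---------------------------------------------------------------------------

class TestBalanceSexes:
    def _sheet(self, male_ages, female_ages, male_pairs=None):
        male_pairs = male_pairs or [f"mp{i}" for i in range(len(male_ages))]
        recs = []
        for i, (a, p) in enumerate(zip(male_ages, male_pairs)):
            recs.append((f"m{i}", "male", a, p))
        for i, a in enumerate(female_ages):
            recs.append((f"f{i}", "female", a, f"fp{i}"))
        return pd.DataFrame(
            recs, columns=["sample_id", "sex", "age", "twin_pair_id"]
        ).set_index("sample_id")

    def test_closest_to_target_mean_kept(self):
        sheet = self._sheet([60, 70, 80], [65, 66])
        kept = x.balance_sexes(sheet)
        ages = sorted(sheet.loc[[k for k in kept
                                 if sheet.loc[k, "sex"] == "male"], "age"])
        assert ages == [60, 70]

    def test_balanced_input_is_identity(self):
        sheet = self._sheet([60, 70], [65, 66])
        assert set(x.balance_sexes(sheet)) == set(sheet.index)

    def test_pair_level_reduction_to_smaller_sex_count(self):
        # 133 male pairs (266) vs 113 female pairs (226) -> 226 of each
        rng = np.random.default_rng(0)
        recs = []
        for p in range(133):
            age = rng.uniform(50, 80)
            recs += [(f"m{p}a", "male", age, f"mp{p:03d}"),
                     (f"m{p}b", "male", age, f"mp{p:03d}")]
        for p in range(113):
            age = rng.uniform(50, 80)
            recs += [(f"f{p}a", "female", age, f"fp{p:03d}"),
                     (f"f{p}b", "female", age, f"fp{p:03d}")]
        sheet = pd.DataFrame(
            recs, columns=["sample_id", "sex", "age", "twin_pair_id"]
        ).set_index("sample_id")
        kept = sheet.loc[x.balance_sexes(sheet)]
        assert (kept["sex"] == "male").sum() == 226
        assert (kept["sex"] == "female").sum() == 226
        # no pair is split
        sizes_in = sheet.groupby("twin_pair_id").size()
        sizes_out = kept.groupby("twin_pair_id").size()
        assert (sizes_in.loc[sizes_out.index] == sizes_out).all()

    @given(st.integers(2, 15), st.integers(2, 15), st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_smaller_sex_never_reduced(self, n_m, n_f, seed):
        rng = np.random.default_rng(seed)
        sheet = self._sheet(rng.uniform(50, 90, n_m).tolist(),
                            rng.uniform(50, 90, n_f).tolist())
        kept = sheet.loc[x.balance_sexes(sheet)]
        small = "male" if n_m <= n_f else "female"
        assert (kept["sex"] == small).sum() == min(n_m, n_f)
        assert (kept["sex"] != small).sum() <= min(n_m, n_f)
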