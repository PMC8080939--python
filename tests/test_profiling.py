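import numpy as np
import pandas as pd
import pytest

from methylprofiler.errors import ProfilingError, ValidationError
from methylprofiler.io import PhenotypeTable, ScoreTable
from methylprofiler.preprocessing import ReferencePanel
from methylprofiler.profiling import (
    CohortFilter,
    case_control_summary,
    individual_profile,
    percentile_ranks,
    reference_trait_correlations,
    score_correlations,
    subset_cohort,
)


def table_from_scores(scores, age=None, sex=None, age_trait=None, traits=None):
    scores = {k: np.asarray(v, dtype=float) for k, v in scores.items()}
    n = len(next(iter(scores.values())))
    ids = pd.Index([f"S{i}" for i in range(1, n + 1)], name="ID")
    cols = {}
    if sex is not None:
        cols["Sex"] = sex
    if age is not None:
        cols["Age"] = np.asarray(age, dtype=float)
    cols.update(scores)
    return ScoreTable(pd.DataFrame(cols, index=ids), traits or list(scores), age_trait)


def oracle_midrank(values):
    """Brute-force mid-rank percentile: p = 100 * (rank - 0.5) / n."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    out = np.empty(n)
    for i, v in enumerate(values):
        below = np.sum(values < v)
        equal = np.sum(values == v)
        rank = below + (equal + 1) / 2.0
        out[i] = 100.0 * (rank - 0.5) / n
    return out


class TestPercentileRanks:
    def test_four_distinct_scores(self):
        t = table_from_scores({"BMI": [1.0, 2.0, 3.0, 4.0]})
        p = percentile_ranks(t)["BMI"].to_numpy()
        np.testing.assert_allclose(p, [12.5, 37.5, 62.5, 87.5])
        np.testing.assert_allclose(p, oracle_midrank([1.0, 2.0, 3.0, 4.0]))

    def test_all_equal_scores_give_fifty(self):
        t = table_from_scores({"BMI": [3.3] * 5})
        np.testing.assert_allclose(percentile_ranks(t)["BMI"].to_numpy(), [50] * 5)

    def test_age_trait_passes_through_in_years(self):
        t = table_from_scores(
            {"Epigenetic Age": [30.2, 41.7], "BMI": [1.0, 2.0]},
            age_trait="Epigenetic Age",
        )
        p = percentile_ranks(t)
        np.testing.assert_allclose(p["Epigenetic Age"].to_numpy(), [30.2, 41.7])
        np.testing.assert_allclose(p["BMI"].to_numpy(), [25.0, 75.0])

    def test_true_age_column_retained(self):
        t = table_from_scores({"BMI": [1.0, 2.0]}, age=[40.0, 60.0])
        assert "Age" in percentile_ranks(t).columns

    def test_single_sample_is_fifty(self):
        t = table_from_scores({"BMI": [9.9]})
        assert percentile_ranks(t)["BMI"].iloc[0] == 50.0

    def test_mean_is_exactly_fifty_when_tie_free(self):
        rng = np.random.default_rng(1)
        t = table_from_scores({"BMI": rng.normal(size=101)})
        assert percentile_ranks(t)["BMI"].mean() == pytest.approx(50.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        a = percentile_ranks(table_from_scores({"T": x}))["T"].to_numpy()
        b = percentile_ranks(table_from_scores({"T": np.exp(2 * x) + 3}))["T"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_bounded_away_from_extremes(self):
        rng = np.random.default_rng(3)
        p = percentile_ranks(table_from_scores({"T": rng.normal(size=50)}))["T"]
        assert (p > 0).all() and (p < 100).all()

    def test_empty_table_rejected(self):
        t = table_from_scores({"BMI": [1.0]})
        empty = t.subset([])
        with pytest.raises(ProfilingError):
            percentile_ranks(empty)


class TestSubsetCohort:
    def test_age_range_on_effective_age(self):
        t = table_from_scores(
            {"Epigenetic Age": [65.0, 30.0, 55.0], "BMI": [1, 2, 3]},
            age=[45.0, np.nan, np.nan],
            age_trait="Epigenetic Age",
        )
        # oracle: S1 true age 45 (epi 65) in range; S2 epi 30 out; S3 epi 55 in
        sub = subset_cohort(t, CohortFilter(age_range=(40, 60)))
        assert sub.sample_ids == ["S1", "S3"]

    def test_sex_filter_excludes_na(self):
        t = table_from_scores(
            {"BMI": [1, 2, 3]}, sex=["Female", "NA", "Male"]
        )
        sub = subset_cohort(t, CohortFilter(sex="Female"))
        assert sub.sample_ids == ["S1"]

    def test_status_filter(self):
        t = table_from_scores({"BMI": [1, 2, 3, 4]})
        phen = PhenotypeTable(
            pd.DataFrame(
                {"diabetes": [1.0, 0.0, np.nan, 1.0]},
                index=pd.Index(["S1", "S2", "S3", "S4"], name="ID"),
            )
        )
        cases = subset_cohort(t, CohortFilter(status_filter=("diabetes", "cases")), phen)
        assert cases.sample_ids == ["S1", "S4"]
        controls = subset_cohort(t, CohortFilter(status_filter=("diabetes", "controls")), phen)
        assert controls.sample_ids == ["S2"]

    def test_empty_result_is_valid(self):
        t = table_from_scores({"BMI": [1.0]}, age=[30.0])
        sub = subset_cohort(t, CohortFilter(age_range=(90, 99)))
        assert len(sub.data) == 0

    def test_unknown_phenotype_errors(self):
        t = table_from_scores({"BMI": [1.0]})
        phen = PhenotypeTable(
            pd.DataFrame({"x": [1.0]}, index=pd.Index(["S1"], name="ID"))
        )
        with pytest.raises(ProfilingError, match="unknown phenotype"):
            subset_cohort(t, CohortFilter(status_filter=("y", "cases")), phen)

    def test_invalid_age_range(self):
        with pytest.raises(ValidationError):
            CohortFilter(age_range=(60, 40))

    def test_ranks_recomputed_on_subset(self):
        t = table_from_scores({"BMI": [1.0, 2.0, 3.0, 4.0]}, age=[30, 40, 50, 60])
        full = percentile_ranks(t)
        sub = subset_cohort(t, CohortFilter(age_range=(45, 65)))
        filtered = percentile_ranks(sub)
        # S4 is top of the full table but also ranked only against the subset
        assert filtered.loc["S4", "BMI"] == 75.0
        assert full.loc["S4", "BMI"] == 87.5


class TestIndividualProfile:
    def test_top_of_ten_is_95(self):
        t = table_from_scores({"BMI": np.arange(10, dtype=float)})
        assert individual_profile(t, "S10")["BMI"] == pytest.approx(95.0)

    def test_self_only_comparison_is_50(self):
        t = table_from_scores({"BMI": [1.0, 2.0]})
        sub = t.subset(["S1"])
        assert individual_profile(sub, "S1")["BMI"] == 50.0

    def test_unknown_trait_lists_available(self):
        t = table_from_scores({"BMI": [1.0, 2.0]})
        with pytest.raises(ProfilingError, match="BMI"):
            individual_profile(t, "S1", ["Nope"])

    def test_unknown_id(self):
        t = table_from_scores({"BMI": [1.0]})
        with pytest.raises(KeyError):
            individual_profile(t, "missing")


class TestCaseControlSummary:
    def _phen(self, statuses):
        ids = pd.Index([f"S{i}" for i in range(1, len(statuses) + 1)], name="ID")
        return PhenotypeTable(pd.DataFrame({"d": statuses}, index=ids))

    def test_single_case_top_of_ten(self):
        t = table_from_scores({"BMI": np.arange(10, dtype=float)})
        phen = self._phen([0.0] * 9 + [1.0])
        s = case_control_summary(t, phen, "d")
        assert s.loc["BMI", "median"] == s.loc["BMI", "q1"] == s.loc["BMI", "q3"] == 95.0
        assert s.loc["BMI", "n_cases"] == 1 and s.loc["BMI", "n_controls"] == 9

    def test_quartiles_linear_interpolation(self):
        # cases land at percentiles 25, 50, 75 of the combined table
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        # mid-rank percentiles: 8.33, 25, 41.67, 58.33, 75, 91.67
        phen = self._phen([0.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        t = table_from_scores({"BMI": scores})
        s = case_control_summary(t, phen, "d")
        np.testing.assert_allclose(s.loc["BMI", "q1"], 37.5)
        np.testing.assert_allclose(s.loc["BMI", "median"], 50.0)
        np.testing.assert_allclose(s.loc["BMI", "q3"], 62.5)

    def test_missing_status_excluded_from_ranking(self):
        t = table_from_scores({"BMI": [1.0, 2.0, 3.0, 100.0]})
        phen = self._phen([0.0, 1.0, 0.0, np.nan])
        s = case_control_summary(t, phen, "d")
        # S4 dropped: ranks computed over 3 samples, case S2 is the middle one
        assert s.loc["BMI", "median"] == 50.0
        assert s.loc["BMI", "n_controls"] == 2

    def test_zero_cases_empty_summary(self):
        t = table_from_scores({"BMI": [1.0, 2.0]})
        s = case_control_summary(t, self._phen([0.0, 0.0]), "d")
        assert len(s) == 0

    def test_quartile_oracle_against_numpy(self):
        # oracle: direct quantile of the case percentiles, linear rule
        rng = np.random.default_rng(8)
        scores = rng.normal(size=30)
        statuses = (rng.random(30) < 0.4).astype(float)
        t = table_from_scores({"BMI": scores})
        phen = self._phen(list(statuses))
        s = case_control_summary(t, phen, "d")
        p = oracle_midrank(scores)[statuses == 1.0]
        np.testing.assert_allclose(
            [s.loc["BMI", "q1"], s.loc["BMI", "median"], s.loc["BMI", "q3"]],
            np.percentile(p, [25, 50, 75]),
            atol=1e-12,
        )


class TestScoreCorrelations:
    def test_diagonal_and_antithetic(self):
        x = np.array([1.0, 2.0, 4.0, 9.0])
        t = table_from_scores({"A": x, "B": -x})
        mats = score_correlations(t)
        assert mats["input"].loc["A", "A"] == pytest.approx(1.0)
        assert mats["input"].loc["A", "B"] == pytest.approx(-1.0)

    def test_independent_traits_weak_correlation(self):
        rng = np.random.default_rng(123)
        t = table_from_scores({"A": rng.normal(size=1000), "B": rng.normal(size=1000)})
        r = score_correlations(t)["input"].loc["A", "B"]
        assert abs(r) < 0.1

    def test_symmetric_psd(self):
        rng = np.random.default_rng(5)
        t = table_from_scores({k: rng.normal(size=50) for k in "ABCD"})
        mat = score_correlations(t)["input"].to_numpy()
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        assert np.linalg.eigvalsh(mat).min() > -1e-10

    def test_zero_variance_trait_undefined_not_zero(self):
        t = table_from_scores({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0]})
        mat = score_correlations(t)["input"]
        assert np.isnan(mat.loc["A", "B"])

    def test_too_few_samples_disabled_with_message(self):
        t = table_from_scores({"A": [1.0, 2.0], "B": [2.0, 1.0]})
        with pytest.raises(ProfilingError, match="at least 3"):
            score_correlations(t)

    def test_needs_two_traits(self):
        t = table_from_scores({"A": [1.0, 2.0, 3.0]})
        with pytest.raises(ProfilingError, match="two traits"):
            score_correlations(t)

    def test_case_control_side_by_side(self):
        rng = np.random.default_rng(9)
        n = 40
        t = table_from_scores({"A": rng.normal(size=n), "B": rng.normal(size=n)})
        phen = PhenotypeTable(
            pd.DataFrame(
                {"d": (np.arange(n) % 2).astype(float)},
                index=pd.Index([f"S{i}" for i in range(1, n + 1)], name="ID"),
            )
        )
        mats = score_correlations(t, phenotypes=phen, phenotype="d")
        assert {"input", "cases", "controls"} <= set(mats)

    def test_reference_matrix_from_panel(self):
        rng = np.random.default_rng(10)
        ref = pd.DataFrame(
            {
                "Sex": ["Male"] * 20,
                "Age": rng.uniform(30, 70, 20),
                "A": rng.normal(size=20),
                "B": rng.normal(size=20),
            },
            index=pd.Index([f"R{i}" for i in range(20)], name="ID"),
        )
        panel = ReferencePanel(pd.Series(dtype=float), reference_scores=ref)
        t = table_from_scores({"A": rng.normal(size=5), "B": rng.normal(size=5)})
        mats = score_correlations(t, panel=panel)
        assert "reference" in mats
        assert mats["reference"].loc["A", "A"] == pytest.approx(1.0)


class TestReferenceTraitCorrelations:
    def _panel(self, n=30, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ids = pd.Index([f"R{i}" for i in range(n)], name="ID")
        score = rng.normal(size=n)
        scores = pd.DataFrame(
            {
                "Sex": np.where(rng.random(n) < 0.5, "Male", "Female"),
                "Age": rng.uniform(30, 70, n),
                "T": score,
            },
            index=ids,
        )
        phen = pd.DataFrame({"T": score + rng.normal(0, noise, n)}, index=ids)
        return ReferencePanel(pd.Series(dtype=float), scores, phen)

    def test_exact_agreement_gives_r_one(self):
        out = reference_trait_correlations(self._panel(noise=0.0))
        assert out.loc["T", "r"] == pytest.approx(1.0)

    def test_attenuation_with_noise(self):
        # r should approximate sigma_s / sqrt(sigma_s^2 + sigma_e^2) = 1/sqrt(2)
        out = reference_trait_correlations(self._panel(n=500, noise=1.0, seed=42))
        assert out.loc["T", "r"] == pytest.approx(1 / np.sqrt(2), abs=0.08)

    def test_filter_excluding_all_rows_unavailable(self):
        out = reference_trait_correlations(
            self._panel(), f=CohortFilter(age_range=(200, 300))
        )
        assert not out.loc["T", "available"]

    def test_absent_trait_reported_unavailable(self):
        out = reference_trait_correlations(self._panel(), traits=["T", "Nope"])
        assert not out.loc["Nope", "available"]
        assert np.isnan(out.loc["Nope", "r"])

    def test_panel_without_pairs_raises(self):
        panel = ReferencePanel(pd.Series(dtype=float))
        with pytest.raises(ProfilingError, match="no paired"):
            reference_trait_correlations(panel)
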