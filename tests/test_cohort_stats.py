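import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ezquant.cohort_stats import (
    _design_matrix,
    _gls_profile,
    anova_oneway,
    apply_bonferroni,
    corr_binary_vs_outcome,
    fit_ar1_longitudinal,
    round_percentage,
    summarize_visits,
    ttest_unpaired,
)
from ezquant.oct_synth import CohortParams, FOLLOW_UP_VISITS, simulate_cohort


PRINTED_PAIRS = [
    (121, 353, 34.3),
    (36, 354, 10.2),
    (28, 327, 8.6),
    (21, 226, 9.3),
    (113, 232, 48.7),
    (120, 308, 39.0),
    (98, 299, 32.8),
    (91, 205, 44.4),
    (111, 231, 48.1),
    (33, 231, 14.3),
]


@pytest.mark.parametrize("count,denom,expected", PRINTED_PAIRS)
def test_percentage_rounding_half_up(count, denom, expected):
    assert round_percentage(count, denom) == expected


def _table_with_counts(visit, n_total, n_ungradable, n_present, n_zero):
    """Cohort rows engineered to given counts for one visit."""
    rows = []
    i = 0
    for _ in range(n_ungradable):
        rows.append((f"P{i}", visit, 60, np.nan, None, False)); i += 1
    for _ in range(n_present):
        rows.append((f"P{i}", visit, 60, 0.1, "patchy", True)); i += 1
    for _ in range(n_zero):
        rows.append((f"P{i}", visit, 60, 0.0, "normal", True)); i += 1
    for _ in range(n_total - i):
        rows.append((f"P{i}", visit, 60, np.nan, None, True)); i += 1
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "visit", "vals_letters",
            "defect_area_mm2", "grade", "gradable",
        ],
    )


def test_summarize_visits_counts_and_percentages():
    # M01 of the target cohort: 353 attended, 121 ungradable, 232 measured
    # of which 113 have no defect
    table = _table_with_counts("M01", 353, 121, 119, 113)
    (s,) = summarize_visits(table, visits=("M01",))
    assert (s.n_total, s.n_ungradable) == (353, 121)
    assert s.pct_ungradable == 34.3
    assert (s.n_measured, s.n_defect_absent) == (232, 113)
    assert s.pct_defect_absent == 48.7
    assert s.pct_defect_present == round_percentage(119, 232)


def test_summarize_visits_zero_count():
    table = _table_with_counts("M06", 50, 0, 10, 40)
    (s,) = summarize_visits(table, visits=("M06",))
    assert s.pct_ungradable == 0.0


class TestTTest:
    def test_identical_samples(self):
        res = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_welch_hand_oracle(self):
        # closed form: means 2 and 5, each var 1, n 3 -> t = -3/sqrt(2/3)
        res = ttest_unpaired([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.6742346, abs=1e-6)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.p == pytest.approx(0.0213116, abs=1e-6)

    def test_common_location_shift_invariance(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0, 8.0]
        r1 = ttest_unpaired(a, b)
        r2 = ttest_unpaired([x + 17.3 for x in a], [x + 17.3 for x in b])
        assert r1.t == pytest.approx(r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            ttest_unpaired([1.0], [2.0, 3.0])


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = anova_oneway({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.f == pytest.approx(0.0, abs=1e-12)

    def test_matches_sum_of_squares_decomposition(self):
        groups = {"n": [0, 0, 0.1], "p": [0.2, 0.3], "a": [0.5, 0.6, 0.7]}
        res = anova_oneway(groups)
        # independent brute-force SS decomposition
        all_vals = np.concatenate([np.asarray(v, float) for v in groups.values()])
        grand = all_vals.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        dfb, dfw = len(groups) - 1, len(all_vals) - len(groups)
        f_oracle = (ssb / dfb) / (ssw / dfw)
        assert res.f == pytest.approx(f_oracle, rel=1e-10)
        assert res.p == pytest.approx(sps.f.sf(f_oracle, dfb, dfw), rel=1e-10)

    def test_null_pvalues_uniform(self):
        """Permutation-style null: identically distributed groups give
        uniform p-values (KS at alpha=0.01)."""
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(1000):
            data = rng.normal(size=15)
            res = anova_oneway({"a": data[:5], "b": data[5:10], "c": data[10:]})
            ps.append(res.p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway({"only": [1, 2, 3]})


class TestPointBiserial:
    def test_hand_oracle(self):
        status = [0, 0, 0, 1, 1, 1]
        outcome = [50, 55, 60, 70, 75, 80]
        res = corr_binary_vs_outcome(status, outcome)
        r_oracle = np.corrcoef(status, outcome)[0, 1]
        assert res.r == pytest.approx(r_oracle)
        assert res.n == 6

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError):
            corr_binary_vs_outcome([0, 1, 0, 1], [5.0, 5.0, 5.0, 5.0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            corr_binary_vs_outcome([1, 1, 1], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortParams(n_participants=300, seed=21))


class TestAr1Model:
    def test_null_rho_recovered(self):
        table = simulate_cohort(CohortParams(n_participants=200, rho=0.0, seed=22))
        fit = fit_ar1_longitudinal(table, "area_continuous")
        assert abs(fit.rho) <= 0.1

    def test_rho_and_sigma_recovered(self, cohort):
        fit = fit_ar1_longitudinal(cohort, "area_continuous")
        assert fit.rho == pytest.approx(0.5, abs=0.15)
        assert fit.sigma == pytest.approx(8.0, rel=0.15)
        assert fit.converged

    def test_reduces_to_ols_at_rho_zero(self, cohort):
        fit = fit_ar1_longitudinal(cohort, "area_continuous", fix_rho=0.0)
        df = cohort.copy()
        rows = df[
            df["visit"].isin(FOLLOW_UP_VISITS)
            & df["vals_change"].notna()
            & df["defect_area_mm2"].notna()
        ]
        X, _ = _design_matrix(rows, "area_continuous")
        y = rows["vals_change"].to_numpy(float)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(fit.params.to_numpy() - beta).max() < 1e-8

    def test_profile_optimality_on_grid(self, cohort):
        """The returned rho beats every grid point by profile likelihood."""
        fit = fit_ar1_longitudinal(cohort, "area_continuous")
        df = cohort.copy()
        rows = df[
            df["visit"].isin(FOLLOW_UP_VISITS)
            & df["vals_change"].notna()
            & df["defect_area_mm2"].notna()
        ]
        X, _ = _design_matrix(rows, "area_continuous")
        y = rows["vals_change"].to_numpy(float)
        vid = rows["visit"].map(
            {v: i for i, v in enumerate(FOLLOW_UP_VISITS)}
        ).to_numpy(int)
        pid = rows["participant_id"].to_numpy()
        groups = []
        for p in pd.unique(pid):
            sel = pid == p
            groups.append((X[sel], y[sel], vid[sel]))
        for rho in np.linspace(-0.9, 0.9, 19):
            ll = _gls_profile(groups, float(rho), X.shape[1])[3]
            assert fit.loglik >= ll - 1e-6

    def test_grade_predictor_design(self, cohort):
        fit = fit_ar1_longitudinal(cohort, "grade_categorical")
        assert fit.converged
        # larger defect burden (absent grade) lowers VALS change at M01
        assert fit.params["grade[absent]:visit[M01]"] < 0


class TestBonferroni:
    def test_strict_threshold(self):
        assert apply_bonferroni([0.0019, 0.002, 0.5]) == [True, False, False]

    def test_empty(self):
        assert apply_bonferroni([]) == []

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            apply_bonferroni([1.5])


def test_defect_eyes_have_lower_vals_at_every_visit():
    """Direction of the qualitative contrast on the default cohort."""
    table = simulate_cohort(CohortParams(seed=9))
    for visit in FOLLOW_UP_VISITS:
        rows = table[(table["visit"] == visit)].dropna(subset=["defect_area_mm2"])
        present = rows[rows["defect_area_mm2"] > 0.004]["vals_letters"]
        absent = rows[rows["defect_area_mm2"] <= 0.004]["vals_letters"]
        assert present.mean() < absent.mean()
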