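"""Statistics layer: tests, adjustments, missing-data correlation, 4PL fits."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from fibromech import (
    SynthProtocol,
    adjust_holm_sidak,
    correlation_matrix,
    fit_dose_response,
    multigroup_tests,
    pairwise_tests,
    synth_dose_response,
)
from fibromech.exceptions import (
    InsufficientDataError,
    NoFitError,
    ParameterError,
    ValidationError,
)
from fibromech.stats import em_mvn_covariance


def mann_whitney_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by exhaustive rank-assignment enumeration."""
    combined = sorted(x + y)
    n1 = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    n = len(combined)
    mid = n1 * len(y) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        grp = [combined[i] for i in idx]
        rest = [combined[i] for i in range(n) if i not in idx]
        u = sum(1 for a in grp for b in rest if a > b) + 0.5 * sum(
            1 for a in grp for b in rest if a == b
        )
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
    return count / total


class TestPairwise:
    def test_mann_whitney_exact_matches_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        oracle = mann_whitney_exact_oracle(x, y)
        assert oracle == pytest.approx(0.1)
        res = pairwise_tests(x, y, method="mann_whitney")
        assert res.p == pytest.approx(oracle, abs=1e-12)

    def test_identical_samples_t_zero_p_one(self):
        res = pairwise_tests([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], method="welch_t")
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_welch_equals_student_at_equal_variance_and_n(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        w = pairwise_tests(x, y, method="welch_t")
        s = pairwise_tests(x, y, method="student_t")
        assert w.statistic == pytest.approx(s.statistic, abs=1e-12)
        assert w.p == pytest.approx(s.p, abs=1e-12)

    def test_log_transform_requires_positive(self):
        with pytest.raises(ParameterError):
            pairwise_tests([1.0, -1.0], [1.0, 2.0], method="welch_t", log_transform=True)

    def test_one_sample_t(self, rng):
        x = rng.normal(5.0, 1.0, 20)
        res = pairwise_tests(x, 5.0, method="one_sample_t")
        ref = sps.ttest_1samp(x, 5.0)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_mann_whitney_type_one_error(self, rng):
        # null: both samples N(0,1), n=15 each (asymptotic path); ~5% rejection
        rejections = sum(
            pairwise_tests(rng.normal(0, 1, 15), rng.normal(0, 1, 15), method="mann_whitney").p
            < 0.05
            for _ in range(2000)
        )
        assert 0.03 <= rejections / 2000 <= 0.07


class TestHolmSidak:
    def test_closed_form_smallest_of_five(self):
        adjusted = adjust_holm_sidak([0.01, 0.2, 0.3, 0.4, 0.5])
        assert adjusted[0] == pytest.approx(1 - 0.99**5, rel=1e-12)
        assert adjusted[0] == pytest.approx(0.049, abs=1e-3)

    def test_single_p_unchanged(self):
        assert adjust_holm_sidak([0.037])[0] == pytest.approx(0.037)

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            adjust_holm_sidak([0.5, 1.2])

    @given(
        ps=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    def test_never_decreases_and_monotone(self, ps):
        adjusted = adjust_holm_sidak(ps)
        assert np.all(adjusted >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)


class TestMultigroup:
    def test_identical_constants(self):
        groups = {k: np.full(5, 3.0) for k in ("a", "b", "c")}
        anova = multigroup_tests(groups, design="anova_dunnett", control="a")
        assert "zero_variance" in anova.omnibus.flags
        kw = multigroup_tests(groups, design="kruskal_dunn", control="a")
        assert kw.omnibus.statistic == 0.0
        assert kw.omnibus.p == 1.0

    def test_kruskal_power_on_separated_groups(self):
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            groups = {
                "a": g.normal(0, 1, 10),
                "b": g.normal(5, 1, 10),
                "c": g.normal(10, 1, 10),
            }
            res = multigroup_tests(groups, design="kruskal_dunn", control="a")
            hits += res.omnibus.p < 0.001
        assert hits == 100

    def test_dunnett_two_groups_reduces_to_t(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1, 12)
        res = multigroup_tests({"c": x, "t": y}, design="anova_dunnett", control="c")
        ref = sps.ttest_ind(y, x, equal_var=True)
        assert res.comparisons[0].p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_dunnett_familywise_error_under_null(self):
        rejections = 0
        reps = 2000
        for seed in range(reps):
            g = np.random.default_rng(seed)
            groups = {k: g.normal(0, 1, 10) for k in ("ctrl", "t1", "t2")}
            res = multigroup_tests(groups, design="anova_dunnett", control="ctrl")
            rejections += any(c.p_adjusted < 0.05 for c in res.comparisons)
        assert rejections / reps <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / reps)

    def test_rm_anova_matches_statsmodels(self, rng):
        from statsmodels.stats.anova import AnovaRM

        n, k = 8, 4
        matrix = rng.normal(0, 1, (n, k)) + np.arange(k) * 0.4
        groups = {f"g{j}": matrix[:, j] for j in range(k)}
        res = multigroup_tests(groups, design="rm_anova_dunnett", control="g0")
        long = pd.DataFrame(
            {
                "y": matrix.ravel(),
                "subject": np.repeat(np.arange(n), k),
                "cond": np.tile(np.arange(k), n),
            }
        )
        oracle = AnovaRM(long, "y", "subject", within=["cond"]).fit()
        assert res.omnibus.statistic == pytest.approx(
            float(oracle.anova_table["F Value"].iloc[0]), rel=1e-9
        )
        assert res.omnibus.p == pytest.approx(
            float(oracle.anova_table["Pr > F"].iloc[0]), rel=1e-9
        )

    def test_rm_design_rejects_incomplete_blocks(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0]}
        with pytest.raises(ValidationError):
            multigroup_tests(groups, design="rm_anova_dunnett", control="a")

    def test_adjusted_p_not_below_raw(self, rng):
        matrix = rng.normal(0, 1, (6, 4))
        groups = {f"g{j}": matrix[:, j] for j in range(4)}
        res = multigroup_tests(groups, design="rm_anova_dunnett", control="g0")
        for c in res.comparisons:
            assert c.p_adjusted >= c.p - 0.01  # MC resolution


class TestCorrelation:
    def test_em_equals_pearson_on_complete_data(self, rng):
        x = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 40)
        df = pd.DataFrame(x, columns=["a", "b"])
        em = correlation_matrix(df, method="em_mvn")
        pe = correlation_matrix(df, method="pearson")
        assert abs(em.r[0, 1] - pe.r[0, 1]) < 1e-8

    def test_spearman_one_for_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        df = pd.DataFrame({"a": x, "b": np.exp(x / 3.0)})
        res = correlation_matrix(df, method="spearman")
        assert res.r[0, 1] == pytest.approx(1.0)

    def test_spearman_monotone_transform_invariance(self, rng):
        x = rng.normal(0, 1, 50)
        y = x + rng.normal(0, 1, 50)
        base = correlation_matrix(pd.DataFrame({"a": x, "b": y}), method="spearman")
        warped = correlation_matrix(
            pd.DataFrame({"a": x, "b": np.exp(y)}), method="spearman"
        )
        assert warped.r[0, 1] == pytest.approx(base.r[0, 1], abs=1e-12)

    def test_em_recovers_correlation_under_mcar(self):
        g = np.random.default_rng(1)
        x = g.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], 500)
        x[g.random((500, 2)) < 0.2] = np.nan
        _, sigma, _, converged, _ = em_mvn_covariance(x)
        r = sigma[0, 1] / math.sqrt(sigma[0, 0] * sigma[1, 1])
        assert converged
        assert r == pytest.approx(0.7, abs=0.05)

    def test_em_matrix_symmetric_psd(self, rng):
        x = rng.multivariate_normal(np.zeros(4), np.eye(4) + 0.4, 120)
        x[rng.random(x.shape) < 0.15] = np.nan
        res = correlation_matrix(pd.DataFrame(x), method="em_mvn")
        assert np.allclose(res.r, res.r.T)
        assert np.linalg.eigvalsh(res.r).min() > -1e-8
        assert np.allclose(np.diag(res.r), 1.0)

    def test_sparse_variable_excluded_with_warning(self, rng):
        df = pd.DataFrame(
            {
                "a": rng.normal(0, 1, 20),
                "b": rng.normal(0, 1, 20),
                "c": [1.0, 2.0] + [np.nan] * 18,
            }
        )
        with pytest.warns(UserWarning, match="c"):
            res = correlation_matrix(df, method="em_mvn")
        assert res.variables == ["a", "b"]


class TestDoseResponse:
    def test_noiseless_round_trip_tenth_percent(self):
        table = synth_dose_response(0.016, hill=1.3, protocol=SynthProtocol(seed=0))
        fit = fit_dose_response(
            table.data["dose_um"].to_numpy(), table.data["activity_pct"].to_numpy()
        )
        assert fit.ic50 == pytest.approx(0.016, rel=1e-3)
        assert fit.hill == pytest.approx(1.3, rel=1e-3)
        assert fit.top == pytest.approx(100.0, rel=1e-3)

    def test_flat_response_no_fit(self):
        with pytest.raises(NoFitError):
            fit_dose_response([0.001, 0.01, 0.1, 1.0], [50.0, 50.0, 50.0, 50.0])

    def test_too_few_dose_levels(self):
        with pytest.raises(InsufficientDataError):
            fit_dose_response([0.01, 0.1, 1.0], [90.0, 50.0, 10.0])

    def test_ic50_recovery_with_noise_over_seeds(self):
        # LOXL2-like IC50 at 2% assay CV, 10 doses in triplicate: within 10%
        doses = np.repeat(np.geomspace(0.005 / 300, 0.005 * 300, 10), 3)
        errs = []
        for seed in range(100):
            table = synth_dose_response(
                0.005, doses_um=doses, protocol=SynthProtocol(seed=seed), noise_rel=0.02
            )
            fit = fit_dose_response(
                table.data["dose_um"].to_numpy(), table.data["activity_pct"].to_numpy()
            )
            errs.append(abs(fit.ic50 / 0.005 - 1.0))
        assert np.max(errs) <= 0.10
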