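import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from calfcontrib import StatsError, lsd_posthoc, rm_anova, skewness
from calfcontrib.stats import compare_conditions

WORKED = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 5.0]])  # hand-computed F = 16


class TestSkewness:
    def test_symmetric_sample(self):
        assert skewness([1.0, 2.0, 3.0]) == pytest.approx(0.0, abs=1e-12)

    def test_bernoulli_sample(self):
        # m2 = 3/16, m3 = 3/32 -> g1 = 2/sqrt(3) = 1.1547
        assert skewness([0.0, 0.0, 0.0, 1.0]) == pytest.approx(1.1547, abs=1e-4)

    def test_zero_variance(self):
        with pytest.raises(StatsError, match="degenerate sample"):
            skewness([5.0, 5.0, 5.0])

    def test_matches_scipy_biased(self, rng):
        x = rng.normal(size=50)
        assert skewness(x) == pytest.approx(sps.skew(x, bias=True), abs=1e-12)


class TestRmAnova:
    def test_worked_example_f_16(self):
        res = rm_anova(WORKED)
        assert res.f_statistic == pytest.approx(16.0, abs=1e-9)
        assert res.df == (1, 2)
        # hand SS decomposition
        assert res.ss_condition == pytest.approx(8.0 / 3.0, abs=1e-12)
        assert res.ss_subject == pytest.approx(19.0 / 3.0, abs=1e-12)
        assert res.ss_error == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_null_effect(self):
        res = rm_anova(np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0]]))
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_f_equals_paired_t_squared(self, rng):
        for _ in range(10):
            data = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1))
            res = rm_anova(data)
            t = sps.ttest_rel(data[:, 0], data[:, 1])
            assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-9)
            assert res.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_ss_conservation(self, rng):
        data = rng.normal(size=(12, 4))
        res = rm_anova(data)
        ss_total = float(np.sum((data - data.mean()) ** 2))
        assert res.ss_condition + res.ss_subject + res.ss_error == pytest.approx(
            ss_total, rel=1e-12
        )

    def test_subject_constant_invariance(self, rng):
        data = rng.normal(size=(10, 3))
        shifted = data + rng.normal(size=(10, 1)) * 50
        assert rm_anova(shifted).f_statistic == pytest.approx(
            rm_anova(data).f_statistic, rel=1e-9
        )

    def test_condition_relabeling_invariance(self, rng):
        data = rng.normal(size=(10, 4))
        perm = data[:, [2, 0, 3, 1]]
        assert rm_anova(perm).f_statistic == pytest.approx(
            rm_anova(data).f_statistic, rel=1e-12
        )

    def test_missing_cell(self):
        data = WORKED.copy()
        data[0, 0] = np.nan
        with pytest.raises(StatsError, match="unbalanced design"):
            rm_anova(data)

    def test_degenerate_error_term(self):
        data = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(StatsError, match="degenerate error term"):
            rm_anova(data)

    def test_too_small(self):
        with pytest.raises(StatsError):
            rm_anova(np.array([[1.0, 2.0]]))


class TestLsdPosthoc:
    def test_worked_example_t(self):
        res = rm_anova(WORKED)
        post = lsd_posthoc(WORKED, res)
        assert post.pairs == ((0, 1),)
        assert abs(post.t_statistics[0]) == pytest.approx(4.0, abs=1e-9)
        assert post.df == 2
        assert post.mean_diffs[0] == pytest.approx(-4.0 / 3.0, abs=1e-12)

    def test_identical_means_null(self):
        data = np.array([[1.0, 1.0], [2.0, 2.0], [4.0, 4.0]])
        res = rm_anova(data)
        post = lsd_posthoc(data, res)
        assert post.t_statistics[0] == pytest.approx(0.0, abs=1e-12)
        assert post.p_values[0] == pytest.approx(1.0)

    def test_k2_p_matches_anova(self, rng):
        data = rng.normal(size=(9, 2))
        res = rm_anova(data)
        post = lsd_posthoc(data, res)
        assert post.p_values[0] == pytest.approx(res.p_value, rel=1e-9)
        assert post.t_statistics[0] ** 2 == pytest.approx(res.f_statistic, rel=1e-9)

    def test_antisymmetry_in_pair_order(self, rng):
        data = rng.normal(size=(6, 3))
        res = rm_anova(data)
        post = lsd_posthoc(data, res)
        flipped = lsd_posthoc(data[:, ::-1], rm_anova(data[:, ::-1]))
        # pair (0,1) on flipped data is pair (2,1) on the original
        orig = dict(zip(post.pairs, post.t_statistics))
        assert flipped.t_statistics[0] == pytest.approx(-orig[(1, 2)], rel=1e-9)


class TestCompareConditions:
    @staticmethod
    def _table(data, muscle="A", phase="braking"):
        rows = []
        n, k = data.shape
        for i in range(n):
            for j in range(k):
                rows.append((i, float(j), phase, muscle, data[i, j]))
        return pd.DataFrame(
            rows,
            columns=["subject", "condition", "phase", "muscle", "contribution_pct"],
        )

    def test_single_condition_rejected(self):
        df = self._table(WORKED)[lambda d: d.condition == 0.0]
        with pytest.raises(StatsError, match=">= 2 conditions"):
            compare_conditions(df)

    def test_report_shape(self, rng):
        data = rng.normal(10, 1, size=(6, 4))
        df = self._table(data)
        out = compare_conditions(df)
        assert list(out["muscle"]) == ["A"]
        assert {"F", "p", "significant"} <= set(out.columns)
        # 4 conditions -> 6 pairwise columns
        assert sum(c.startswith("p_") and "vs" in c for c in out.columns) == 6

    def test_induced_effect_flagged(self, rng):
        base = rng.normal(10, 0.5, size=(10, 4))
        base[:, 0] += 3.0  # strong condition effect
        out = compare_conditions(self._table(base))
        assert bool(out["significant"].iloc[0])


@pytest.mark.slow
class TestMonteCarlo:
    def test_type_I_error_within_binomial_ci(self):
        # 2000 seeded null replicates at alpha = 0.05: the rejection count
        # must fall inside the 99% binomial interval around 0.05
        rng = np.random.default_rng(20240901)
        n_rep, n, k, alpha = 2000, 10, 4, 0.05
        rejections = 0
        for _ in range(n_rep):
            data = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            if rm_anova(data).p_value < alpha:
                rejections += 1
        lo, hi = sps.binom.interval(0.99, n_rep, alpha)
        assert lo <= rejections <= hi

    def test_null_p_distribution_uniform(self):
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(2000):
            data = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1))
            pvals.append(rm_anova(data).p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_power_against_shifted_mean(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(200):
            data = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1))
            data[:, 0] += 1.5
            if rm_anova(data).p_value < 0.05:
                hits += 1
        assert hits / 200 > 0.8
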