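import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ssapipe.exceptions import DataError, DegenerateDataError, InsufficientDataError
from ssapipe.stats import (
    ONE_SAMPLE_T,
    PAIRED_T,
    WILCOXON,
    gated_one_sample_test,
    gated_paired_test,
    holm_bonferroni_adjust,
    lilliefors_test,
    rm_anova_gg,
)


class TestLilliefors:
    def test_statistic_matches_statsmodels(self, rng):
        from statsmodels.stats.diagnostic import lilliefors as sm_lillie

        for n in (10, 50, 200):
            x = rng.normal(2.0, 3.0, n)
            d_ours, _ = lilliefors_test(x, n_mc=500, seed=0)
            d_sm, _ = sm_lillie(x, dist="norm")
            assert d_ours == pytest.approx(d_sm, abs=1e-12)

    def test_null_calibration_on_normal_samples(self):
        rng = np.random.default_rng(0)
        passed = sum(
            lilliefors_test(rng.normal(0, 1, 1000), seed=7)[1] > 0.05
            for _ in range(200)
        )
        assert passed >= 0.90 * 200

    def test_power_against_exponential_samples(self):
        rng = np.random.default_rng(0)
        rejected = sum(
            lilliefors_test(rng.exponential(1.0, 1000), seed=7)[1] < 0.05
            for _ in range(100)
        )
        assert rejected >= 99

    def test_constant_and_tiny_samples_rejected(self):
        with pytest.raises(DegenerateDataError):
            lilliefors_test([1.0] * 10)
        with pytest.raises(InsufficientDataError):
            lilliefors_test([1.0, 2.0, 3.0])


class TestGatedOneSample:
    def test_forced_t_branch_closed_form(self):
        # t = mean/(sd/sqrt(n)) = 2/(1/sqrt(3)), df = 2
        res = gated_one_sample_test([1.0, 2.0, 3.0], 0.0, force="t")
        assert res.test_used == ONE_SAMPLE_T
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.p_value == pytest.approx(0.0742, abs=1e-4)

    @pytest.mark.parametrize("force", ["t", "wilcoxon"])
    def test_symmetric_sample_is_not_significant(self, force):
        x = [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]
        res = gated_one_sample_test(x, 0.0, force=force)
        assert res.p_value > 0.5

    def test_heavy_tails_select_the_nonparametric_branch(self):
        rng = np.random.default_rng(5)
        chosen = sum(
            gated_one_sample_test(rng.standard_cauchy(25), 0.0, seed=99).test_used
            == WILCOXON
            for _ in range(60)
        )
        assert chosen > 30  # most repeats

    def test_sample_equal_to_null_is_degenerate_with_p_one(self):
        res = gated_one_sample_test([0.5] * 6, 0.5)
        assert res.degenerate and res.p_value == 1.0


class TestGatedPaired:
    def test_identical_samples_flagged_degenerate(self):
        x = np.arange(6.0)
        res = gated_paired_test(x, x)
        assert res.degenerate and res.p_value == 1.0

    def test_constant_nonzero_difference_is_an_error(self):
        x = np.arange(5.0)
        with pytest.raises(DegenerateDataError):
            gated_paired_test(x + 1.0, x)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(DataError):
            gated_paired_test([1.0, 2.0], [1.0])

    def test_normal_shifted_pairs_power(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(40):
            y = rng.normal(0, 1, 25)
            x = y + rng.normal(1.0, 1.0, 25)
            res = gated_paired_test(x, y, seed=17)
            hits += res.test_used == PAIRED_T and res.p_value < 0.01
        assert hits >= 0.95 * 40


def brute_force_rm_anova(x):
    """Independent sums-of-squares oracle by direct summation."""
    n, a, b = x.shape
    grand = x.mean()
    ss = {"A": 0.0, "B": 0.0, "AB": 0.0, "AS": 0.0, "BS": 0.0, "ABS": 0.0}
    for i in range(a):
        ss["A"] += n * b * (x[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss["B"] += n * a * (x[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (
                x[:, i, j].mean() - x[:, i, :].mean() - x[:, :, j].mean() + grand
            ) ** 2
    for s in range(n):
        for i in range(a):
            ss["AS"] += b * (
                x[s, i, :].mean() - x[:, i, :].mean() - x[s].mean() + grand
            ) ** 2
        for j in range(b):
            ss["BS"] += a * (
                x[s, :, j].mean() - x[:, :, j].mean() - x[s].mean() + grand
            ) ** 2
        for i in range(a):
            for j in range(b):
                ss["ABS"] += (
                    x[s, i, j]
                    - x[s, i, :].mean()
                    - x[s, :, j].mean()
                    - x[:, i, j].mean()
                    + x[s].mean()
                    + x[:, i, :].mean()
                    + x[:, :, j].mean()
                    - grand
                ) ** 2
    f_a = (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (n - 1)))
    f_b = (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (n - 1)))
    f_ab = (ss["AB"] / ((a - 1) * (b - 1))) / (
        ss["ABS"] / ((a - 1) * (b - 1) * (n - 1))
    )
    return f_a, f_b, f_ab


class TestRmAnova:
    def test_two_level_factor_has_epsilon_exactly_one(self, rng):
        x = rng.normal(size=(6, 2, 4))
        res = rm_anova_gg(x)
        assert res.effects["light"].epsilon == 1.0

    def test_matches_brute_force_oracle_on_small_table(self, rng):
        x = rng.normal(size=(4, 2, 3)) + np.arange(3)[None, None, :]
        res = rm_anova_gg(x)
        f_a, f_b, f_ab = brute_force_rm_anova(x)
        assert res.effects["light"].F == pytest.approx(f_a, abs=1e-8)
        assert res.effects["tone"].F == pytest.approx(f_b, abs=1e-8)
        assert res.effects["light*tone"].F == pytest.approx(f_ab, abs=1e-8)

    def test_matches_pingouin_including_gg_correction(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(size=(8, 2, 5)) + np.linspace(0, 1, 5)[None, None, :]
        res = rm_anova_gg(x)
        rows = [
            {"subj": s, "light": i, "tone": j, "y": x[s, i, j]}
            for s in range(8)
            for i in range(2)
            for j in range(5)
        ]
        aov = pg.rm_anova(
            data=pd.DataFrame(rows),
            dv="y",
            within=["light", "tone"],
            subject="subj",
            correction=True,
            detailed=True,
        ).set_index("Source")
        for ours, theirs in [("light", "light"), ("tone", "tone"), ("light*tone", "light * tone")]:
            e = res.effects[ours]
            assert e.F == pytest.approx(aov.loc[theirs, "F"], rel=1e-9)
            assert e.epsilon == pytest.approx(aov.loc[theirs, "eps"], rel=1e-9)
            assert e.p_gg == pytest.approx(aov.loc[theirs, "p_GG_corr"], rel=1e-9)

    def test_compound_symmetry_keeps_epsilon_high(self):
        rng = np.random.default_rng(42)
        eps = []
        for _ in range(10):
            subj = rng.normal(0, 1, (50, 1, 1))
            x = subj + rng.normal(0, 1, (50, 2, 4))  # exchangeable errors
            eps.append(rm_anova_gg(x).effects["tone"].epsilon)
        assert np.mean(eps) > 0.9

    def test_epsilon_stays_within_theoretical_bounds(self, rng):
        for _ in range(20):
            x = rng.normal(size=(6, 2, 5)) * rng.uniform(0.2, 3.0, size=(1, 1, 5))
            res = rm_anova_gg(x)
            k = 5
            assert 1.0 / (k - 1) - 1e-9 <= res.effects["tone"].epsilon <= 1.0 + 1e-9

    def test_uncorrected_p_equals_gg_p_when_epsilon_is_one(self, rng):
        x = rng.normal(size=(6, 2, 4))
        e = rm_anova_gg(x).effects["light"]  # single contrast: eps == 1
        assert e.p_gg == pytest.approx(e.p_uncorrected, abs=1e-15)

    def test_preconditions(self, rng):
        with pytest.raises(InsufficientDataError):
            rm_anova_gg(rng.normal(size=(2, 2, 3)))
        bad = rng.normal(size=(5, 2, 3))
        bad[0, 0, 0] = np.nan
        with pytest.raises(DataError):
            rm_anova_gg(bad)


class TestHolm:
    def test_step_down_hand_example(self):
        adj = holm_bonferroni_adjust([0.01, 0.02, 0.30])
        np.testing.assert_allclose(adj.adjusted, [0.03, 0.04, 0.30])
        assert list(adj.reject) == [True, True, False]

    def test_single_p_unchanged(self):
        adj = holm_bonferroni_adjust([0.04])
        assert adj.adjusted[0] == pytest.approx(0.04)

    def test_equal_ps_accumulate_the_max(self):
        adj = holm_bonferroni_adjust([0.05, 0.05, 0.05])
        np.testing.assert_allclose(adj.adjusted, [0.15, 0.15, 0.15])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 9)
        adj = holm_bonferroni_adjust(p)
        _, p_sm, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(adj.adjusted, p_sm, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dominates_bonferroni_and_preserves_order(self, p):
        adj = holm_bonferroni_adjust(p)
        m = len(p)
        assert np.all(adj.adjusted <= np.minimum(1.0, m * adj.raw) + 1e-12)
        assert np.all(adj.adjusted >= adj.raw - 1e-12)
        order = np.argsort(adj.raw, kind="stable")
        assert np.all(np.diff(adj.adjusted[order]) >= -1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(DataError):
            holm_bonferroni_adjust([0.1, 1.2])
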