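"""Inferential statistics against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from swnf import stats as sws


class TestTTests:
    def test_one_sample_symmetric_data(self):
        out = sws.ttest_zero([-1.0, 0.0, 1.0])
        assert out.statistic == 0.0
        assert out.p_value == 1.0

    def test_two_equal_samples(self):
        out = sws.ttest_ind([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.statistic == 0.0

    def test_pooled_t_matches_hand_formula(self, rng):
        a = rng.normal(1.0, 1.0, 12)
        b = rng.normal(0.0, 1.5, 9)
        out = sws.ttest_ind(a, b)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
               ) / (len(a) + len(b) - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a)
                                                        + 1 / len(b)))
        assert out.statistic == pytest.approx(t_hand, rel=1e-12)
        assert out.df == len(a) + len(b) - 2

    def test_paired_equals_one_sample_on_differences(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        assert sws.ttest_paired(a, b).statistic == pytest.approx(
            sws.ttest_zero(a - b).statistic, rel=1e-12)

    def test_zero_variance_zero_effect_convention(self):
        with pytest.warns(UserWarning):
            out = sws.ttest_ind([2.0, 2.0, 2.0], [2.0, 2.0])
        assert out.p_value == 1.0

    def test_type_one_error_calibrated(self):
        """Null rejection rate of the two-sample test is 5% +- 1%."""
        rng = np.random.default_rng(7)
        n, runs = 17, 10_000
        a = rng.standard_normal((runs, n))
        b = rng.standard_normal((runs, n))
        from scipy.stats import ttest_ind
        _, p = ttest_ind(a, b, axis=1)
        rate = (p < 0.05).mean()
        assert 0.04 <= rate <= 0.06


def _mixed_anova_oracle(df):
    """Brute-force sums-of-squares for a balanced 2-group x m-day design."""
    groups = sorted(df["group"].unique())
    days = sorted(df["day"].unique())
    grand = df["value"].mean()
    n_per_group = df[df.group == groups[0]]["subject"].nunique()
    m = len(days)
    subj_means = df.groupby("subject")["value"].mean()
    subj_group = df.groupby("subject")["group"].first()
    ss_group = m * sum(
        n_per_group * (df[df.group == g]["value"].mean() - grand) ** 2
        for g in groups)
    ss_subj_within = m * sum(
        (subj_means[s] - df[df.group == subj_group[s]]["value"].mean()) ** 2
        for s in subj_means.index)
    ss_day = len(groups) * n_per_group * sum(
        (df[df.day == d]["value"].mean() - grand) ** 2 for d in days)
    ss_int = 0.0
    for g in groups:
        for d in days:
            cell = df[(df.group == g) & (df.day == d)]["value"].mean()
            ss_int += n_per_group * (
                cell - df[df.group == g]["value"].mean()
                - df[df.day == d]["value"].mean() + grand) ** 2
    ss_total = ((df["value"] - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj_within - ss_day - ss_int
    df_group = len(groups) - 1
    df_sw = len(groups) * (n_per_group - 1)
    df_day = m - 1
    df_int = df_group * df_day
    df_err = df_sw * df_day
    return {
        "group": (ss_group / df_group) / (ss_subj_within / df_sw),
        "day": (ss_day / df_day) / (ss_err / df_err),
        "interaction": (ss_int / df_int) / (ss_err / df_err),
    }


class TestMixedAnova:
    def _frame(self, values):
        rows = []
        for g, group in enumerate(("UP", "DOWN")):
            for s in range(len(values[g])):
                for d in range(3):
                    rows.append((f"{group}{s}", group, d, values[g][s][d]))
        return pd.DataFrame(rows, columns=["subject", "group", "day",
                                           "value"])

    def test_constant_data_gives_zero_f(self):
        df = self._frame([[[1.0] * 3] * 4, [[1.0] * 3] * 4])
        res = sws.rm_anova_mixed(df)
        assert np.allclose(res["F"].fillna(0.0), 0.0)

    def test_pure_interaction_pattern(self, rng):
        up = [[v + 0.05 * rng.normal() for v in (1.0, 0.0, -1.0)]
              for _ in range(4)]
        down = [[v + 0.05 * rng.normal() for v in (-1.0, 0.0, 1.0)]
                for _ in range(4)]
        res = sws.rm_anova_mixed(self._frame([up, down])).set_index("effect")
        assert res.loc["interaction", "F"] > 10
        assert res.loc["interaction", "F"] > 100 * res.loc["day", "F"]
        assert res.loc["interaction", "F"] > 100 * res.loc["group", "F"]

    def test_matches_brute_force_oracle(self, rng):
        vals = [[list(rng.normal(size=3)) for _ in range(6)]
                for _ in range(2)]
        df = self._frame(vals)
        res = sws.rm_anova_mixed(df).set_index("effect")
        oracle = _mixed_anova_oracle(df)
        for effect in ("group", "day", "interaction"):
            assert res.loc[effect, "F"] == pytest.approx(oracle[effect],
                                                         abs=1e-10)

    def test_missing_cells_rejected(self):
        df = self._frame([[[1.0, 2.0, 3.0]] * 3, [[0.0, 1.0, 2.0]] * 3])
        with pytest.raises(ValueError):
            sws.rm_anova_mixed(df.iloc[:-1])


class TestPearson:
    def test_perfect_correlations(self, rng):
        x = rng.normal(size=10)
        assert sws.pearson_corr(x, x).statistic == pytest.approx(1.0)
        assert sws.pearson_corr(x, -2 * x).statistic == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum()
                      * ((y - y.mean()) ** 2).sum())
        assert sws.pearson_corr(x, y).effect == pytest.approx(num / den,
                                                              rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sws.pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFDR:
    def test_step_up_by_hand(self):
        rejected, adjusted = sws.fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert rejected.all()
        assert adjusted[-1] == pytest.approx(0.04)

    def test_all_ones_reject_nothing(self):
        rejected, _ = sws.fdr_bh([1.0, 1.0, 1.0])
        assert not rejected.any()

    @pytest.mark.parametrize("q_pair", [(0.01, 0.05), (0.05, 0.2)])
    def test_rejections_monotone_in_q(self, q_pair, rng):
        p = rng.uniform(size=40)
        lo, _ = sws.fdr_bh(p, q=q_pair[0])
        hi, _ = sws.fdr_bh(p, q=q_pair[1])
        assert lo.sum() <= hi.sum()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sws.fdr_bh([0.1, 1.3])


class TestEdgewise:
    def test_identical_groups_select_nothing(self, rng):
        a = rng.normal(size=(10, 50))
        res = sws.edgewise_ttest(a, a.copy())
        assert not res["selected"].any()

    def test_selection_mask_matches_p_threshold(self, rng):
        a = rng.normal(size=(17, 595))
        b = rng.normal(size=(17, 595))
        res = sws.edgewise_ttest(a, b, alpha=0.01)
        assert res["selected"].sum() == (res["p"] < 0.01).sum()

    def test_large_shift_detected(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = r.normal(size=(17, 100))
            b = r.normal(size=(17, 100))
            a[:, 42] += 5.0   # 5 pooled SDs
            res = sws.edgewise_ttest(a, b, alpha=0.01)
            hits += bool(res["selected"][42])
        assert hits >= 95

    def test_small_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            sws.edgewise_ttest(rng.normal(size=(1, 10)),
                               rng.normal(size=(5, 10)))


class TestSampleSize:
    def test_study_configuration_gives_28(self):
        assert sws.sample_size_rm_anova(sws.PowerSpec()) == 28

    def test_minimality(self):
        spec = sws.PowerSpec()
        n = sws.sample_size_rm_anova(spec)
        assert sws.power_rm_interaction(n, spec) >= spec.power
        assert sws.power_rm_interaction(n - 2, spec) < spec.power

    def test_monotone_in_effect_size(self):
        big = sws.PowerSpec(effect_size_f=0.5)
        assert sws.sample_size_rm_anova(big) < sws.sample_size_rm_anova()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            sws.PowerSpec(effect_size_f=-1.0)
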