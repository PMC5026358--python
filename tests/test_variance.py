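"""Explained-variance indices and repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ansacuity.variance import paired_contrasts, r2_lr, r2_ols, rm_anova_gg
from conftest import make_bernoulli_trials
from ansacuity.psychomodels import predict_accuracy_linear


def _rt_trials(item_set, rt_fn, rng):
    return make_bernoulli_trials(
        lambda r: np.full_like(r, 0.8), item_set, rng, rt_fn=rt_fn
    )


class TestR2:
    def test_exact_linear_rt_gives_unity(self, small_item_set):
        rng = np.random.default_rng(0)
        t = _rt_trials(small_item_set, lambda r, g: 100.0 + 50.0 * r, rng)
        assert r2_ols(t) == pytest.approx(1.0)

    def test_ratio_free_rt_gives_near_zero(self, item_set):
        rng = np.random.default_rng(1)
        t = _rt_trials(item_set, lambda r, g: 500.0 + g.normal(0, 50, len(r)), rng)
        assert r2_ols(t) < 0.02

    def test_added_noise_reduces_r2(self, item_set):
        rng = np.random.default_rng(2)
        lo = _rt_trials(item_set, lambda r, g: 500 + 50 * r + g.normal(0, 5, len(r)), rng)
        hi = _rt_trials(item_set, lambda r, g: 500 + 50 * r + g.normal(0, 50, len(r)), rng)
        assert r2_ols(lo) > r2_ols(hi)

    def test_constant_rt_defined_as_zero(self, small_item_set):
        rng = np.random.default_rng(3)
        t = _rt_trials(small_item_set, lambda r, g: np.full(len(r), 500.0), rng)
        assert r2_ols(t) == 0.0

    def test_r2_lr_formula_against_direct_loglik(self, item_set):
        rng = np.random.default_rng(4)
        t = make_bernoulli_trials(
            lambda r: predict_accuracy_linear(1.0 / r, 0.4), item_set, rng
        )
        value = r2_lr(t)
        # independent computation of the two log-likelihoods
        import statsmodels.api as sm

        y = t["correct"].to_numpy(dtype=float)
        x = sm.add_constant(t["ratio_R"].to_numpy())
        l1 = sm.Logit(y, x).fit(disp=0).llf
        l0 = len(y) * (
            np.mean(y) * np.log(np.mean(y)) + (1 - np.mean(y)) * np.log(1 - np.mean(y))
        )
        expect = 1.0 - np.exp((2.0 / len(y)) * (l0 - l1))
        assert value == pytest.approx(expect, rel=1e-6)
        assert 0.0 < value < 1.0

    def test_r2_lr_invariant_to_side_relabeling(self, item_set):
        rng = np.random.default_rng(5)
        t = make_bernoulli_trials(
            lambda r: predict_accuracy_linear(1.0 / r, 0.4), item_set, rng
        )
        flipped = t.copy()
        flipped["n_left"], flipped["n_right"] = t["n_right"], t["n_left"]
        flipped["response_side"] = np.where(
            t["response_side"] == "left", "right", "left"
        )
        flipped["ratio_R"] = t["ratio_R"]
        assert r2_lr(flipped) == pytest.approx(r2_lr(t))

    def test_accuracy_carries_more_ratio_variance_than_rt(self, ddm_cohort):
        """The generator's ratio effect lands mostly in accuracy, not RT."""
        lr_vals, rt_vals = [], []
        for _, grp in ddm_cohort.groupby("participant_id"):
            try:
                lr_vals.append(r2_lr(grp))
            except ValueError:
                continue
            rt_vals.append(r2_ols(grp))
        assert np.nanmean(lr_vals) > np.nanmean(rt_vals)


class TestRmAnova:
    def test_two_conditions_equal_squared_paired_t(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 12)
        b = a + 0.5 + rng.normal(0, 0.5, 12)
        res = rm_anova_gg(np.column_stack([a, b]))
        t, p = stats.ttest_rel(a, b)
        assert res.epsilon_gg == pytest.approx(1.0)
        assert res.F == pytest.approx(t**2, rel=1e-9)
        assert res.p_uncorrected == pytest.approx(p, rel=1e-9)

    def test_compound_symmetric_data_epsilon_near_one(self):
        rng = np.random.default_rng(7)
        subj = rng.normal(0, 1, size=(200, 1))
        X = subj + rng.normal(0, 1, size=(200, 3))
        res = rm_anova_gg(X)
        assert res.epsilon_gg > 0.97

    def test_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        n, k = 15, 4
        X = rng.normal(0, 1, size=(n, k)) + rng.normal(0, 1, size=(n, 1))
        X[:, 0] += np.linspace(0, 2, n)  # break sphericity
        res = rm_anova_gg(X)
        long = pd.DataFrame(
            {
                "y": X.ravel(),
                "cond": np.tile(np.arange(k), n),
                "subj": np.repeat(np.arange(n), k),
            }
        )
        ref = pingouin.rm_anova(
            data=long, dv="y", within="cond", subject="subj", correction=True
        )
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.epsilon_gg == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)
        assert res.p_gg == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-4)

    def test_permutation_leaves_f_distribution_centered(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, size=(20, 3))
        base = rm_anova_gg(X).F
        fs = []
        for _ in range(50):
            Xp = np.array([row[rng.permutation(3)] for row in X])
            fs.append(rm_anova_gg(Xp).F)
        # under exchangeability the observed F is typical of the permuted Fs
        assert np.quantile(fs, 0.01) <= base <= np.quantile(fs, 0.99)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_gg(np.ones((5, 1)))


class TestContrasts:
    def test_identical_columns_null(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        out = paired_contrasts(df, [("a", "b")])
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p_raw"] == 1.0
        assert out.loc[0, "p_adj"] == out.loc[0, "p_raw"]

    def test_only_true_effect_survives_adjustment(self):
        rng = np.random.default_rng(10)
        hits = 0
        for rep in range(20):
            n = 25
            base = rng.normal(0, 1, n)
            df = pd.DataFrame(
                {
                    "a": base + rng.normal(0, 0.3, n),
                    "b": base + rng.normal(0, 0.3, n),
                    "c": base + 0.5 + rng.normal(0, 0.3, n),
                }
            )
            out = paired_contrasts(df, [("a", "b"), ("a", "c"), ("b", "c")])
            sig = out[out["p_adj"] < 0.05]
            if set(map(tuple, sig[["a", "b"]].to_numpy())) == {("a", "c"), ("b", "c")}:
                hits += 1
        assert hits >= 15  # the true contrasts dominate across replicates
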