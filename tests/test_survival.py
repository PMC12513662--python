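import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flydemog import survival
from flydemog.survival import (km_estimate, logrank, pairwise_logrank_bh,
                               percentile)
from flydemog.synth import gompertz_lifespans

from conftest import deaths_frame


def _brute_force_product_limit(df):
    """Independent oracle: explicit interval-by-interval product."""
    agg = df.groupby("day")[["n_dead", "n_censored"]].sum().sort_index()
    n = agg.sum().sum()
    out = {}
    s = 1.0
    for day, row in agg.iterrows():
        s *= 1 - row["n_dead"] / n
        n -= row["n_dead"] + row["n_censored"]
        out[day] = s
    return out


class TestKaplanMeier:
    def test_uncensored_equals_empirical(self):
        df = deaths_frame([1, 2, 3, 4])
        curve = km_estimate(df)
        assert curve.survival_at(2) == pytest.approx(0.5)
        assert curve.survival_at(4) == pytest.approx(0.0)

    def test_censoring_at_event_day(self):
        # censored fly at risk through its census day, removed after
        df = deaths_frame([1], dead=[1], censored=[1])
        assert km_estimate(df).survival_at(1) == pytest.approx(0.5)

    def test_matches_brute_force_on_mixed_table(self):
        df = deaths_frame(
            days=[2, 4, 6, 9, 11, 13, 16, 18, 20, 23],
            dead=[3, 1, 0, 4, 2, 5, 1, 0, 2, 1],
            censored=[0, 1, 1, 0, 2, 0, 0, 1, 0, 0])
        curve = km_estimate(df)
        oracle = _brute_force_product_limit(df)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(oracle[t], abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(2)
        t = rng.integers(1, 25, size=200)
        dead = rng.uniform(size=200) > 0.2
        df = deaths_frame(list(t), dead=list(dead.astype(int)),
                          censored=list((~dead).astype(int)))
        curve = km_estimate(df)
        kmf = KaplanMeierFitter().fit(t, dead.astype(int))
        for day, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(kmf.predict(day), abs=1e-12)

    def test_all_censored_warns_and_stays_one(self):
        df = deaths_frame([2, 4], dead=[0, 0], censored=[1, 1])
        with pytest.warns(UserWarning):
            curve = km_estimate(df)
        assert (curve.survival == 1.0).all()
        assert not percentile(curve, 0.5).defined

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(deaths_frame([-1]))
        with pytest.raises(ValueError):
            km_estimate(deaths_frame([1], dead=[-2]))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 40), min_size=1, max_size=60))
    def test_no_censoring_equals_empirical_survival(self, days):
        # with no censoring the product-limit estimate is the empirical
        # survival function exactly
        df = deaths_frame(days)
        curve = km_estimate(df)
        days_arr = np.array(days)
        for t in curve.times:
            emp = (days_arr > t).mean()
            assert curve.survival_at(t) == pytest.approx(emp, abs=1e-12)


class TestPercentile:
    def test_median_of_four_deaths(self):
        curve = km_estimate(deaths_frame([1, 2, 3, 4]))
        est = percentile(curve, 0.5)
        assert est.day == 2
        assert est.ci_low <= est.day <= est.ci_high

    def test_unreached_level_flagged(self):
        # S_min = 0.25: the 10% percentile is undefined, never imputed
        df = deaths_frame([1, 2, 3, 4], dead=[1, 1, 1, 0],
                          censored=[0, 0, 0, 1])
        est = percentile(km_estimate(df), 0.1)
        assert not est.defined
        assert est.day is None

    def test_exponential_median_covered_by_ci(self):
        a = 0.05
        rng = np.random.default_rng(8)
        t = gompertz_lifespans(a, 0.0, 2000, rng)
        curve = km_estimate(deaths_frame(list(t)))
        est = percentile(curve, 0.5)
        true_median = np.log(2) / a
        assert est.ci_low <= true_median <= est.ci_high

    def test_monotone_in_level(self):
        rng = np.random.default_rng(5)
        curve = km_estimate(deaths_frame(list(rng.integers(1, 50, 300))))
        days = [percentile(curve, lv).day for lv in (0.9, 0.5, 0.1)]
        assert days[0] <= days[1] <= days[2]

    def test_bad_level_rejected(self):
        curve = km_estimate(deaths_frame([1, 2]))
        with pytest.raises(ValueError):
            percentile(curve, 1.5)


class TestLogRank:
    def test_identical_groups_null(self):
        df = deaths_frame([2, 4, 6, 9], dead=[3, 2, 4, 1])
        res = logrank({"a": df, "b": df.copy()})
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_four_groups_three_df(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": deaths_frame(list(rng.integers(1, 30, 40)))
                  for i in range(4)}
        assert logrank(groups).df == 3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank({"a": deaths_frame([1, 2])})

    def test_matches_lifelines_statistic(self):
        from lifelines.statistics import multivariate_logrank_test
        rng = np.random.default_rng(4)
        groups, durs, labs, obs = {}, [], [], []
        for g in ("A", "B", "C"):
            t = rng.integers(1, 20, size=50)
            dead = rng.uniform(size=50) > 0.15
            groups[g] = deaths_frame(list(t), dead=list(dead.astype(int)),
                                     censored=list((~dead).astype(int)))
            durs += list(t)
            labs += [g] * 50
            obs += list(dead.astype(int))
        res = logrank(groups)
        ref = multivariate_logrank_test(durs, labs, obs)
        assert res.chi2 == pytest.approx(ref.test_statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.p_value, abs=1e-9)

    def test_p_close_to_permutation_null(self):
        # two small uncensored groups against a permutation oracle
        rng = np.random.default_rng(12)
        ta = np.array([3.0, 5, 7, 9, 12, 15, 18, 30])
        tb = np.array([2.0, 4, 6, 8, 10, 11, 13, 14])
        obs = logrank({"a": deaths_frame(list(ta)),
                       "b": deaths_frame(list(tb))}).chi2
        pooled = np.concatenate([ta, tb])
        n_reps = 2000
        count = 0
        for _ in range(n_reps):
            perm = rng.permutation(pooled)
            chi2 = logrank({"a": deaths_frame(list(perm[:8])),
                            "b": deaths_frame(list(perm[8:]))}).chi2
            if chi2 >= obs:
                count += 1
        p_perm = count / n_reps
        p_chi2 = logrank({"a": deaths_frame(list(ta)),
                          "b": deaths_frame(list(tb))}).p
        # chi-square approximation vs Monte-Carlo reference
        mc_se = np.sqrt(p_perm * (1 - p_perm) / n_reps)
        assert abs(p_chi2 - p_perm) < 0.03 + 3 * mc_se


class TestPairwiseBH:
    def test_single_pair_adjusted_equals_raw(self):
        rng = np.random.default_rng(1)
        groups = {"a": deaths_frame(list(rng.integers(1, 20, 30))),
                  "b": deaths_frame(list(rng.integers(5, 30, 30)))}
        out = pairwise_logrank_bh(groups)
        assert len(out) == 1
        assert out["p_adj"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_adjustment_matches_hand_bh(self):
        # independent step-up oracle on the raw p-values
        rng = np.random.default_rng(9)
        groups = {g: deaths_frame(list(rng.integers(1, 20 + 5 * i, 30)))
                  for i, g in enumerate("abcd")}
        out = pairwise_logrank_bh(groups)
        raw = out["p_raw"].to_numpy()
        m = len(raw)
        order = np.argsort(raw)
        hand = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, raw[i] * m / (rank + 1))
            hand[i] = running
        assert np.allclose(out["p_adj"], np.maximum(hand, raw))

    def test_eight_groups_give_28_comparisons(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": deaths_frame(list(rng.integers(1, 25, 25)))
                  for i in range(8)}
        assert len(pairwise_logrank_bh(groups)) == 28

    def test_adjusted_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": deaths_frame(list(rng.integers(1, 20 + 4 * i, 30)))
                  for i in range(5)}
        out = pairwise_logrank_bh(groups).sort_values("p_raw")
        assert (out["p_adj"].to_numpy() >= out["p_raw"].to_numpy()).all()
        assert (np.diff(out["p_adj"].to_numpy()) >= -1e-15).all()


def test_survival_summary_shape(small_study):
    deaths, _, _, _ = small_study
    out = survival.survival_summary(deaths, by=("regime", "sex"),
                                    levels=(0.9, 0.5, 0.1))
    assert len(out) == 8 * 3
    assert set(out.columns) >= {"group", "level", "day", "ci_low", "ci_high"}
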