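import numpy as np
import pandas as pd
import pytest

from stann import evaluation as ev


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestStratifiedSplits:
    def test_small_cohort_geometry(self):
        y = np.zeros(100, int)
        y[:10] = 1
        plan = ev.BootstrapPlan(n_rounds=5, seed=0)
        for train, test in ev.stratified_splits(y, plan):
            assert len(test) == 20 and y[test].sum() == 2
            assert len(train) == 80 and y[train].sum() == 8
            assert len(np.intersect1d(train, test)) == 0

    def test_reference_cohort_train_size(self):
        y = np.zeros(4395, int)
        y[:149] = 1
        plan = ev.BootstrapPlan(n_rounds=3, seed=1)
        for train, _ in ev.stratified_splits(y, plan):
            assert len(train) == 3516

    def test_master_seed_reproducible(self):
        y = (np.random.default_rng(0).uniform(size=300) < 0.1).astype(int)
        plan = ev.BootstrapPlan(n_rounds=4, seed=9)
        s1 = ev.stratified_splits(y, plan)
        s2 = ev.stratified_splits(y, plan)
        for (a, b), (c, d) in zip(s1, s2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_stratification_invariant(self):
        rng = np.random.default_rng(4)
        y = (rng.uniform(size=500) < 0.05).astype(int)
        plan = ev.BootstrapPlan(n_rounds=20, seed=2)
        rate = y.mean()
        for _, test in ev.stratified_splits(y, plan):
            assert abs(y[test].mean() - rate) < 1.0 / len(test)

    def test_degenerate_cohorts_rejected(self):
        with pytest.raises(ValueError):
            ev.stratified_splits(np.zeros(10, int), ev.BootstrapPlan(n_rounds=1))
        with pytest.raises(ValueError):
            y = np.zeros(10, int)
            y[0] = 1
            ev.stratified_splits(y, ev.BootstrapPlan(n_rounds=1))


class TestAuc:
    def test_worked_example(self):
        assert ev.auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_perfect_ranking(self):
        assert ev.auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert ev.auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            ev.auc([1, 2], [1, 1])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(4, 30)
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert ev.auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )


class TestHanleyMcNeil:
    def test_half_with_ten_per_class(self):
        se, lo, hi = ev.hanley_mcneil_ci(0.5, 10, 10)
        assert se == pytest.approx(np.sqrt(0.0175), abs=1e-12)
        assert lo == pytest.approx(0.5 - 1.96 * se, abs=1e-12)
        assert hi == pytest.approx(0.5 + 1.96 * se, abs=1e-12)

    def test_degenerate_perfect_auc(self):
        se, lo, hi = ev.hanley_mcneil_ci(1.0, 5, 5)
        assert se == 0.0 and (lo, hi) == (1.0, 1.0)

    def test_se_monotone_in_n(self):
        ses = [ev.hanley_mcneil_ci(0.7, n, n)[0] for n in (10, 100, 1000)]
        assert ses[0] > ses[1] > ses[2]

    def test_symmetric_before_clipping(self):
        se, lo, hi = ev.hanley_mcneil_ci(0.6, 30, 200)
        assert (0.6 - lo) == pytest.approx(hi - 0.6, abs=1e-12)


class TestDichotomize:
    def test_quartile_cutoff_interpolated(self):
        flags, cut = ev.dichotomize_upper_quartile(np.arange(1.0, 9.0))
        assert cut == pytest.approx(6.25)
        np.testing.assert_array_equal(flags, [0, 0, 0, 0, 0, 0, 1, 1])

    def test_external_cutoff_truncated_one_sig_digit(self):
        _, cut = ev.dichotomize_upper_quartile(np.arange(4.0), external_cutoff=0.2736)
        assert cut == pytest.approx(0.2)

    def test_leading_zero_truncation(self):
        _, cut = ev.dichotomize_upper_quartile(np.arange(4.0), external_cutoff=0.0734)
        assert cut == pytest.approx(0.07)

    def test_ties_go_low_risk(self):
        flags, cut = ev.dichotomize_upper_quartile(np.array([1.0, 1, 1, 1]))
        assert flags.sum() == 0

    def test_truncate_sig_values(self):
        assert ev.truncate_sig(0.2736) == pytest.approx(0.2)
        assert ev.truncate_sig(0.0734) == pytest.approx(0.07)
        assert ev.truncate_sig(273.6) == pytest.approx(200.0)
        assert ev.truncate_sig(-0.27) == pytest.approx(-0.2)


class TestCox:
    def test_identical_groups_hr_one(self):
        t = np.tile([50.0, 120, 200, 365, 365, 365], 2)
        e = np.tile([1, 1, 1, 0, 0, 0], 2)
        g = np.repeat([0, 1], 6)
        hr, lo, hi = ev.cox_hr(g, t, e, horizon_days=365)
        assert hr == pytest.approx(1.0, abs=1e-6)

    def test_event_after_horizon_censored(self):
        t = np.array([400.0, 100, 50, 300, 365, 20, 200, 80])
        e = np.array([1, 1, 1, 0, 0, 1, 1, 0])
        g = np.array([1, 1, 0, 0, 1, 0, 1, 0])
        hr365, _, _ = ev.cox_hr(g, t, e, horizon_days=365)
        t2 = t.copy()
        t2[0] = 365.0
        e2 = e.copy()
        e2[0] = 0
        hr_censored, _, _ = ev.cox_hr(g, t2, e2, horizon_days=365)
        assert hr365 == pytest.approx(hr_censored, rel=1e-9)

    def test_simulation_recovery(self):
        # exponential two-group simulation, true rate ratio 3
        rng = np.random.default_rng(1)
        estimates, covered = [], 0
        reps = 40
        for _ in range(reps):
            n = 2000
            g = (rng.uniform(size=n) < 0.25).astype(int)
            lam = 0.0004 * 3.0**g
            t = rng.exponential(1 / lam)
            e = (t <= 365).astype(int)
            t = np.minimum(t, 365)
            hr, lo, hi = ev.cox_hr(g, t, e, horizon_days=365)
            estimates.append(hr)
            covered += lo <= 3.0 <= hi
        assert 2.4 < np.median(estimates) < 3.7
        assert covered / reps >= 0.9

    def test_no_events_in_group_eliminates_round(self):
        t = np.array([10.0, 20, 30, 40])
        e = np.array([1, 1, 0, 0])
        g = np.array([0, 0, 1, 1])
        with pytest.raises(ev.RoundEliminated):
            ev.cox_hr(g, t, e, horizon_days=365)


class TestNri:
    def test_worked_example(self):
        counts = ev.ReclassificationCounts(4, 2, 1, 10, 1, 3)
        assert ev.nri(counts) == pytest.approx(0.45)

    def test_no_reclassification_zero(self):
        counts = ev.ReclassificationCounts(5, 0, 0, 5, 0, 0)
        assert ev.nri(counts) == 0.0

    def test_maximum_two(self):
        counts = ev.ReclassificationCounts(4, 4, 0, 6, 0, 6)
        assert ev.nri(counts) == pytest.approx(2.0)

    def test_bounds_and_null_mean(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(300):
            y = rng.integers(0, 2, 60)
            if y.sum() in (0, 60):
                continue
            old = rng.normal(size=60)
            new = rng.normal(size=60)  # label-independent reclassification
            counts = ev.counts_from_scores(old, new, y)
            v = ev.nri(counts)
            assert -2.0 <= v <= 2.0
            vals.append(v)
        assert abs(np.mean(vals)) < 0.05

    def test_counts_from_classes(self):
        old = np.array([0, 0, 1, 1, 0])
        new = np.array([1, 0, 0, 1, 1])
        y = np.array([1, 1, 0, 0, 0])
        c = ev.counts_from_classes(old, new, y)
        assert (c.events_up, c.events_down) == (1, 0)
        assert (c.nonevents_up, c.nonevents_down) == (1, 1)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            ev.ReclassificationCounts(2, 2, 1, 5, 0, 0)


class TestKmCurve:
    def test_no_events_survival_one(self):
        out = ev.km_curve(np.array([10.0, 20, 30]), np.zeros(3, int), np.zeros(3))
        assert np.all(out["survival"] == 1.0)

    def test_hand_product_limit(self):
        t = np.array([1.0, 2.0, 50.0, 50.0])
        e = np.array([1, 1, 0, 0])
        out = ev.km_curve(t, e, np.zeros(4), horizon_days=60)
        s = out.set_index("time")["survival"]
        assert s.loc[1.0] == pytest.approx(0.75)
        assert s.loc[2.0] == pytest.approx(0.5)

    def test_all_events_at_zero(self):
        out = ev.km_curve(np.zeros(4), np.ones(4, int), np.zeros(4))
        assert out["survival"].iloc[-1] == pytest.approx(0.0)

    def test_at_risk_counts_by_group(self):
        t = np.array([10.0, 70.0, 30.0, 70.0])
        e = np.array([1, 0, 1, 0])
        g = np.array(["hi", "hi", "lo", "lo"])
        out = ev.km_curve(t, e, g, horizon_days=60, tick_times=(0, 20, 40, 60))
        ticks = out.attrs["tick_at_risk"]
        assert ticks["hi"][0] == 2 and ticks["hi"][20] == 1


class TestPairedCompare:
    def test_identical_vectors_p_one(self):
        a = np.arange(10.0)
        assert ev.paired_compare(a, a.copy()) == 1.0

    def test_constant_shift_tiny_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=1000)
        assert ev.paired_compare(a, a + 0.05) < 1e-10

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            ev.paired_compare(rng.normal(size=200), rng.normal(size=200)) < 0.05
            for _ in range(200)
        )
        assert 0.01 < rejections / 200 < 0.11

    def test_zero_variance_nonzero_difference(self):
        with pytest.warns(UserWarning):
            p = ev.paired_compare(np.ones(5), np.full(5, 2.0))
        assert p == 0.0


class TestRunBenchmark:
    def test_zero_rounds_empty_result(self, small_cohort):
        plan = ev.BootstrapPlan(n_rounds=0, seed=0)
        res = ev.run_benchmark(
            small_cohort["history"],
            small_cohort["y"],
            small_cohort["time_days"],
            plan,
            st_feats=small_cohort["features"],
            model_names=("lr_hx",),
            compute_hr=False,
        )
        assert res.per_round.empty and res.summary == {}

    def test_determinism(self, small_cohort):
        plan = ev.BootstrapPlan(n_rounds=2, seed=3)
        kwargs = dict(
            st_feats=small_cohort["features"],
            windows=small_cohort["windows"],
            model_names=("lr_hx", "ann"),
            compute_hr=False,
        )
        r1 = ev.run_benchmark(
            small_cohort["history"], small_cohort["y"], small_cohort["time_days"], plan, **kwargs
        )
        r2 = ev.run_benchmark(
            small_cohort["history"], small_cohort["y"], small_cohort["time_days"], plan, **kwargs
        )
        pd.testing.assert_frame_equal(r1.per_round, r2.per_round)
        assert r1.summary == r2.summary

    def test_hr_columns_present_with_elimination_flags(self, small_cohort):
        plan = ev.BootstrapPlan(n_rounds=2, seed=1)
        res = ev.run_benchmark(
            small_cohort["history"],
            small_cohort["y"],
            small_cohort["time_days"],
            plan,
            st_feats=small_cohort["features"],
            model_names=("lr_hx_st",),
            horizons=(365, 14),
            compute_hr=True,
        )
        assert {"hr_365", "hr_14", "hr_365_eliminated"} <= set(res.per_round.columns)
        assert "hr_365" in res.summary["lr_hx_st"]

    def test_trs_model_requires_column(self, small_cohort):
        plan = ev.BootstrapPlan(n_rounds=1, seed=1)
        with pytest.raises(ValueError, match="TRS"):
            ev.run_benchmark(
                small_cohort["history"],
                small_cohort["y"],
                small_cohort["time_days"],
                plan,
                model_names=("trs",),
                compute_hr=False,
            )
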