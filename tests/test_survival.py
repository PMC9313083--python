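"""Kaplan–Meier product-limit, log-rank (vs hand table, permutation and
lifelines), and expression dichotomization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from degnet import dichotomize, km_estimate, logrank_test, screen_gene, screen_genes


class TestKMEstimate:
    def test_all_censored_stays_at_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(10.0) == 1.0

    def test_single_event_among_four(self):
        curve = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0])
        assert curve.survival_at(1.0) == pytest.approx(0.75)

    def test_hand_product_limit_with_censoring(self):
        # event t=1 (4 at risk), censored t=1.5, event t=2 (2 at risk), censored t=3
        curve = km_estimate([1.0, 1.5, 2.0, 3.0], [1, 0, 1, 0])
        assert curve.survival_at(1.0) == pytest.approx(0.75)
        assert curve.survival_at(2.0) == pytest.approx(0.375)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10.0, size=50)
        curve = km_estimate(times, np.ones(50, dtype=int))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            # S(t) = fraction with time > t when nothing is censored
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_event_before_censoring_at_tied_time(self):
        # the tied censored subject is still at risk when the event occurs
        curve = km_estimate([2.0, 2.0, 5.0], [1, 0, 0])
        assert curve.survival_at(2.0) == pytest.approx(2 / 3)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        times = rng.exponential(10, size=40)
        events = rng.integers(0, 2, size=40)
        events[0] = 1
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        curve = km_estimate(times, events)
        for t in curve.event_times:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10)


def hand_logrank(times_a, events_a, times_b, events_b):
    """Independent O/E/V tabulation over pooled event times."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a), np.asarray(events_b)
    ts = sorted(set(np.concatenate([times_a[events_a == 1],
                                    times_b[events_b == 1]])))
    O = E = V = 0.0
    for t in ts:
        na = (times_a >= t).sum()
        nb = (times_b >= t).sum()
        da = ((times_a == t) & (events_a == 1)).sum()
        db = ((times_b == t) & (events_b == 1)).sum()
        n, d = na + nb, da + db
        O += da
        E += d * na / n
        if n > 1:
            V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return chi2, float(stats.chi2.sf(chi2, 1))


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_table(self):
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
        tb, eb = [2.0, 4.0, 6.0], [1, 0, 1]
        res = logrank_test(ta, ea, tb, eb)
        chi2, p = hand_logrank(ta, ea, tb, eb)
        assert res.chi2 == pytest.approx(chi2, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_hand_table_random(self, rng):
        for _ in range(20):
            ta = rng.exponential(5, size=8)
            tb = rng.exponential(9, size=10)
            ea = rng.integers(0, 2, size=8)
            eb = rng.integers(0, 2, size=10)
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank_test(ta, ea, tb, eb)
            if res.degenerate:
                continue
            chi2, p = hand_logrank(ta, ea, tb, eb)
            assert res.chi2 == pytest.approx(chi2, abs=1e-10)

    def test_matches_lifelines(self, rng):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        ta = rng.exponential(5, size=15)
        tb = rng.exponential(12, size=15)
        ea = np.ones(15, dtype=int)
        eb = rng.integers(0, 2, size=15)
        res = logrank_test(ta, ea, tb, eb)
        ref = lifelines_stats.logrank_test(ta, tb, event_observed_A=ea,
                                           event_observed_B=eb)
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-8)

    def test_label_swap_symmetry(self, rng):
        ta = rng.exponential(5, size=10)
        tb = rng.exponential(10, size=12)
        ea = np.ones(10, dtype=int)
        eb = np.ones(12, dtype=int)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.chi2 == pytest.approx(r2.chi2, abs=1e-12)
        assert r1.hazard_ratio == pytest.approx(1.0 / r2.hazard_ratio, rel=1e-10)

    def test_p_close_to_permutation_p(self, rng):
        # chi-square p vs a label-permutation reference on 20 subjects
        times = rng.exponential(5, size=20)
        events = rng.integers(0, 2, size=20)
        events[:4] = 1
        labels = np.array([True] * 10 + [False] * 10)
        obs = logrank_test(times[labels], events[labels],
                           times[~labels], events[~labels]).chi2
        n_perm, hits = 2000, 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            chi2 = logrank_test(times[perm], events[perm],
                                times[~perm], events[~perm]).chi2
            hits += chi2 >= obs - 1e-12
        p_perm = hits / n_perm
        p_asym = float(stats.chi2.sf(obs, 1))
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-4
        assert abs(p_asym - p_perm) <= 4 * se + 0.03

    def test_null_rejection_rate_calibrated(self, rng):
        n_reps, rejections = 1000, 0
        for _ in range(n_reps):
            times = rng.exponential(5, size=30)
            events = (rng.uniform(size=30) > 0.3).astype(int)
            if events[:15].sum() + events[15:].sum() == 0:
                continue
            res = logrank_test(times[:15], events[:15], times[15:], events[15:])
            rejections += (not res.degenerate) and res.p_value <= 0.05
        rate = rejections / n_reps
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) <= 3 * se

    def test_power_against_strong_effect(self, rng):
        # hazard ratio 3 between groups of 50: near-certain detection
        n_reps, rejections = 200, 0
        for _ in range(n_reps):
            ta = rng.exponential(1.0, size=50)   # high hazard
            tb = rng.exponential(3.0, size=50)
            res = logrank_test(ta, np.ones(50, int), tb, np.ones(50, int))
            rejections += res.p_value <= 0.05
        assert rejections / n_reps >= 0.9


class TestDichotomize:
    def test_median_split(self):
        high, cutoff = dichotomize([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(high, [False, False, True, True])
        assert cutoff == pytest.approx(2.5)

    def test_ties_go_low(self):
        high, _ = dichotomize([1.0, 2.0, 2.0, 3.0])
        # median is 2.0; the tied values are in the low group
        np.testing.assert_array_equal(high, [False, False, False, True])

    def test_constant_expression_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dichotomize([2.0, 2.0, 2.0, 2.0])

    def test_best_cutoff_matches_exhaustive_scan(self, rng):
        times = rng.exponential(5, size=24)
        events = np.ones(24, dtype=int)
        expr = rng.normal(size=24)
        res = screen_gene(times, events, expr, mode="best_cutoff")
        assert res.cutoff_optimized
        lo, hi = np.quantile(expr, [0.25, 0.75])
        best = -1.0
        for cut in np.unique(expr[(expr >= lo) & (expr <= hi)]):
            high = expr > cut
            if 0 < high.sum() < 24:
                best = max(best, logrank_test(times[high], events[high],
                                              times[~high], events[~high]).chi2)
        assert res.chi2 == pytest.approx(best, abs=1e-12)


class TestScreenGenes:
    def test_wide_table_screen(self, rng):
        n = 60
        expr = rng.normal(size=n)
        # strong effect: high expression doubles the hazard
        times = rng.exponential(np.where(expr > np.median(expr), 1.0, 4.0))
        df = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                           "time": times, "event": 1,
                           "RISK": expr, "NULL": rng.normal(size=n)})
        res = screen_genes(df, ["RISK", "NULL"])
        assert res.loc["RISK", "p_value"] < 0.01
        assert res.loc["RISK", "hazard_ratio"] > 1.0
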