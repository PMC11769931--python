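"""IPCW concordance, censoring KM, bootstrap, Welch, Brier, calibration."""

import numpy as np
import pytest

from daptsurv import (
    bootstrap_ci,
    brier_score,
    calibration_curve,
    censoring_survival,
    ctd_index,
    evaluate_predictions,
    welch_t,
)
from daptsurv.evaluation import G_FLOOR, evaluable_labels


def brute_force_ctd(r, t, d, tau, g_floor=G_FLOOR):
    """Exhaustive double loop over all ordered pairs with explicit weights."""
    G = censoring_survival(t, d)
    num = den = 0.0
    for i in range(len(t)):
        if d[i] != 1 or t[i] > tau:
            continue
        w = 1.0 / max(G(t[i], left_limit=True), g_floor) ** 2
        for j in range(len(t)):
            if t[i] < t[j]:
                den += w
                if r[i] > r[j]:
                    num += w
                elif r[i] == r[j]:
                    num += 0.5 * w
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


class TestCensoringSurvival:
    def test_no_censoring_gives_identity(self):
        t = np.array([3.0, 5.0, 9.0])
        G = censoring_survival(t, np.array([1, 1, 1]))
        assert G(0.0) == 1.0
        assert G(8.9) == 1.0

    def test_single_censored_subject_drops_to_zero(self):
        G = censoring_survival(np.array([10.0]), np.array([0]))
        assert G(9.99) == 1.0
        assert G(10.0) == 0.0
        assert G(10.0, left_limit=True) == 1.0

    def test_eight_subject_fixture_matches_product_limit_table(self):
        """Hand-computed product-limit over censorings (events flip roles)."""
        t = np.array([2.0, 3.0, 3.0, 5.0, 6.0, 8.0, 9.0, 11.0])
        d = np.array([1,   0,   1,   0,   1,   0,   1,   1])
        G = censoring_survival(t, d)
        # censorings at 3 (7 at risk), 5 (5 at risk), 8 (3 at risk)
        g3 = 1 - 1 / 7
        g5 = g3 * (1 - 1 / 5)
        g8 = g5 * (1 - 1 / 3)
        assert G(3.0) == pytest.approx(g3, abs=1e-12)
        assert G(5.5) == pytest.approx(g5, abs=1e-12)
        assert G(10.0) == pytest.approx(g8, abs=1e-12)

    def test_matches_lifelines_km_of_censoring_distribution(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(0)
        t = rng.uniform(1, 50, 200)
        d = rng.integers(0, 2, 200)
        G = censoring_survival(t, d)
        km = lifelines.KaplanMeierFitter().fit(t, 1 - d)
        for q in np.linspace(1, 49, 20):
            assert G(q) == pytest.approx(
                float(km.survival_function_at_times(q).iloc[0]), abs=1e-10
            )

    def test_nonincreasing_step_function(self):
        rng = np.random.default_rng(1)
        G = censoring_survival(rng.uniform(1, 30, 50), rng.integers(0, 2, 50))
        vals = G(np.linspace(0, 35, 100))
        assert np.all(np.diff(vals) <= 0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            censoring_survival(np.array([]), np.array([]))


class TestCtdIndex:
    def test_perfect_ranking_uncensored_gives_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        d = np.ones(5, dtype=int)
        risk = -t  # earlier event = higher risk
        assert ctd_index(risk, t, d, tau=5.0) == 1.0

    def test_reversed_ranking_gives_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        d = np.ones(5, dtype=int)
        assert ctd_index(t, t, d, tau=5.0) == 0.0

    def test_constant_scores_give_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert ctd_index(np.zeros(4), t, np.ones(4, dtype=int), tau=4.0) == 0.5

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            ctd_index(np.array([1.0, 2.0]), np.array([5.0, 5.0]),
                      np.array([0, 0]), tau=5.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_pair_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 100))
        t = rng.uniform(1, 100, n)
        d = rng.integers(0, 2, n)
        if d.sum() == 0:
            d[0] = 1
        r = rng.normal(size=n)
        tau = float(np.percentile(t, 75))
        assert ctd_index(r, t, d, tau) == pytest.approx(
            brute_force_ctd(r, t, d, tau), abs=1e-12
        )

    def test_reversing_scores_complements_index_when_uncensored(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(1, 50, 40)
        d = np.ones(40, dtype=int)
        r = rng.normal(size=40)
        c = ctd_index(r, t, d, tau=50.0)
        assert ctd_index(-r, t, d, tau=50.0) == pytest.approx(1 - c, abs=1e-12)

    def test_reduces_to_harrell_without_censoring(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(4)
        t = rng.uniform(1, 100, 60)
        r = rng.normal(size=60)
        mine = ctd_index(r, t, np.ones(60, dtype=int), tau=float(t.max()))
        harrell = 1 - concordance_index(t, r)
        assert mine == pytest.approx(harrell, abs=1e-12)

    def test_matches_uno_estimator_under_censoring(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(5)
        n = 120
        t = rng.uniform(1, 100, n)
        d = rng.integers(0, 2, n)
        r = rng.normal(size=n)
        y = np.array([(bool(dd), tt) for dd, tt in zip(d, t)],
                     dtype=[("event", bool), ("time", float)])
        tau = float(np.percentile(t, 80))
        uno = sksurv_metrics.concordance_index_ipcw(y, y, r, tau=tau)[0]
        assert ctd_index(r, t, d, tau) == pytest.approx(uno, abs=1e-10)


class TestBootstrap:
    def test_constant_metric_degenerate_ci(self):
        lo, hi, vals = bootstrap_ci(lambda x: 7.0, np.arange(50.0), trials=100, seed=0)
        assert lo == hi == 7.0

    def test_exactly_500_trial_values(self):
        _, _, vals = bootstrap_ci(np.mean, np.arange(30.0), trials=500, seed=1)
        assert len(vals) == 500

    def test_percentiles_match_sort_and_index(self):
        _, _, vals = bootstrap_ci(np.mean, np.random.default_rng(2).normal(size=40),
                                  trials=500, seed=3)
        lo, hi, _ = bootstrap_ci(np.mean, np.random.default_rng(2).normal(size=40),
                                 trials=500, seed=3)
        assert lo == pytest.approx(float(np.percentile(vals, 2.5)), abs=1e-12)
        assert hi == pytest.approx(float(np.percentile(vals, 97.5)), abs=1e-12)

    def test_failed_trials_skipped_and_counted(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise ValueError("no comparable pairs")
            return float(np.mean(x))

        lo, hi, vals = bootstrap_ci(flaky, np.arange(20.0), trials=30, seed=4)
        assert np.isnan(vals).sum() == 10
        assert lo <= hi

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, np.array([]), trials=10, seed=0)


class TestWelchT:
    def test_identical_samples(self):
        stat, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == 0.0
        assert p == 1.0

    def test_textbook_example(self):
        """a=(1,2,3), b=(1,2,3,4,5,6): t = -1.5/sqrt(1/3 + 3.5/6), Welch df."""
        stat, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        expected_t = -1.5 / np.sqrt(1 / 3 + 3.5 / 6)
        assert stat == pytest.approx(expected_t, abs=1e-10)
        from scipy import stats as sps

        se2_a, se2_b = 1 / 3, 3.5 / 6
        df = (se2_a + se2_b) ** 2 / (se2_a ** 2 / 2 + se2_b ** 2 / 5)
        expected_p = 2 * sps.t.sf(abs(expected_t), df)
        assert p == pytest.approx(expected_p, abs=1e-10)

    def test_swapping_samples_negates_t_preserves_p(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 2, 20)
        t1, p1 = welch_t(a, b)
        t2, p2 = welch_t(b, a)
        assert t2 == pytest.approx(-t1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_degenerate_equal_means_convention(self):
        stat, p = welch_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (stat, p) == (0.0, 1.0)

    def test_too_small_sample_raises(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestBrier:
    def test_perfect_predictions_score_zero(self):
        assert brier_score(np.array([0.0, 1.0, 1.0]), np.array([0, 1, 1])) == 0.0

    def test_constant_half_scores_quarter(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 50)
        assert brier_score(np.full(50, 0.5), y) == 0.25

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 30)
        y = rng.integers(0, 2, 30)
        assert brier_score(p, y) == pytest.approx(
            float(np.mean((p - y) ** 2)), abs=1e-12
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            brier_score(np.array([]), np.array([]))

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            brier_score(np.array([1.2]), np.array([1]))


class TestEvaluableLabels:
    def test_event_censored_and_beyond_horizon(self):
        t = np.array([100.0, 200.0, 400.0, 365.0])
        d = np.array([1, 0, 0, 1])
        mask, y = evaluable_labels(t, d, 365.0)
        # censored at 200 < 365 is excluded; event at 365 counts (<=)
        np.testing.assert_array_equal(mask, [True, False, True, True])
        np.testing.assert_array_equal(y, [1.0, 0.0, 1.0])


class TestCalibration:
    def test_degenerate_single_bin(self):
        cal = calibration_curve(np.full(20, 0.05), np.zeros(20), bins=10)
        assert cal["count"][0] == 20
        assert cal["observed_fraction"][0] == 0.0
        assert np.isnan(cal["observed_fraction"][3])

    def test_bin_counts_partition_n(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 500)
        cal = calibration_curve(p, rng.integers(0, 2, 500), bins=10)
        assert cal["count"].sum() == 500

    def test_calibrated_bernoulli_draws_within_binomial_bands(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 20_000)
        y = rng.binomial(1, p)
        cal = calibration_curve(p, y, bins=10)
        for k in range(10):
            n_k = cal["count"][k]
            mean_p = cal["mean_predicted"][k]
            sd = np.sqrt(mean_p * (1 - mean_p) / n_k)
            assert abs(cal["observed_fraction"][k] - mean_p) < 3 * sd

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve(np.array([0.5]), np.array([1]), bins=1)


class TestEvaluateReport:
    def test_report_fields_and_ci_ordering(self):
        rng = np.random.default_rng(11)
        n = 150
        t = rng.uniform(9, 400, n)
        d = rng.integers(0, 2, n)
        risks = np.sort(rng.uniform(0, 1, (n, 2)), axis=1)
        report = evaluate_predictions(risks, t, d, horizons=[180.0, 365.0],
                                      seed=0, bootstrap_trials=50)
        for tau in (180.0, 365.0):
            lo, hi = report.ctd_ci[tau]
            assert lo <= hi
            assert 0.0 <= report.ctd[tau] <= 1.0
        assert report.brier is not None
        assert report.n_evaluable + report.n_excluded_censored == n
        d_json = report.to_dict()
        assert set(d_json["ctd"]) == {"180", "365"}
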