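import numpy as np
import pandas as pd
import pytest

from dtbc.bud_counting import regions_from_areas, sweep_bud_definitions
from dtbc.survival_analysis import (
    assign_tertiles,
    budsize_prognosis_sweep,
    cox_fit,
    cox_forward,
    kaplan_meier,
    logrank,
)


class TestTertiles:
    def test_one_to_nine(self):
        labels = assign_tertiles(np.arange(1, 10))
        np.testing.assert_array_equal(labels, [1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_ties_share_a_tertile(self):
        values = np.array([0, 1, 2, 2, 2, 2, 2, 5, 9])
        labels = assign_tertiles(values)
        assert len(set(labels[values == 2])) == 1

    def test_group_sizes_near_thirds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 50, size=90).astype(float)
            labels = assign_tertiles(x)
            q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
            ties = max(np.sum(x == q1), np.sum(x == q2), 1)
            for g in (1, 2, 3):
                assert abs(np.sum(labels == g) - 30) <= ties

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            assign_tertiles(np.array([1.0, 1.0, 2.0, 2.0]))


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(2.0, 100)
        curves = kaplan_meier(t, np.ones(100, int))
        c = curves["all"]
        for tau in (0.5, 1.0, 2.0):
            assert c.survival_at(tau) == pytest.approx(np.mean(t > tau))

    def test_all_censored_flat_at_one(self):
        c = kaplan_meier(np.arange(1.0, 6.0), np.zeros(5, int))["all"]
        assert (c.survival == 1.0).all()

    def test_hand_computed_six_patient_table(self):
        t = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 0, 1, 0, 1])
        c = kaplan_meier(t, e)["all"]
        assert c.survival_at(1.0) == pytest.approx(5 / 6)
        assert c.survival_at(2.0) == pytest.approx(5 / 6 * 4 / 5)
        assert c.survival_at(3.0) == pytest.approx(5 / 6 * 4 / 5 * 2 / 3)
        assert c.survival_at(5.0) == pytest.approx(0.0)
        assert c.at_risk == {0.0: 6, 1.0: 6, 3.0: 3, 5.0: 1}

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier(np.array([-1.0]), np.array([1]))


class TestLogrank:
    def test_duplicated_sample_gives_zero_statistic(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, 50)
        e = rng.integers(0, 2, 50)
        tt = np.concatenate([t, t])
        ee = np.concatenate([e, e])
        g = np.repeat([0, 1], 50)
        chi2, df, p = logrank(tt, ee, g)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 1

    def test_power_under_strong_hazard_ratio(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 40
        for _ in range(reps):
            g = np.repeat([0, 1], 150)
            rate = np.where(g == 0, 1.0, 3.0)
            t = rng.exponential(1.0 / rate)
            _, _, p = logrank(t, np.ones(300, int), g)
            hits += p < 0.01
        assert hits >= int(0.9 * reps)

    def test_single_group_and_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank(np.ones(5), np.ones(5, int), np.zeros(5))
        with pytest.raises(ValueError):
            logrank(np.ones(6), np.zeros(6, int), np.repeat([0, 1], 3))


def _exp_cohort(n, loghr, seed, censor=8.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.2 * np.exp(loghr * x)))
    c = rng.uniform(0, censor, n)
    return pd.DataFrame(
        {"os_time": np.minimum(t, c), "os_event": (t <= c).astype(int), "x": x}
    )


class TestCoxFit:
    def test_recovers_true_hazard_ratio(self):
        df = _exp_cohort(10_000, np.log(2.0), seed=4)
        fit = cox_fit(df, ["x"], "os")
        assert 1.9 <= fit.hazard_ratio("x") <= 2.1

    def test_null_covariate(self):
        df = _exp_cohort(10_000, 0.0, seed=5)
        fit = cox_fit(df, ["x"], "os")
        assert 0.95 <= fit.hazard_ratio("x") <= 1.05
        lo, hi = fit.table.loc["x", ["ci_low", "ci_high"]]
        assert lo <= fit.hazard_ratio("x") <= hi

    def test_loghr_equivariance_under_covariate_scaling(self):
        df = _exp_cohort(500, 0.7, seed=6)
        df["x10"] = 10.0 * df["x"]
        b1 = np.log(cox_fit(df, ["x"], "os").hazard_ratio("x"))
        b10 = np.log(cox_fit(df, ["x10"], "os").hazard_ratio("x10"))
        assert b10 == pytest.approx(b1 / 10.0, rel=1e-6)

    def test_efron_partial_likelihood_grid_oracle(self):
        # one tied event pair; brute-force Efron log PL maximized on a grid
        df = pd.DataFrame(
            {
                "os_time": [1.0, 2.0, 2.0, 3.0, 4.0],
                "os_event": [1, 1, 1, 0, 1],
                "x": [0.5, -0.2, 0.9, 0.0, -1.1],
            }
        )

        def efron_ll(beta):
            t = df["os_time"].to_numpy()
            e = df["os_event"].to_numpy()
            x = df["x"].to_numpy()
            theta = np.exp(beta * x)
            ll = 0.0
            for tau in np.unique(t[e == 1]):
                d = (t == tau) & (e == 1)
                r = t >= tau
                xd, td = x[d], theta[d]
                m = d.sum()
                ll += beta * xd.sum()
                s_r, s_d = theta[r].sum(), td.sum()
                for l in range(m):
                    ll -= np.log(s_r - l / m * s_d)
            return ll

        grid = np.arange(-3.0, 3.0, 1e-3)
        lls = np.array([efron_ll(b) for b in grid])
        beta_oracle = grid[np.argmax(lls)]
        fit = cox_fit(df, ["x"], "os")
        assert np.log(fit.hazard_ratio("x")) == pytest.approx(beta_oracle, abs=2e-3)

    def test_contract_errors(self):
        df = _exp_cohort(100, 0.5, seed=7)
        df["c"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["c"], "os")
        df0 = df.assign(os_event=0)
        with pytest.raises(ValueError, match="event"):
            cox_fit(df0, ["x"], "os")
        with pytest.raises(ValueError):
            cox_fit(df, ["x"], "os", ties="breslow")


def _multi_cohort(n, seed, true_loghr=(0.7, 0.7), n_noise=2):
    rng = np.random.default_rng(seed)
    cols = {}
    lp = np.zeros(n)
    for i, b in enumerate(true_loghr):
        x = rng.normal(size=n)
        cols[f"true{i}"] = x
        lp += b * x
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.2 * np.exp(lp)))
    c = rng.uniform(0, 8, n)
    cols["os_time"] = np.minimum(t, c)
    cols["os_event"] = (t <= c).astype(int)
    return pd.DataFrame(cols)


class TestCoxForward:
    def test_true_predictors_selected(self):
        found = 0
        for seed in range(8):
            df = _multi_cohort(1000, seed=100 + seed)
            fit = cox_forward(df, ["noise0", "true0", "noise1", "true1"], "os")
            assert fit is not None
            found += {"true0", "true1"} <= set(fit.variables)
        assert found >= 7

    def test_all_noise_usually_empty_model(self):
        empty = 0
        reps = 20
        for seed in range(reps):
            df = _multi_cohort(300, seed=200 + seed, true_loghr=(), n_noise=3)
            fit = cox_forward(df, ["noise0", "noise1", "noise2"], "os")
            empty += fit is None
        assert empty / reps >= 0.7  # ~0.95^3 expected under the null

    def test_entry_boundary_single_candidate(self):
        from scipy import stats

        df = _exp_cohort(150, 0.2, seed=9)
        from dtbc.survival_analysis import _null_log_likelihood

        ll1 = cox_fit(df, ["x"], "os").log_likelihood
        ll0 = _null_log_likelihood(df, ["x"], "os")
        p = stats.chi2.sf(2 * (ll1 - ll0), 1)
        assert cox_forward(df, ["x"], "os", entry_p=p * 1.01) is not None
        assert cox_forward(df, ["x"], "os", entry_p=p * 0.99) is None

    def test_order_invariance_with_distinct_pvalues(self):
        df = _multi_cohort(800, seed=10)
        a = cox_forward(df, ["true0", "noise0", "true1", "noise1"], "os")
        b = cox_forward(df, ["noise1", "true1", "noise0", "true0"], "os")
        assert set(a.variables) == set(b.variables)


class TestBudsizeSweep:
    @staticmethod
    def _signal_cohort(n_patients=800, seed=11):
        # hazard driven only by the count of small (sub-950) islands
        rng = np.random.default_rng(seed)
        tables = {}
        small_counts = np.zeros(n_patients)
        for i in range(n_patients):
            areas = rng.uniform(200, 3800, rng.poisson(60))
            tables[f"P{i:04d}"] = regions_from_areas(areas)
            small_counts[i] = np.count_nonzero(areas < 950)
        z = (small_counts - small_counts.mean()) / small_counts.std()
        t = rng.exponential(1.0 / (0.15 * np.exp(0.5 * z)))
        c = rng.uniform(0, 8, n_patients)
        cohort = pd.DataFrame(
            {
                "id": list(tables),
                "os_time": np.minimum(t, c),
                "os_event": (t <= c).astype(int),
            }
        )
        return tables, cohort

    def test_small_island_signal_gives_negative_trend(self):
        tables, cohort = self._signal_cohort()
        sweep = sweep_bud_definitions(tables, range(2, 21))
        res = budsize_prognosis_sweep(sweep, cohort, "os")
        ok = res.table[~res.table["skipped"]]
        assert len(ok) >= 10
        assert res.trend_slope is not None and res.trend_slope < 0
        assert res.trend_p < 0.05

    def test_single_ceiling_row_without_trend(self):
        tables, cohort = self._signal_cohort(n_patients=200, seed=12)
        sweep = sweep_bud_definitions(tables, [5])
        res = budsize_prognosis_sweep(sweep, cohort, "os")
        assert len(res.table) == 1
        assert res.trend_slope is None
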