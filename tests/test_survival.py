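import numpy as np
import pandas as pd
import pytest

import sleeplife as sl
from sleeplife.survival import (
    NoEventsError,
    StepFunction,
    _censoring_km,
    _G_left,
    fit_cox,
    fit_finegray,
    predict_cumhaz,
)

# ---------------------------------------------------------------------------
# printed toy dataset with left truncation, one binary covariate
# (entry, exit, status, x)
# ---------------------------------------------------------------------------
TOY_ROWS = np.array(
    [
        [0.0, 2.0, 1, 1.0],
        [0.5, 3.0, 1, 0.0],
        [0.0, 4.0, 0, 1.0],
        [1.0, 4.5, 1, 0.0],
        [2.5, 5.0, 0, 1.0],
        [0.2, 6.0, 1, 1.0],
    ]
)


def naive_efron_loglik(beta, rows):
    """Independent oracle: direct Efron partial likelihood with delayed
    entry, evaluated for an array of betas by explicit risk-set loops."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll = np.zeros_like(beta)
    event_times = sorted({r[1] for r in rows if r[2] == 1})
    for t in event_times:
        deaths = [r for r in rows if r[2] == 1 and r[1] == t]
        risk = [r for r in rows if r[0] < t <= r[1]]
        d = len(deaths)
        S = sum(np.exp(beta * r[3]) for r in risk)
        SD = sum(np.exp(beta * r[3]) for r in deaths)
        ll += sum(beta * r[3] for r in deaths)
        for l in range(d):
            ll -= np.log(S - (l / d) * SD)
    return ll


def simulate_right_censored(n, beta, seed):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1.0 / np.exp(beta * x))
    c = rng.uniform(0, 2.5, n)
    return np.minimum(t, c), (t <= c).astype(int), x


class TestFitCox:
    def test_grid_search_oracle(self):
        """Newton solution matches brute-force grid maximization of the same
        left-truncated partial likelihood."""
        grid = np.arange(-5.0, 5.0 + 1e-12, 1e-4)
        ll = naive_efron_loglik(grid, TOY_ROWS)
        beta_grid = grid[np.argmax(ll)]
        fit = fit_cox(TOY_ROWS[:, 0], TOY_ROWS[:, 1], TOY_ROWS[:, 2], TOY_ROWS[:, 3:4], names=("x",))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(beta_grid, abs=1e-3)
        # and the implementation's loglik agrees with the oracle's at the optimum
        assert fit.loglik == pytest.approx(naive_efron_loglik(fit.beta[0], TOY_ROWS)[0], abs=1e-8)

    def test_null_effect_recovery(self):
        time, status, x = simulate_right_censored(5000, 0.0, seed=2)
        fit = fit_cox(np.zeros(5000), time, status, x[:, None], names=("x",))
        assert abs(fit.beta[0]) < 3 * fit.se()[0]

    def test_simulation_recovery_transition_one(self):
        """True log-HR 0.5 on transition 1 recovered within 3 SE on
        generate_cohort data, n = 20,000."""
        from conftest import zero_sleep_effects

        effects = zero_sleep_effects()
        effects[1] = {"healthy": 0.0, "intermediate": 0.0, "poor": 0.5}
        truth = sl.SimulationTruth(
            sleep_log_hr=effects,
            covariate_log_hr={},
            sleep_prevalence={
                s: {"healthy": 0.5, "intermediate": 0.0, "poor": 0.5}
                for s in ("female", "male")
            },
            missing_rates={},
            prevalent_cvd_rate=0.0,
            seed=13,
        )
        participants, _ = sl.generate_cohort(truth, 20_000)
        from sleeplife.cohort import build_followup, to_multistate

        fu = build_followup(participants)
        ms = to_multistate(fu, extra_columns=["true_sleep_category"])
        rows = ms[ms["transition"] == 1]
        x = (rows["true_sleep_category"] == "poor").to_numpy(dtype=float)
        fit = fit_cox(rows["entry"], rows["exit"], rows["status"], x[:, None], names=("poor",))
        assert abs(fit.beta[0] - 0.5) < 3 * fit.se()[0]

    def test_matches_lifelines_on_right_censored_data(self):
        lifelines = pytest.importorskip("lifelines")
        time, status, x = simulate_right_censored(2000, 0.7, seed=5)
        fit = fit_cox(np.zeros(2000), time, status, x[:, None], names=("x",))
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"T": time, "E": status, "x": x}), "T", "E"
        )
        assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se()[0] == pytest.approx(cph.standard_errors_["x"], rel=1e-4)

    def test_matches_lifelines_with_heavy_ties(self):
        lifelines = pytest.importorskip("lifelines")
        time, status, x = simulate_right_censored(400, 0.5, seed=6)
        time = np.round(time, 1) + 1e-6  # force many tied event times
        fit = fit_cox(np.zeros(400), time, status, x[:, None], names=("x",))
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"T": time, "E": status, "x": x}), "T", "E"
        )
        assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=1e-5)

    def test_efron_equals_breslow_without_ties(self):
        time, status, x = simulate_right_censored(500, 0.4, seed=7)
        fe = fit_cox(np.zeros(500), time, status, x[:, None], ties="efron")
        fb = fit_cox(np.zeros(500), time, status, x[:, None], ties="breslow")
        assert fe.beta[0] == pytest.approx(fb.beta[0], abs=1e-10)
        assert fe.loglik == pytest.approx(fb.loglik, abs=1e-10)

    def test_location_shift_invariance(self):
        time, status, x = simulate_right_censored(800, 0.6, seed=8)
        f1 = fit_cox(np.zeros(800), time, status, x[:, None], reference=np.array([0.0]))
        f2 = fit_cox(np.zeros(800), time, status, (x + 5.0)[:, None], reference=np.array([5.0]))
        assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-9)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        np.testing.assert_allclose(f1.baseline.increments, f2.baseline.increments, rtol=1e-9)

    def test_zero_events_named_error(self):
        with pytest.raises(NoEventsError):
            fit_cox(np.zeros(3), np.ones(3), np.zeros(3), np.ones((3, 1)))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant covariates"):
            fit_cox(np.zeros(3), np.ones(3), np.array([1, 0, 0]), np.ones((3, 1)), names=("c",))

    def test_perfect_separation_flagged(self):
        # x perfectly orders events before censorings -> monotone likelihood
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        status = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = fit_cox(np.zeros(6), time, status, x[:, None])
        assert not fit.converged
        assert "separation" in fit.message or "monotone" in fit.message

    def test_serialization_round_trip(self):
        time, status, x = simulate_right_censored(300, 0.3, seed=9)
        fit = fit_cox(np.zeros(300), time, status, x[:, None], names=("x",), transition=1)
        clone = sl.TransitionFit.from_dict(fit.to_dict())
        np.testing.assert_allclose(clone.beta, fit.beta)
        np.testing.assert_allclose(clone.baseline.increments, fit.baseline.increments)
        assert clone.names == fit.names


class TestBreslowBaseline:
    def test_nelson_aalen_by_hand(self):
        """Event ages {1, 2} with risk sets {2, 1}: increments {1/2, 1}."""
        fit = fit_cox(np.array([0.0, 0.0]), np.array([1.0, 2.0]), np.array([1, 1]), None)
        np.testing.assert_allclose(fit.baseline.times, [1.0, 2.0])
        np.testing.assert_allclose(fit.baseline.increments, [0.5, 1.0])

    def test_left_truncation_shrinks_risk_set(self):
        # third subject enters after the first event time
        fit = fit_cox(
            np.array([0.0, 0.0, 1.5]),
            np.array([1.0, 2.0, 3.0]),
            np.array([1, 1, 1]),
            None,
        )
        np.testing.assert_allclose(fit.baseline.increments, [0.5, 0.5, 1.0])

    def test_covariance_properties(self):
        time, status, x = simulate_right_censored(500, 0.4, seed=10)
        X = np.column_stack([x, np.random.default_rng(1).normal(size=500)])
        fit = fit_cox(np.zeros(500), time, status, X)
        cov = fit.covariance
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > 0)
        assert np.all(np.diff(fit.baseline.times) > 0)
        assert np.all(fit.baseline.increments >= 0)
        assert fit.baseline.times.max() <= time.max()


class TestPredictCumhaz:
    @pytest.fixture
    def fit(self):
        time, status, x = simulate_right_censored(500, np.log(2.0), seed=11)
        return fit_cox(np.zeros(500), time, status, x[:, None], names=("x",), reference=np.array([0.0]))

    def test_reference_profile_returns_baseline(self, fit):
        sf = predict_cumhaz(fit, {"x": 0.0})
        np.testing.assert_allclose(sf.increments, fit.baseline.increments)

    def test_binary_flip_scales_by_hazard_ratio(self, fit):
        sf0 = predict_cumhaz(fit, {"x": 0.0})
        sf1 = predict_cumhaz(fit, {"x": 1.0})
        np.testing.assert_allclose(sf1.increments, sf0.increments * np.exp(fit.beta[0]))

    def test_in_sample_consistency(self, fit):
        """Profile equal to a person's covariates matches direct computation."""
        expected = fit.baseline.increments * np.exp(fit.beta[0] * 1.0)
        np.testing.assert_allclose(predict_cumhaz(fit, {"x": 1.0}).increments, expected)

    def test_missing_covariate_named_error(self, fit):
        with pytest.raises(KeyError, match="missing covariates"):
            predict_cumhaz(fit, {"y": 1.0})


class TestStepFunction:
    def test_evaluation_right_continuous(self):
        sf = StepFunction(np.array([1.0, 2.0]), np.array([0.5, 0.25]))
        np.testing.assert_allclose(sf([0.5, 1.0, 1.5, 2.0, 3.0]), [0.0, 0.5, 0.5, 0.75, 0.75])

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            StepFunction(np.array([2.0, 1.0]), np.array([0.1, 0.1]))

    def test_rejects_negative_increments(self):
        with pytest.raises(ValueError):
            StepFunction(np.array([1.0]), np.array([-0.1]))


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self):
        time, status, x = simulate_right_censored(1000, 0.5, seed=12)
        fg = fit_finegray(time, status, x[:, None], names=("x",))
        cx = fit_cox(np.zeros(1000), time, status, x[:, None], names=("x",), ties="breslow")
        assert fg.beta[0] == pytest.approx(cx.beta[0], abs=1e-8)

    def test_recovers_planted_subdistribution_hr(self):
        df = sl.simulate_subdistribution(20_000, np.log(1.5), seed=3)
        fg = fit_finegray(df["time"], df["event"], df[["x"]].to_numpy(), names=("x",))
        assert fg.converged
        assert abs(fg.beta[0] - np.log(1.5)) < 3 * fg.se()[0]
        hr, lo, hi = fg.hr["x"]
        assert lo < hr < hi

    def test_administrative_censoring_weights_are_one(self):
        """With only administrative censoring at a common horizon, the
        censoring survival is 1 before the horizon, so every IPCW weight
        ratio equals 1 there."""
        rng = np.random.default_rng(4)
        t = rng.exponential(1.0, 500)
        horizon = 2.0
        time = np.minimum(t, horizon)
        event = np.where(t <= horizon, rng.integers(1, 3, 500), 0)
        ct, G = _censoring_km(time, event == 0)
        probe = np.linspace(0, horizon - 1e-9, 50)
        np.testing.assert_allclose(_G_left(ct, G, probe), 1.0)

    def test_no_events_named_error(self):
        with pytest.raises(NoEventsError):
            fit_finegray(np.ones(4), np.array([0, 0, 2, 2]), np.ones((4, 1)))

    def test_competing_events_shift_estimate(self):
        # sanity: treating cause-2 subjects as plain censored differs from FG
        df = sl.simulate_subdistribution(5000, np.log(2.0), seed=6)
        fg = fit_finegray(df["time"], df["event"], df[["x"]].to_numpy())
        censored = df["event"].replace(2, 0)
        naive = fit_cox(
            np.zeros(len(df)), df["time"], (censored == 1).astype(int), df[["x"]].to_numpy(), ties="breslow"
        )
        assert fg.beta[0] != pytest.approx(naive.beta[0], abs=1e-3)
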