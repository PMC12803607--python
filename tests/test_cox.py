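"""Cox fitter vs lifelines oracle; ladder, elimination, spline LR test."""

import numpy as np
import pandas as pd
import pytest

import fibrosurv as fs
from fibrosurv.cox import ConvergenceError, fit_cox


@pytest.fixture(scope="module")
def cox_data(cohort_524):
    df = cohort_524.copy()
    df["cvf_high"] = (df["cvf_percent"] > 32).astype(int)
    return df


COLS = ["cvf_high", "log_ntprobnp", "bmi"]


class TestFitCox:
    def test_matches_lifelines_efron(self, cox_data):
        import lifelines

        mine = fit_cox(cox_data, "time_composite_years", "event_composite", COLS)
        cph = lifelines.CoxPHFitter().fit(
            cox_data[["time_composite_years", "event_composite", *COLS]],
            "time_composite_years",
            "event_composite",
        )
        np.testing.assert_allclose(mine.coef, cph.params_.values, atol=2e-4)
        np.testing.assert_allclose(
            np.sqrt(np.diag(mine.cov)), cph.standard_errors_.values, atol=1e-4
        )
        assert mine.log_partial_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_matches_lifelines_with_heavy_ties(self, cox_data):
        import lifelines

        tied = cox_data.copy()
        tied["time_composite_years"] = tied["time_composite_years"].round(0).clip(lower=0.5)
        mine = fit_cox(tied, "time_composite_years", "event_composite", COLS[:2])
        cph = lifelines.CoxPHFitter().fit(
            tied[["time_composite_years", "event_composite", *COLS[:2]]],
            "time_composite_years",
            "event_composite",
        )
        np.testing.assert_allclose(mine.coef, cph.params_.values, atol=2e-4)
        assert mine.log_partial_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_breslow_differs_from_efron_under_ties(self, cox_data):
        tied = cox_data.copy()
        tied["time_composite_years"] = tied["time_composite_years"].round(0).clip(lower=0.5)
        efron = fit_cox(tied, "time_composite_years", "event_composite", ["cvf_high"])
        breslow = fit_cox(
            tied, "time_composite_years", "event_composite", ["cvf_high"], ties="breslow"
        )
        assert efron.coef[0] != breslow.coef[0]

    def test_score_norm_small_at_optimum(self, cox_data):
        from fibrosurv.cox import _partial_lik_derivs

        m = fit_cox(cox_data, "time_composite_years", "event_composite", COLS)
        sub = cox_data[["time_composite_years", "event_composite", *COLS]].dropna()
        x = sub[COLS].to_numpy(float)
        _, grad, _ = _partial_lik_derivs(
            m.coef * x.std(0),  # standardised internal scale
            (x - x.mean(0)) / x.std(0),
            sub["time_composite_years"].to_numpy(float),
            sub["event_composite"].to_numpy(int),
            "efron",
        )
        assert np.linalg.norm(grad) < 1e-6

    def test_aic_identity(self, cox_data):
        m = fit_cox(cox_data, "time_composite_years", "event_composite", COLS)
        assert m.aic == pytest.approx(-2 * m.log_partial_likelihood + 2 * len(COLS))

    def test_ci_contains_point_estimate(self, cox_data):
        m = fit_cox(cox_data, "time_composite_years", "event_composite", COLS)
        for est in m.terms.values():
            assert est.ci95[0] <= est.hr <= est.ci95[1]
            assert 0 < est.p_value <= 1

    def test_null_covariate_small_coefficient(self):
        rng = np.random.default_rng(12)
        covered = 0
        for s in range(30):
            df = fs.simulate_cohort(fs.CohortSpec(n=1000, seed=500 + s, betas={}))
            df["noise"] = rng.permutation(df["cvf_percent"].to_numpy())  # no association
            m = fit_cox(df, "time_composite_years", "event_composite", ["noise"])
            est = m.terms["noise"]
            covered += est.coef - 1.96 * est.se <= 0 <= est.coef + 1.96 * est.se
        assert covered >= 27

    def test_perfect_separation_flagged(self):
        # the covariate perfectly orders a tiny all-event sample
        df = pd.DataFrame(
            {"t": np.arange(1.0, 13.0), "e": 1, "x": np.arange(12.0)}
        )
        m = fit_cox(df, "t", "e", ["x"])
        assert m.flagged == "monotone_likelihood"

    def test_constant_covariate_rejected(self, cox_data):
        df = cox_data.assign(const=1.0)
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, "time_composite_years", "event_composite", ["const"])

    def test_no_events_rejected(self, cox_data):
        df = cox_data.assign(event_composite=0)
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, "time_composite_years", "event_composite", ["cvf_high"])


class TestTwoPredictorLadder:
    def test_cvf_adjustment_lowers_aic_when_only_cvf_matters(self):
        wins = 0
        for s in range(8):
            df = fs.simulate_cohort(fs.CohortSpec(n=800, seed=900 + s, betas={}))
            ladder = fs.two_predictor_ladder(
                df,
                "time_composite_years",
                "event_composite",
                predictors={"age": ["age"], "bmi": ["bmi"]},
                adjust_name="cvf_percent",
            )
            ok = ladder[ladder["status"] == "ok"]
            wins += (ok["adjusted_aic"] < ok["single_aic"]).all()
        assert wins >= 5

    def test_collinear_predictor_flagged(self, cox_data):
        ladder = fs.two_predictor_ladder(
            cox_data,
            "time_composite_years",
            "event_composite",
            predictors={"clone": ["cvf_percent"]},
            adjust_name="cvf_percent",
        )
        assert ladder.loc[0, "status"] == "collinear_with_adjuster"

    def test_empty_predictor_list(self, cox_data):
        ladder = fs.two_predictor_ladder(
            cox_data, "time_composite_years", "event_composite", predictors={}
        )
        assert len(ladder) == 0

    def test_fit_error_recorded_not_raised(self, cox_data):
        df = cox_data.assign(const=1.0)
        ladder = fs.two_predictor_ladder(
            df,
            "time_composite_years",
            "event_composite",
            predictors={"const": ["const"], "bmi": ["bmi"]},
        )
        assert ladder.set_index("predictor").loc["const", "status"].startswith("fit_error")
        assert ladder.set_index("predictor").loc["bmi", "status"] == "ok"


def _ph_frame(seed, n=1000, beta=1.0, n_noise=5):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(
        rng.standard_normal((n, n_noise + 1)), columns=[f"x{i}" for i in range(n_noise + 1)]
    )
    eta = beta * x["x0"]
    t = 10 * (-np.log(rng.random(n)) * np.exp(-eta))
    c = rng.exponential(8, n)
    return x.assign(time=np.minimum(t, c), event=(t <= c).astype(int))


class TestBackwardElimination:
    def test_strong_predictor_retained(self):
        hits = 0
        for s in range(10):
            df = _ph_frame(seed=40 + s)
            res = fs.backward_eliminate(
                df, "time", "event", {f"x{i}": [f"x{i}"] for i in range(6)}
            )
            hits += "x0" in res.included_terms
        assert hits >= 9

    def test_all_noise_can_be_empty(self):
        df = _ph_frame(seed=7, beta=0.0)
        res = fs.backward_eliminate(
            df, "time", "event", {f"x{i}": [f"x{i}"] for i in range(6)}
        )
        if res.status == "empty":
            assert res.model is None and res.included_terms == []
        else:
            assert all(
                res.model.wald_test([t])[2] < 0.05 for t in res.included_terms
            )

    def test_removal_order_reproducible(self):
        df = _ph_frame(seed=40)
        cands = {f"x{i}": [f"x{i}"] for i in range(6)}
        a = fs.backward_eliminate(df, "time", "event", cands)
        b = fs.backward_eliminate(df, "time", "event", cands)
        assert a.removal_history == b.removal_history
        assert a.included_terms == b.included_terms

    def test_final_terms_all_significant(self):
        df = _ph_frame(seed=41)
        res = fs.backward_eliminate(
            df, "time", "event", {f"x{i}": [f"x{i}"] for i in range(6)}
        )
        if res.status == "ok":
            for term in res.included_terms:
                assert res.model.wald_test([term])[2] < 0.05


class TestNonlinearityTest:
    @staticmethod
    def _sim(seed, n, shape):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-2, 2, n)
        eta = 0.6 * x**2 if shape == "quadratic" else 0.5 * x
        t = 8 * (-np.log(rng.random(n)) * np.exp(-eta))
        c = rng.exponential(6, n)
        return pd.DataFrame({"x": x, "time": np.minimum(t, c), "event": (t <= c).astype(int)})

    def test_power_against_quadratic_hazard(self):
        rejections = sum(
            fs.nonlinearity_test(self._sim(200 + s, 1000, "quadratic"), "time", "event", "x")[
                "p_value"
            ]
            < 0.05
            for s in range(15)
        )
        assert rejections >= 12  # >= 80% power

    def test_level_under_linear_hazard(self):
        pvals = [
            fs.nonlinearity_test(self._sim(400 + s, 500, "linear"), "time", "event", "x")[
                "p_value"
            ]
            for s in range(40)
        ]
        assert np.mean(np.array(pvals) < 0.05) <= 0.15  # near-nominal level
        assert np.mean(pvals) > 0.3  # roughly uniform, not degenerate

    def test_spline_nests_linear(self):
        df = self._sim(1, 600, "quadratic")
        res = fs.nonlinearity_test(df, "time", "event", "x")
        assert (
            res["spline_model"].log_partial_likelihood
            >= res["linear_model"].log_partial_likelihood - 1e-9
        )
        assert res["df"] == 2
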