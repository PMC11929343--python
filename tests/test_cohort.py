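import numpy as np
import pandas as pd
import pytest

from bevmr.cohort import (
    ConvergenceError,
    build_design,
    difference_method,
    fit_cox,
    incidence_summary,
    schoenfeld_test,
    screen_mediators_obs,
)
from bevmr.simulate import CohortSimConfig, simulate_cohort


def naive_efron_loglik(beta, x, time, event):
    """Independent brute-force Efron partial log-likelihood (1 covariate)."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d_idx = np.flatnonzero((time == t) & (event == 1))
        r_idx = np.flatnonzero(time >= t)
        d = len(d_idx)
        s_r = np.exp(beta * x[r_idx]).sum()
        s_d = np.exp(beta * x[d_idx]).sum()
        ll += beta * x[d_idx].sum()
        for el in range(d):
            ll -= np.log(s_r - el / d * s_d)
    return ll


def grid_search_beta(x, time, event, lo=-4, hi=4):
    """1-D oracle: coarse grid then golden-section refinement."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda b: -naive_efron_loglik(b, x, time, event),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return res.x


SMALL_INSTANCES = [
    # (time, event, x) -- all <= 10 subjects, with and without ties
    ([1, 2, 3, 4], [1, 1, 0, 1], [1.0, 0.0, 1.0, 0.0]),
    ([2, 2, 3, 5, 7], [1, 1, 1, 0, 1], [0.5, -0.2, 1.0, 0.0, -1.0]),
    ([1, 1, 1, 2, 2, 3], [1, 1, 0, 1, 1, 1], [1.0, 0.0, 1.0, 0.0, 1.0, 0.0]),
    ([3, 1, 4, 1, 5, 9, 2, 6], [1, 0, 1, 1, 0, 1, 1, 1],
     [0.1, 0.9, -0.4, 0.7, 0.0, -0.9, 0.3, 0.5]),
    ([1, 2, 2, 2, 3, 3, 4, 4, 5, 6], [1, 1, 1, 0, 1, 1, 0, 1, 1, 1],
     [0.0, 1.0, 1.0, 0.0, -1.0, 0.5, 0.5, -0.5, 1.5, 0.0]),
]


class TestFitCox:
    def test_four_subject_closed_form(self, four_subject_cox):
        fit = fit_cox(four_subject_cox, ["x"])
        assert fit.coefficients["x"] == pytest.approx(0.5 * np.log(2), abs=1e-9)
        assert fit.hr.loc["x", "hr"] == pytest.approx(np.sqrt(2), abs=1e-8)

    @pytest.mark.parametrize("time,event,x", SMALL_INSTANCES)
    def test_matches_grid_search_oracle(self, time, event, x):
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        fit = fit_cox(df, ["x"])
        oracle = grid_search_beta(
            np.array(x, float), np.array(time, float), np.array(event, int)
        )
        assert fit.coefficients["x"] == pytest.approx(oracle, abs=1e-6)

    def test_balanced_label_swap_symmetry(self):
        # two subjects with identical times and swapped exposure labels:
        # the partial likelihood is symmetric in beta -> beta_hat = 0
        df = pd.DataFrame(
            {"time": [1.0, 1.0, 2.0, 2.0], "event": [1, 1, 1, 1],
             "x": [1.0, 0.0, 0.0, 1.0]}
        )
        fit = fit_cox(df, ["x"])
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_lifelines_multivariate(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 400
        df = pd.DataFrame(
            {"x1": rng.normal(size=n), "x2": rng.binomial(1, 0.4, n).astype(float)}
        )
        eta = 0.5 * df.x1 - 0.3 * df.x2
        df["time"] = np.ceil(rng.exponential(np.exp(-eta)) * 3)  # heavy ties
        df["event"] = rng.binomial(1, 0.7, n)
        mine = fit_cox(df, ["x1", "x2"])
        cph = CoxPHFitter()
        cph.fit(df[["time", "event", "x1", "x2"]], "time", "event")
        np.testing.assert_allclose(
            mine.coefficients.to_numpy(), cph.params_.to_numpy(), atol=1e-5
        )
        np.testing.assert_allclose(
            mine.covariance.to_numpy(), cph.variance_matrix_.to_numpy(), atol=1e-6
        )
        assert mine.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_loglik_monotone_across_iterations(self):
        rec, _ = simulate_cohort(
            CohortSimConfig(n_subjects=800, seed=4, baseline_scale=40,
                            confounder_count=3)
        )
        fit = fit_cox(rec, ["exposure", "mediator", "conf_1", "conf_2", "conf_3"])
        assert all(np.diff(fit.loglik_path) >= -1e-9)

    def test_no_events_is_error(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="two events"):
            fit_cox(df, ["x"])

    def test_constant_term_is_error(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1],
                           "x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, ["x"])

    def test_perfect_separation_raises_naming_term(self):
        # all events in one stratum of the binary covariate
        df = pd.DataFrame(
            {"time": [1, 2, 3, 4, 5, 6, 7, 8.0],
             "event": [1, 1, 1, 1, 0, 0, 0, 0],
             "x": [1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0]}
        )
        with pytest.raises(ConvergenceError, match="x"):
            fit_cox(df, ["x"])

    def test_categorical_exposure_expands_to_contrasts(self):
        rec, _ = simulate_cohort(
            CohortSimConfig(n_subjects=1500, seed=2, baseline_scale=30)
        )
        fit = fit_cox(rec, ["exposure_level"])
        assert list(fit.coefficients.index) == ["exposure_level[>=1]"]


class TestSchoenfeld:
    def test_type_i_error_calibrated_under_ph(self):
        """Under proportional hazards, rejection at 0.05 stays nominal."""
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            cfg = CohortSimConfig(
                n_subjects=300, exposure_prevalence=0.5, hr_direct=1.5,
                mediator_effect_on_hazard=0.0, exposure_effect_on_mediator=0.0,
                baseline_scale=25.0, confounder_count=0, seed=30_000 + rep,
            )
            rec, _ = simulate_cohort(cfg)
            fit = fit_cox(rec, ["exposure"])
            p = schoenfeld_test(fit, rec)["exposure"]
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_detects_reversing_effect(self):
        """Effect flipping sign halfway through follow-up is detected."""
        rng = np.random.default_rng(99)
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        # piecewise hazard: HR = e^1 before t=1, e^-1 after
        t1 = rng.exponential(1.0 / np.exp(1.0 * x))
        t = np.where(t1 < 1.0, t1, 1.0 + rng.exponential(1.0 / np.exp(-1.0 * x)))
        df = pd.DataFrame({"time": np.minimum(t, 4.0), "event": (t <= 4.0).astype(int),
                           "x": x})
        fit = fit_cox(df, ["x"])
        p = schoenfeld_test(fit, df)["x"]
        assert p < 0.01

    def test_single_event_is_error(self, four_subject_cox):
        fit = fit_cox(four_subject_cox, ["x"])
        one_event = four_subject_cox.assign(event=[1, 0, 0, 0])
        with pytest.raises(ValueError):
            schoenfeld_test(fit, one_event)


class TestIncidence:
    def test_study_scale_totals(self):
        n = 13_567
        df = pd.DataFrame(
            {"time": np.full(n, 201_277.0 / n), "event": 0, "g": "all"}
        )
        df.loc[:242, "event"] = 1  # 243 cases
        out = incidence_summary(df)
        assert out.loc["overall", "person_years"] == pytest.approx(201_277.0)
        assert out.loc["overall", "mean_followup_years"] == pytest.approx(14.8, abs=0.05)
        assert out.loc["overall", "rate_per_1000py"] == pytest.approx(1.207, abs=1e-3)

    def test_zero_events_group(self):
        df = pd.DataFrame({"time": [2.0, 3.0], "event": [0, 0], "g": ["a", "a"]})
        out = incidence_summary(df, group="g")
        assert out.loc["a", "rate_per_1000py"] == 0.0

    def test_single_subject_rate(self):
        df = pd.DataFrame({"time": [2.0], "event": [1], "g": ["a"]})
        out = incidence_summary(df)
        assert out.loc["overall", "rate_per_1000py"] == pytest.approx(500.0)

    def test_group_sums_match_overall(self):
        rec, _ = simulate_cohort(
            CohortSimConfig(n_subjects=3000, seed=8, baseline_scale=60)
        )
        overall = incidence_summary(rec)
        by_group = incidence_summary(rec, group="exposure_level")
        assert by_group["person_years"].sum() == pytest.approx(
            overall.loc["overall", "person_years"]
        )
        assert by_group["events"].sum() == overall.loc["overall", "events"]


class TestMediatorScreenObs:
    def test_exact_deterministic_relation(self):
        df = pd.DataFrame(
            {"x": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0], "m": [0.0, 2.0, 0.0, 2.0, 0.0, 2.0]}
        )
        out = screen_mediators_obs(df, mediator="m", exposure="x")
        assert out.loc[0, "coef"] == pytest.approx(2.0, abs=1e-10)
        assert out.loc[0, "p"] < 1e-10

    def test_six_point_dataset_matches_normal_equations_oracle(self):
        df = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
             "z": [0.3, -0.1, 0.5, 0.2, 0.0, -0.4],
             "m": [1.0, 1.7, 2.9, 0.8, 2.1, 3.2]}
        )
        out = screen_mediators_obs(df, "m", "x", ["z"])
        X = np.column_stack([np.ones(6), df["x"], df["z"]])
        oracle = np.linalg.solve(X.T @ X, X.T @ df["m"].to_numpy())
        assert out.loc[0, "coef"] == pytest.approx(oracle[1], abs=1e-10)

    def test_null_rejection_rate_nominal(self):
        rng = np.random.default_rng(55)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            df = pd.DataFrame(
                {"x": rng.binomial(1, 0.5, 120).astype(float),
                 "m": rng.normal(size=120)}
            )
            rejections += screen_mediators_obs(df, "m", "x").loc[0, "p"] < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_collinear_terms_named(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "z": [0.0, 2.0, 4.0, 6.0],
                           "m": [0.1, 0.4, 0.2, 0.9]})
        with pytest.raises(ValueError, match="collinear"):
            screen_mediators_obs(df, "m", "x", ["z"])


class TestDifferenceMethod:
    def test_null_mediator_truncation_frequent(self):
        """Mediator unrelated to exposure/outcome: pm centred on 0."""
        pms = []
        truncs = 0
        for rep in range(40):
            cfg = CohortSimConfig(
                n_subjects=1500, exposure_prevalence=0.5, hr_direct=1.8,
                mediator_effect_on_hazard=0.0, exposure_effect_on_mediator=0.0,
                baseline_scale=25.0, confounder_count=0, seed=40_000 + rep,
            )
            rec, _ = simulate_cohort(cfg)
            res = difference_method(rec, "exposure", "mediator", n_boot=0)
            pms.append(res.pm_raw)
            truncs += res.truncated
        assert abs(np.mean(pms)) < 0.05
        assert truncs > 5  # null pm is negative about half the time

    def test_bootstrap_ci_deterministic_and_brackets_point(self):
        cfg = CohortSimConfig(
            n_subjects=1200, exposure_prevalence=0.5, hr_direct=1.5,
            mediator_effect_on_hazard=0.4, exposure_effect_on_mediator=0.6,
            baseline_scale=25.0, confounder_count=2, seed=77,
        )
        rec, truth = simulate_cohort(cfg)
        a = difference_method(rec, "exposure", "mediator", ["conf_1", "conf_2"],
                              n_boot=60, seed=5)
        b = difference_method(rec, "exposure", "mediator", ["conf_1", "conf_2"],
                              n_boot=60, seed=5)
        assert a.pm_ci95 == b.pm_ci95
        assert a.pm_ci95[0] <= a.pm_raw <= a.pm_ci95[1]
        assert a.beta_total > a.beta_direct  # mediator carries part of the effect

    def test_direct_exceeding_total_truncates(self):
        # constructed cohort where adjusting for the mediator strengthens
        # the exposure coefficient -> negative pm -> truncated
        rng = np.random.default_rng(11)
        n = 1500
        x = rng.binomial(1, 0.5, n).astype(float)
        m = 0.8 * x + rng.normal(size=n)  # suppressor: mediator lowers the hazard
        eta = 0.5 * x - 0.3 * m
        t = rng.exponential(np.exp(-eta)) * 10
        df = pd.DataFrame({"time": np.minimum(t, 15.0),
                           "event": (t <= 15.0).astype(int),
                           "exposure": x, "mediator": m})
        res = difference_method(df, "exposure", "mediator", n_boot=0)
        assert res.pm_raw < 0
        assert res.pm == 0.0
        assert res.truncated


def test_build_design_categorical_reference_is_lowest():
    lvl = pd.Categorical(
        ["<1", ">6", "1-2", "<1"], categories=["<1", "1-2", ">6"], ordered=True
    )
    design = build_design(pd.DataFrame({"lvl": lvl}), ["lvl"])
    assert list(design.columns) == ["lvl[1-2]", "lvl[>6]"]
    # binary labels sort with "<1" first even as plain strings
    design2 = build_design(pd.DataFrame({"lvl": ["<1", ">=1", "<1"]}), ["lvl"])
    assert list(design2.columns) == ["lvl[>=1]"]
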