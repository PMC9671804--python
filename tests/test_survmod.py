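"""Cox partial likelihood vs brute force, splines, contrasts, PH diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from stepcourse import survmod
from stepcourse.survmod import (
    CoxFitResult,
    SplineSpec,
    baseline_cumhaz,
    cumulative_incidence,
    fit_cox_tv,
    hr_contrast,
    hr_curve,
    log_partial_likelihood,
    ph_diagnostics,
    rcs_basis,
    rcs_knots,
    schoenfeld_residuals,
    select_by_aic,
    wald_chunk_test,
)


def oracle_logpl(df, covs, beta, ties="efron"):
    """Hand-written partial likelihood: explicit loops over risk sets."""
    starts = df["start"].tolist()
    stops = df["stop"].tolist()
    ev = df["event"].astype(bool).tolist()
    X = df[covs].to_numpy(dtype=float)
    eta = [float(X[i] @ np.asarray(beta)) for i in range(len(df))]
    ll = 0.0
    for t in sorted({stops[i] for i in range(len(df)) if ev[i]}):
        risk = [i for i in range(len(df)) if starts[i] < t <= stops[i]]
        dead = [i for i in risk if ev[i] and stops[i] == t]
        d = len(dead)
        s_risk = sum(math.exp(eta[i]) for i in risk)
        s_dead = sum(math.exp(eta[i]) for i in dead)
        ll += sum(eta[i] for i in dead)
        for k in range(d):
            f = k / d if ties == "efron" else 0.0
            ll -= math.log(s_risk - f * s_dead)
    return ll


def random_toy(rng, max_persons=5):
    """Small random counting-process table with gaps, late entry and ties."""
    rows = []
    n = int(rng.integers(2, max_persons + 1))
    for p in range(n):
        t = 0.0
        for _ in range(int(rng.integers(1, 4))):
            start = t + float(rng.integers(0, 2))  # occasional gap
            stop = start + float(rng.integers(1, 4))
            rows.append(
                {
                    "person_id": p,
                    "start": start,
                    "stop": stop,
                    "event": 0,
                    "x": float(rng.normal()),
                    "z": float(rng.normal()),
                }
            )
            t = stop
    df = pd.DataFrame(rows)
    # mark up to 3 events on row endpoints (integer stops force ties sometimes)
    last_rows = df.groupby("person_id").tail(1).index
    k = int(rng.integers(1, min(3, len(last_rows)) + 1))
    df.loc[rng.choice(last_rows, size=k, replace=False), "event"] = 1
    return df


class TestRcsBasis:
    def test_three_knots_two_columns(self):
        x = np.linspace(0, 10, 50)
        assert rcs_basis(x, [2, 5, 8]).shape == (50, 2)

    @pytest.mark.parametrize("k,ncol", [(3, 2), (4, 3), (5, 4)])
    def test_k_minus_one_columns(self, k, ncol, rng):
        x = rng.normal(8000, 2500, 400)
        B = rcs_basis(x, rcs_knots(x, k))
        assert B.shape == (400, ncol)

    def test_below_first_knot_nonlinear_terms_vanish(self):
        B = rcs_basis(np.array([0.0, 1.0, 1.9]), [2, 5, 8, 11])
        assert np.allclose(B[:, 1:], 0.0)

    def test_linear_beyond_last_knot(self, rng):
        knots = [2.0, 5.0, 8.0, 11.0]
        x = np.linspace(12, 30, 200)
        B = rcs_basis(x, knots)
        for _ in range(10):
            coef = rng.normal(size=B.shape[1])
            y = B @ coef
            second_diff = np.diff(y, 2)
            assert np.max(np.abs(second_diff)) < 1e-8 * max(1, np.max(np.abs(y)))

    def test_quantile_placement(self, rng):
        x = rng.normal(0, 1, 10_000)
        np.testing.assert_allclose(
            rcs_knots(x, 3), np.quantile(x, [0.10, 0.50, 0.90]), rtol=1e-12
        )
        np.testing.assert_allclose(
            rcs_knots(x, 5), np.quantile(x, [0.05, 0.275, 0.50, 0.725, 0.95]), rtol=1e-12
        )

    def test_bad_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis([1.0], [3, 3, 5])
        with pytest.raises(ValueError):
            rcs_basis([1.0], [3, 2])
        with pytest.raises(ValueError):
            rcs_knots([1.0, 2.0], 6)


class TestPartialLikelihood:
    def test_null_model_closed_form(self):
        # 4 persons, distinct event times, no covariates:
        # log PL = -sum log |risk set| = -(log4 + log3 + log2 + log1)
        df = pd.DataFrame(
            {
                "person_id": [1, 2, 3, 4],
                "start": [0.0] * 4,
                "stop": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 1, 1],
            }
        )
        fit = fit_cox_tv(df, [])
        assert fit.loglik == pytest.approx(-(math.log(4) + math.log(3) + math.log(2)))

    def test_three_person_toy_matches_bruteforce_maximum(self):
        # events do not line up with the covariate ordering, so the partial
        # likelihood has an interior maximum
        df = pd.DataFrame(
            {
                "person_id": [1, 2, 3],
                "start": [0.0, 0.0, 0.0],
                "stop": [1.0, 2.0, 3.0],
                "event": [1, 1, 0],
                "x": [-0.5, 1.0, 0.5],
            }
        )
        fit = fit_cox_tv(df, ["x"])
        res = optimize.minimize_scalar(
            lambda b: -oracle_logpl(df, ["x"], [b]), bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.params["x"] == pytest.approx(res.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-9)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_oracle_on_random_toys(self, ties, rng):
        for _ in range(60):
            df = random_toy(rng)
            beta = rng.normal(0, 0.7, 2)
            got = log_partial_likelihood(df, ["x", "z"], beta, ties=ties)
            assert got == pytest.approx(oracle_logpl(df, ["x", "z"], beta, ties), abs=1e-9)

    def test_efron_differs_from_breslow_under_ties(self):
        df = pd.DataFrame(
            {
                "person_id": [1, 2, 3, 4],
                "start": [0.0] * 4,
                "stop": [2.0, 2.0, 3.0, 3.0],
                "event": [1, 1, 1, 0],
                "x": [1.0, 0.5, -0.5, -1.0],
            }
        )
        b = [0.4]
        le = log_partial_likelihood(df, ["x"], b, ties="efron")
        lb = log_partial_likelihood(df, ["x"], b, ties="breslow")
        assert le != pytest.approx(lb)
        assert le == pytest.approx(oracle_logpl(df, ["x"], b, "efron"), abs=1e-10)

    def test_error_conditions(self):
        df = pd.DataFrame(
            {"person_id": [1], "start": [0.0], "stop": [1.0], "event": [0], "x": [1.0]}
        )
        with pytest.raises(ValueError, match="no events"):
            fit_cox_tv(df, ["x"])
        df2 = pd.DataFrame(
            {
                "person_id": [1, 2],
                "start": [0.0, 0.0],
                "stop": [1.0, 2.0],
                "event": [1, 1],
                "x": [3.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="constant"):
            fit_cox_tv(df2, ["x"])

    def test_matches_lifelines_on_simulated_data(self, rng):
        lifelines = pytest.importorskip("lifelines")
        rows = []
        for p in range(150):
            x = rng.normal()
            t_event = rng.exponential(1.0 / (0.08 * math.exp(0.5 * x)))
            stop = min(t_event, 20.0)
            rows.append(
                {
                    "person_id": p,
                    "start": 0.0,
                    "stop": stop + rng.uniform(0, 1e-6),  # continuous, no ties
                    "event": int(t_event < 20.0),
                    "x": x,
                }
            )
        df = pd.DataFrame(rows)
        fit = fit_cox_tv(df, ["x"])
        ctv = lifelines.CoxTimeVaryingFitter(penalizer=0.0)
        ctv.fit(df, id_col="person_id", start_col="start", stop_col="stop", event_col="event")
        assert fit.params["x"] == pytest.approx(ctv.params_["x"], abs=1e-4)
        assert fit.se()["x"] == pytest.approx(ctv.standard_errors_["x"], abs=1e-4)

    def test_recovers_injected_effect(self, rng):
        rows = []
        beta_true = -0.4
        for p in range(600):
            x = rng.normal()
            lam = 0.05 * math.exp(beta_true * x)
            t_event = rng.exponential(1.0 / lam)
            stop = min(t_event, 30.0)
            rows.append(
                {
                    "person_id": p,
                    "start": 0.0,
                    "stop": stop,
                    "event": int(t_event < 30.0),
                    "x": x,
                }
            )
        fit = fit_cox_tv(pd.DataFrame(rows), ["x"])
        assert fit.params["x"] == pytest.approx(beta_true, abs=3 * fit.se()["x"])


class TestModelSelection:
    def _fit_like(self, ll, p, n_events=10):
        return CoxFitResult(
            params=pd.Series(np.zeros(p), index=[f"b{i}" for i in range(p)]),
            cov=pd.DataFrame(np.eye(p), index=[f"b{i}" for i in range(p)],
                             columns=[f"b{i}" for i in range(p)]),
            loglik=ll, n=50, n_events=n_events, n_rows=50, converged=True, ties="efron",
        )

    def test_aic_formula(self):
        assert self._fit_like(-100.0, 2).aic == pytest.approx(204.0)

    def test_equal_loglik_prefers_fewer_parameters(self):
        f2, f4 = self._fit_like(-100.0, 2), self._fit_like(-100.0, 4)
        assert select_by_aic([f4, f2]) is f2

    def test_argmin_aic(self):
        fits = [self._fit_like(-100.0, 2), self._fit_like(-90.0, 4), self._fit_like(-95.0, 3)]
        assert select_by_aic(fits) is fits[1]

    def test_differing_event_counts_rejected(self):
        with pytest.raises(ValueError):
            select_by_aic([self._fit_like(-10, 1, 5), self._fit_like(-10, 1, 6)])


class TestChunkTest:
    def _manual_fit(self, beta, cov, names):
        return CoxFitResult(
            params=pd.Series(beta, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            loglik=0.0, n=10, n_events=5, n_rows=10, converged=True, ties="efron",
            center=pd.Series(np.zeros(len(names)), index=names),
        )

    def test_zero_block_gives_p_one(self):
        fit = self._manual_fit([0.0, 0.0], np.eye(2), ["a", "b"])
        ct = wald_chunk_test(fit, ["a", "b"])
        assert ct.statistic == 0.0 and ct.p == 1.0

    def test_single_df_equals_squared_wald_z(self):
        fit = self._manual_fit([0.3, -0.1], np.diag([0.04, 0.01]), ["a", "b"])
        ct = wald_chunk_test(fit, ["a"])
        z = 0.3 / 0.2
        assert ct.statistic == pytest.approx(z**2)
        assert ct.df == 1

    def test_unknown_terms_rejected(self):
        fit = self._manual_fit([0.0], [[1.0]], ["a"])
        with pytest.raises(ValueError):
            wald_chunk_test(fit, ["zz"])

    def test_agrees_with_likelihood_ratio_at_large_n(self, ct_factory):
        # a modest effect keeps the two statistics in their common asymptotic regime
        table, _, _, _, _ = ct_factory(seed=901, kind="loglinear", n=1200, hr_per_1000=0.95)
        t = table.assign(steps_k=table["steps"] / 1000.0)
        full = fit_cox_tv(t, ["steps_k"])
        null_ll = log_partial_likelihood(t, ["steps_k"], [0.0])
        lr = 2 * (full.loglik - null_ll)
        wald = wald_chunk_test(full, ["steps_k"]).statistic
        assert wald == pytest.approx(lr, rel=0.10)


def _linear_fit(beta_per_step, var=1e-12):
    return CoxFitResult(
        params=pd.Series([beta_per_step], index=["steps"]),
        cov=pd.DataFrame([[var]], index=["steps"], columns=["steps"]),
        loglik=0.0, n=100, n_events=40, n_rows=100, converged=True, ties="efron",
        center=pd.Series([0.0], index=["steps"]),
    )


class TestHrCurveAndContrast:
    def test_reference_point_is_exactly_one(self):
        fit = _linear_fit(math.log(0.8) / 1000)
        curve = hr_curve(fit, SplineSpec(), [8000.0], reference=8000.0)
        assert curve["hr"].iloc[0] == 1.0
        assert curve["lo"].iloc[0] == pytest.approx(1.0)
        assert curve["hi"].iloc[0] == pytest.approx(1.0)

    def test_linear_thousand_step_ratio(self):
        fit = _linear_fit(math.log(0.8) / 1000)
        curve = hr_curve(fit, SplineSpec(), [9000.0], reference=8000.0)
        assert curve["hr"].iloc[0] == pytest.approx(0.8)

    def test_extrapolation_flagged(self):
        fit = _linear_fit(0.0)
        curve = hr_curve(fit, SplineSpec(), [2000.0, 8000.0], 8000.0, observed_range=(4000, 12000))
        assert curve["extrapolated"].tolist() == [True, False]

    def test_contrast_closed_form(self):
        # beta = ln(0.8)/1000, spread 4,580 steps -> HR = exp(-0.2231*4.58)
        fit = _linear_fit(math.log(0.8) / 1000)
        values = np.concatenate([np.full(50, 6000.0), np.full(50, 10580.0)])
        con = hr_contrast(fit, SplineSpec(), values)
        assert con.s75 - con.s25 == pytest.approx(4580.0)
        assert con.hr == pytest.approx(math.exp(math.log(0.8) / 1000 * 4580), rel=1e-9)
        assert con.hr == pytest.approx(0.36, abs=0.005)

    def test_zero_effect_contrast_is_one(self):
        con = hr_contrast(_linear_fit(0.0), SplineSpec(), np.linspace(4000, 12000, 100))
        assert con.hr == 1.0

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            hr_contrast(_linear_fit(0.0), SplineSpec(), np.full(10, 8000.0))

    def test_spline_curve_matches_linear_predictor_difference(self, ct_factory):
        table, cohort, person_steps, _, _ = ct_factory(seed=902, n=600)
        spec = SplineSpec(rcs_knots(table["steps"], 4))
        t = table.copy()
        des = spec.design(t["steps"].to_numpy())
        for c in spec.columns:
            t[c] = des[c].to_numpy()
        fit = fit_cox_tv(t, spec.columns)
        ref = float(np.median(table["steps"]))
        grid = np.quantile(table["steps"], [0.2, 0.5, 0.8])
        curve = hr_curve(fit, spec, grid, ref)
        for s, hr in zip(grid, curve["hr"]):
            lp_s = spec.design_row(float(s)) @ fit.params[spec.columns].to_numpy()
            lp_r = spec.design_row(ref) @ fit.params[spec.columns].to_numpy()
            assert hr == pytest.approx(math.exp(lp_s - lp_r), rel=1e-9)

    def test_curve_invariant_to_affine_covariate_recoding(self, ct_factory):
        table, _, _, _, _ = ct_factory(seed=903, n=500)
        t = table.assign(steps_k=table["steps"] / 1000.0)
        t["age_like"] = np.linspace(30, 80, len(t))
        t["age_rescaled"] = (t["age_like"] - 50) / 10
        spec = SplineSpec(name="steps_k")
        f1 = fit_cox_tv(t, ["steps_k", "age_like"])
        f2 = fit_cox_tv(t, ["steps_k", "age_rescaled"])
        c1 = hr_contrast(f1, spec, t["steps_k"])
        c2 = hr_contrast(f2, spec, t["steps_k"])
        assert c1.hr == pytest.approx(c2.hr, rel=1e-6)
        assert c1.se == pytest.approx(c2.se, rel=1e-5)


class TestCumulativeIncidence:
    def test_constant_hazard_closed_form(self, rng):
        lam, T = 0.03, 40.0
        rows = []
        for p in range(800):
            t_event = rng.exponential(1 / lam)
            rows.append(
                {
                    "person_id": p,
                    "start": 0.0,
                    "stop": min(t_event, T),
                    "event": int(t_event < T),
                    "x": float(rng.normal()),
                }
            )
        df = pd.DataFrame(rows)
        fit = fit_cox_tv(df, ["x"])
        ic = cumulative_incidence(fit, SplineSpec(name="x"), 0.0, {}, years=(1, 2, 3))
        for y, f in zip(ic.years, ic.incidence):
            months = y * survmod.MONTHS_PER_YEAR
            assert f == pytest.approx(1 - math.exp(-lam * months), abs=0.03)

    def test_monotone_in_time(self, ct_factory):
        table, _, _, _, _ = ct_factory(seed=904, n=500)
        t = table.assign(steps_k=table["steps"] / 1000.0)
        fit = fit_cox_tv(t, ["steps_k"])
        ic = cumulative_incidence(fit, SplineSpec(name="steps_k"), 8.0, {}, years=(3, 5, 7))
        assert ic.incidence[0] <= ic.incidence[1] <= ic.incidence[2]
        assert np.all(ic.incidence >= 0) and np.all(ic.incidence <= 1)
        assert np.all(ic.lo <= ic.incidence) and np.all(ic.incidence <= ic.hi)

    def test_vanishing_hazard_multiplier_gives_zero(self, ct_factory):
        table, _, _, _, _ = ct_factory(seed=905, n=400)
        t = table.assign(steps_k=table["steps"] / 1000.0)
        fit = fit_cox_tv(t, ["steps_k"])
        # drive the linear predictor to -inf analytically: huge protective steps
        ic = cumulative_incidence(fit, SplineSpec(name="steps_k"), 1e9, {}, years=(3,))
        assert ic.incidence[0] == pytest.approx(0.0, abs=1e-12)

    def test_baseline_cumhaz_nondecreasing(self, ct_factory):
        table, _, _, _, _ = ct_factory(seed=906, n=400)
        fit = fit_cox_tv(table.assign(steps_k=table["steps"] / 1000.0), ["steps_k"])
        bch = baseline_cumhaz(fit)
        assert (np.diff(bch["cumhaz"]) >= 0).all()


def _exp_cox_table(rng, n, beta, lam=0.05, T=30.0, drift=None):
    """Per-month piecewise table; optional time-varying true effect."""
    rows = []
    for p in range(n):
        x = float(rng.normal())
        alive = True
        for m in range(int(T)):
            b = beta if drift is None else beta * (1 + drift * m / T)
            rate = lam * math.exp(b * x)
            t_event = rng.exponential(1 / rate)
            if t_event < 1.0:
                rows.append({"person_id": p, "start": float(m), "stop": m + t_event,
                             "event": 1, "x": x})
                alive = False
                break
            rows.append({"person_id": p, "start": float(m), "stop": float(m + 1),
                         "event": 0, "x": x})
        if alive:
            pass
    return pd.DataFrame(rows)


class TestPhDiagnostics:
    def test_schoenfeld_residual_by_hand(self):
        df = pd.DataFrame(
            {
                "person_id": [1, 2, 3],
                "start": [0.0, 0.0, 0.0],
                "stop": [1.0, 2.0, 3.0],
                "event": [1, 1, 0],
                "x": [1.0, 0.0, -1.0],
            }
        )
        fit = fit_cox_tv(df, ["x"])
        res = schoenfeld_residuals(fit)
        b = fit.params["x"]
        c = fit.center["x"]
        w = np.exp(b * (df["x"].to_numpy() - c))
        # event at t=1: all three at risk
        xbar1 = (w * df["x"]).sum() / w.sum()
        # event at t=2: persons 2 and 3 at risk
        xbar2 = (w[1:] * df["x"][1:]).sum() / w[1:].sum()
        assert res["x"].iloc[0] == pytest.approx(1.0 - xbar1)
        assert res["x"].iloc[1] == pytest.approx(0.0 - xbar2)

    def test_null_rejection_rate_calibrated(self, rng):
        rejections = 0
        n_reps = 50
        for _ in range(n_reps):
            df = _exp_cox_table(rng, 150, beta=0.5)
            fit = fit_cox_tv(df, ["x"])
            p = ph_diagnostics(fit).query("term == 'GLOBAL'")["p"].iloc[0]
            rejections += p < 0.05
        assert 0 <= rejections / n_reps <= 0.14

    def test_detects_time_varying_effect(self, rng):
        hits = 0
        for _ in range(5):
            df = _exp_cox_table(rng, 500, beta=0.6, drift=2.0)  # effect triples over time
            fit = fit_cox_tv(df, ["x"])
            p = ph_diagnostics(fit).query("term == 'GLOBAL'")["p"].iloc[0]
            hits += p < 0.05
        assert hits >= 3

    def test_transform_options(self, ct_factory):
        table, _, _, _, _ = ct_factory(seed=907, n=400)
        fit = fit_cox_tv(table.assign(steps_k=table["steps"] / 1000.0), ["steps_k"])
        for tr in ("identity", "rank", "log"):
            out = ph_diagnostics(fit, transform=tr)
            assert set(out["term"]) == {"steps_k", "GLOBAL"}
            assert ((out["p"] >= 0) & (out["p"] <= 1)).all()
        with pytest.raises(ValueError):
            ph_diagnostics(fit, transform="spline")


def test_model_suite_registry_nesting():
    m = survmod.MODEL_SUITE
    assert set(m["model1"]) < set(m["model2"])
    assert set(m["model2"]) < set(m["model3"])
    assert "wear_hours_tv" in m["model3"]
    assert "baseline_steps_3mo" in m["model4"]
    assert "baseline_steps_6mo" in m["model5"]
    assert "bmi" in m["model2"] and "bmi" not in m["model1"]
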