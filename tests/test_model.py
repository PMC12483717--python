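"""SLCM: linear predictor, marginal likelihood, fitting, EB effects."""

import numpy as np
import pandas as pd
import pytest

from slcm import (
    DispersionTrajectory,
    GrowthParams,
    GrowthSpec,
    QuadSpec,
    SLCM,
    SLCMParams,
    SimDesign,
    check_identification,
    compare_to_average,
    eb_random_effects,
    fit_slcm,
    individual_loglik,
    linear_predictor,
    population_curve,
    simulate_dataset,
)
from slcm.dispersion import dispersion_at
from slcm.distributions import nb2_logpmf
from slcm.growth import eval_growth


class TestLinearPredictor:
    def test_unit_exposure_at_origin(self):
        gp = GrowthParams(-5.8, 0.25, 0.0, 10.0)
        assert linear_predictor({"exposure": 1.0, "bin_t": 0.0}, gp) == pytest.approx(-5.8)

    def test_offset_contract(self):
        gp = GrowthParams(-5.8, 0.25, 0.0, 10.0)
        e1 = linear_predictor({"exposure": 100.0, "bin_t": 9.0}, gp)
        e2 = linear_predictor({"exposure": 200.0, "bin_t": 9.0}, gp)
        assert e2 - e1 == pytest.approx(np.log(2.0), abs=1e-12)

    def test_rate_per_thousand(self):
        gp = GrowthParams(np.log(3.0 / 1000.0), 0.25, 0.0, 10.0)
        eta = linear_predictor({"exposure": 1000.0, "bin_t": 0.0}, gp)
        assert np.exp(eta) == pytest.approx(3.0)

    def test_nonpositive_exposure(self):
        with pytest.raises(ValueError):
            linear_predictor({"exposure": 0.0, "bin_t": 0.0}, GrowthParams(0, 0, 0, 1))


@pytest.fixture(scope="module")
def one_child():
    return pd.DataFrame({
        "id": 0, "bin_t": [0.0, 9.0, 24.0, 45.0],
        "count": [0, 2, 4, 3], "exposure": [60, 110, 90, 140],
    })


class TestIndividualLoglik:
    def test_degenerate_T_equals_fixed_effects(self, truth, one_child):
        p0 = SLCMParams(truth.fixed, np.zeros((4, 4)), truth.disp, (True,) * 4)
        t = one_child["bin_t"].to_numpy(float)
        mu = one_child["exposure"].to_numpy(float) * np.exp(eval_growth(t, truth.fixed))
        direct = nb2_logpmf(one_child["count"].to_numpy(), mu, dispersion_at(t, truth.disp)).sum()
        assert individual_loglik(one_child, p0) == pytest.approx(direct, abs=1e-12)

    def test_matches_dense_grid_in_one_dimension(self, truth, one_child):
        """AGH with one random effect against a 1e5-point trapezoid integral."""
        var = 0.2
        p1 = SLCMParams(truth.fixed, np.array([[var]]), truth.disp,
                        (True, False, False, False))
        agh = individual_loglik(one_child, p1, QuadSpec(nodes_per_dim=15))
        t = one_child["bin_t"].to_numpy(float)
        y = one_child["count"].to_numpy()
        u = one_child["exposure"].to_numpy(float)
        b = np.linspace(-10 * np.sqrt(var), 10 * np.sqrt(var), 100_001)
        mu = (u * np.exp(eval_growth(t, truth.fixed)))[:, None] * np.exp(b)[None, :]
        lp = nb2_logpmf(y[:, None], mu, dispersion_at(t, truth.disp)[:, None]).sum(axis=0)
        dens = np.exp(lp - b**2 / (2 * var)) / np.sqrt(2 * np.pi * var)
        oracle = np.log(np.trapezoid(dens, b))
        assert agh == pytest.approx(oracle, abs=1e-6)

    def test_invariant_to_record_order(self, truth, one_child):
        p = SLCMParams(truth.fixed, np.diag([0.2, 0.005]), truth.disp,
                       (True, True, False, False))
        shuffled = one_child.sample(frac=1.0, random_state=1)
        assert individual_loglik(one_child, p) == pytest.approx(
            individual_loglik(shuffled, p), abs=1e-10)


class TestQuadratureConvergence:
    def test_refinement_converges(self, truth, one_child):
        p = SLCMParams(truth.fixed, np.diag([0.2, 4.0]), truth.disp,
                       (True, False, False, True))
        vals = {n: individual_loglik(one_child, p, QuadSpec(nodes_per_dim=n))
                for n in (5, 9, 15, 25)}
        err5 = abs(vals[5] - vals[25])
        err9 = abs(vals[9] - vals[25])
        err15 = abs(vals[15] - vals[25])
        assert err9 <= err5 + 1e-12
        assert err15 <= err9 + 1e-12


class TestIdentification:
    def test_final_model_counts(self):
        rep = check_identification(GrowthSpec(), "expdecay", (True,) * 4, W=18,
                                   re_structure="full")
        assert rep.p_mean == 4
        assert rep.p_cov == 13  # 10 unique T elements + 3 decay coefficients
        assert rep.mean_status == "overidentified"
        assert rep.cov_status == "overidentified"
        assert rep.overall == "overidentified"

    def test_underidentified_mean(self):
        rep = check_identification(GrowthSpec(), "expdecay", (True,) * 4, W=3,
                                   re_structure="full")
        assert rep.mean_status == "underidentified"
        assert rep.overall == "underidentified"

    def test_diagonal_T_counting(self):
        rep = check_identification(GrowthSpec(), "loglinear", (True, True, False, False),
                                   W=10, re_structure="diagonal")
        assert rep.p_cov == 2 + 2


class TestFitting:
    def test_self_consistency(self, small_fit):
        """Refitting from the solution reproduces the solution.

        The changepoint basin refinement is a multi-start heuristic around
        the discontinuities at bin times and is not exactly idempotent, so
        the fixed-point contract is checked on the core optimizer.
        """
        data, fit = small_fit
        refit = fit_slcm(data, quad=QuadSpec(nodes_per_dim=3), init=fit.params,
                         compute_se=False, refine_changepoint=False)
        assert abs(refit.loglik - fit.loglik) < 1e-6

    def test_free_dispersion_nests_expdecay(self, small_fit):
        """The decay-constrained model cannot beat the free-dispersion one."""
        data, fit_decay = small_fit
        fit_free = fit_slcm(data, dispersion="free", quad=QuadSpec(nodes_per_dim=3),
                            compute_se=False)
        assert fit_decay.loglik <= fit_free.loglik + 1e-4

    def test_zero_variance_truth_recovered_at_boundary(self, truth):
        p0 = SLCMParams(truth.fixed, np.zeros((4, 4)), truth.disp, (True,) * 4)
        data = simulate_dataset(SimDesign(N=150, truth=p0), seed=21)
        fit = fit_slcm(data, quad=QuadSpec(nodes_per_dim=3))
        for name in ("var_beta0", "var_beta1", "var_beta3", "var_gamma"):
            est = fit.estimates[name]
            se = fit.se.get(name, 0.0)
            assert est < max(3 * se, 0.01), name

    def test_aic_bic_identities(self, small_fit):
        _, fit = small_fit
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.bic == pytest.approx(-2 * fit.loglik + fit.n_params * np.log(fit.n_individuals))


class TestStandardErrors:
    def test_robust_and_model_based_agree_on_average(self, fit300):
        """Under a correctly specified model the sandwich and the inverse
        information estimate the same quantity (information equality)."""
        rels = []
        for name, se in fit300.se.items():
            rob = fit300.robust_se[name]
            if se > 0:
                rels.append(abs(rob - se) / se)
        assert np.mean(rels) < 0.25

    def test_robust_se_positive(self, fit300):
        assert all(v > 0 for v in fit300.robust_se.values())

    def test_scores_sum_to_zero_at_optimum(self, dataset300, fit300):
        from slcm.model import _AGHEngine, _as_table, _make_par

        table = _as_table(dataset300)
        par = _make_par(table, "expdecay", "diagonal", (True,) * 4, 3.0)
        engine = _AGHEngine(table, par, QuadSpec(nodes_per_dim=5))
        _, _, grads = engine.evaluate(fit300.theta_internal, want_grad=True)
        total = grads.sum(axis=0)
        scale = np.abs(grads).sum(axis=0).max()
        assert np.abs(total).max() < 1e-3 * scale


class TestEmpiricalBayes:
    def test_modes_zero_when_T_vanishes(self, dataset300, truth):
        tiny = SLCMParams(truth.fixed, np.diag([1e-10] * 4), truth.disp, (True,) * 4)
        eb = eb_random_effects(_fit_result_for(tiny), dataset300.head(40))
        for col in [c for c in eb.columns if c.startswith("b_")]:
            assert np.abs(eb[col]).max() < 1e-4

    def test_mode_matches_dense_grid_1d(self, truth, one_child):
        var = 0.2
        p1 = SLCMParams(truth.fixed, np.array([[var]]), truth.disp,
                        (True, False, False, False))
        fake = _fit_result_for(p1)
        eb = eb_random_effects(fake, one_child)
        t = one_child["bin_t"].to_numpy(float)
        y = one_child["count"].to_numpy()
        u = one_child["exposure"].to_numpy(float)
        b = np.linspace(-3, 3, 600_001)
        mu = (u * np.exp(eval_growth(t, truth.fixed)))[:, None] * np.exp(b)[None, :]
        lp = nb2_logpmf(y[:, None], mu, dispersion_at(t, truth.disp)[:, None]).sum(axis=0)
        post = lp - b**2 / (2 * var)
        assert eb["b_beta0"].iloc[0] == pytest.approx(b[np.argmax(post)], abs=1e-4)

    def test_individual_on_population_curve_has_small_mode(self, truth):
        t = np.array([0.0, 9.0, 24.0, 45.0])
        u = np.full_like(t, 5000.0)
        mu = u * np.exp(eval_growth(t, truth.fixed))
        child = pd.DataFrame({"id": 0, "bin_t": t, "count": np.round(mu).astype(int),
                              "exposure": u.astype(int)})
        p = SLCMParams(truth.fixed, np.diag([0.2, 0.005, 0.002, 4.0]), truth.disp, (True,) * 4)
        eb = eb_random_effects(_fit_result_for(p), child)
        sds = np.sqrt(np.diag(p.T))
        for j, name in enumerate(["beta0", "beta1", "beta3", "gamma"]):
            assert abs(eb[f"b_{name}"].iloc[0]) < 0.05 * sds[j] + 1e-3, name


def _fit_result_for(params):
    """Minimal FitResult shell so EB helpers can run from bare parameters."""
    from slcm.model import FitResult, IdentificationReport

    return FitResult(
        params=params, loglik=0.0, aic=0.0, bic=0.0, n_params=0, se={}, robust_se={},
        converged=True, message="", n_individuals=1, n_obs=0, W=0,
        eb=pd.DataFrame(), identification=IdentificationReport(0, 0, 0, 0, "", "", ""),
    )


class TestPopulationCurve:
    def test_origin_value_and_changepoint(self, truth):
        curve = population_curve(_fit_result_for(
            SLCMParams(truth.fixed, np.diag([0.1] * 4), truth.disp, (True,) * 4)),
            [0.0, 10.0, 20.0], per_exposure=1.0)
        assert curve["expected_count"].iloc[0] == pytest.approx(np.exp(-5.8))
        assert curve.attrs["shifted_changepoint_months"] == pytest.approx(28.0)

    def test_monotone_when_slopes_nonnegative(self, truth):
        p = SLCMParams(truth.fixed, np.diag([0.1] * 4), truth.disp, (True,) * 4)
        curve = population_curve(_fit_result_for(p), np.arange(0.0, 54.0, 3.0))
        assert np.all(np.diff(curve["expected_count"]) >= 0)

    def test_slope_changes_at_changepoint(self):
        gp = GrowthParams(-5.0, 0.3, 0.05, 12.0)
        p = SLCMParams(gp, np.diag([0.1] * 4),
                       DispersionTrajectory("expdecay", (2.0, 0.9, 0.2)), (True,) * 4)
        t = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        curve = population_curve(_fit_result_for(p), t, per_exposure=1.0)
        logc = np.log(curve["expected_count"].to_numpy())
        np.testing.assert_allclose(np.diff(logc)[:2], 0.3, atol=1e-10)
        np.testing.assert_allclose(np.diff(logc)[-2:], 0.05, atol=1e-10)


class TestCompareToAverage:
    def test_partition_and_tie_class(self, fit300):
        out = compare_to_average(fit300)
        assert out["crosstab"]["n"].sum() == out["n"] == fit300.n_individuals
        assert set(out["flags"]["entry"]).issubset({"above", "below", "at"})

    def test_negative_intercept_slope_correlation(self, truth):
        """With corr(entry, phase-1 slope) < 0 the EB classes mirror it."""
        T = np.array([[0.3, -0.75 * np.sqrt(0.3 * 0.006)],
                      [-0.75 * np.sqrt(0.3 * 0.006), 0.006]])
        p = SLCMParams(truth.fixed, T, truth.disp, (True, True, False, False))
        data = simulate_dataset(SimDesign(N=200, truth=p), seed=13)
        fit = fit_slcm(data, re_structure="full", random_effects=("beta0", "beta1"),
                       quad=QuadSpec(nodes_per_dim=7), compute_se=False)
        out = compare_to_average(fit)
        flags = out["flags"]
        above = flags[flags["entry"] == "above"]
        frac_below = (above["phase1_slope"] == "below").mean()
        assert frac_below > 0.5


class TestEstimatorFacade:
    def test_sklearn_contract(self, dataset300):
        est = SLCM(nodes_per_dim=3, compute_se=False)
        params = est.get_params()
        assert params["nodes_per_dim"] == 3
        est.set_params(max_iter=150)
        est.fit(dataset300.head(200))
        assert hasattr(est, "result_")
        preds = est.predict(dataset300.head(10))
        assert np.all(preds > 0)

    def test_accepts_raw_ages(self):
        data = simulate_dataset(SimDesign(N=60, jitter_ages=True), seed=2)
        est = SLCM(nodes_per_dim=3, compute_se=False, random_state=0)
        est.fit(data[["id", "age_months", "count", "exposure"]])
        assert est.result_.W >= 10
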