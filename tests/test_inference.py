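import numpy as np
import pytest

import mortalcohort as mc
from mortalcohort.pipeline import _fit_once
from conftest import make_data


def _system_for(data, method, pattern="monotone", gamma=-0.2, scenario="none"):
    miss, reg = mc.analysis_designs(
        "monotone" if pattern == "monotone" else "nonmonotone", scenario,
        data.n_visits)
    recipe = mc.FitRecipe(method=method, pattern=pattern,
                          qfun=mc.SelectionBiasFunction.linear(gamma),
                          miss_designs=miss, reg_builder=reg)
    fit, mf, rg = _fit_once(data, recipe)
    return fit, mc.build_stacked_system(data, method, pattern, recipe.qfun,
                                        fit.model, fit, miss_fits=mf, regression=rg)


def test_iee_sandwich_matches_closed_form_robust_variance():
    """Complete data, saturated model: the sandwich equals the contrast
    transform of the empirical covariance of per-subject outcome vectors."""
    rng = np.random.default_rng(5)
    n, J = 120, 3
    y = rng.normal(4.0, 1.0, (n, J)) + rng.normal(0, 0.7, (n, 1))  # correlated
    data = make_data(y.tolist())
    fit, system = _system_for_iee(data)
    ve = mc.sandwich_variance(system)
    T = np.array([[1, 0, 0], [-1, 1, 0], [-1, 0, 1]], dtype=float)
    S = np.cov(y, rowvar=False, ddof=0)
    closed = T @ (S / n) @ T.T
    np.testing.assert_allclose(ve.cov, closed, rtol=1e-5)


def _system_for_iee(data):
    model = mc.MarginalModel.saturated(data.n_visits)
    fit = mc.fit_iee(data, model)
    system = mc.build_stacked_system(data, "iee", "monotone",
                                     mc.SelectionBiasFunction.linear(0.0),
                                     model, fit)
    return fit, system


def test_ipw_sandwich_matches_weighted_mean_closed_form():
    """Single visit, intercept-only estimated missingness model: the IPW
    estimate is the observed mean and the stacked sandwich variance is
    var(y_obs)/n_obs (the nuisance term vanishes at the solution)."""
    rng = np.random.default_rng(6)
    n = 200
    y = rng.normal(3.0, 1.2, n)
    robs = rng.random(n) < 0.7
    rows = [[float(y[i])] if robs[i] else [None] for i in range(n)]
    data = make_data(rows)
    q0 = mc.SelectionBiasFunction.linear(0.0)
    miss = {1: mc.HistoryDesign(("intercept",))}
    recipe = mc.FitRecipe(method="ipw", pattern="monotone", qfun=q0,
                          miss_designs=miss)
    fit, mf, rg = _fit_once(data, recipe)
    assert fit.beta[0] == pytest.approx(y[robs].mean(), rel=1e-9)
    system = mc.build_stacked_system(data, "ipw", "monotone", q0, fit.model,
                                     fit, miss_fits=mf)
    ve = mc.sandwich_variance(system)
    n_obs = robs.sum()
    closed = y[robs].var(ddof=0) / n_obs
    assert ve.cov[0, 0] == pytest.approx(closed, rel=1e-4)


def test_sandwich_invariant_to_subject_reordering():
    data = mc.simulate_monotone(mc.SimulationDesign(study="monotone", n=300, seed=8))
    _, system = _system_for(data, "aipw")
    cov1 = mc.sandwich_variance(system).cov
    perm = np.random.default_rng(0).permutation(data.n_subjects)
    data2 = data.take(perm)
    _, system2 = _system_for(data2, "aipw")
    cov2 = mc.sandwich_variance(system2).cov
    np.testing.assert_allclose(cov1, cov2, rtol=1e-6)


def test_stacked_estimating_functions_vanish_at_the_fit():
    data = mc.simulate_nonmonotone(mc.SimulationDesign(study="nonmonotone",
                                                       n=400, seed=9))
    for method in ("ipw", "cmor", "aipw"):
        _, system = _system_for(data, method, pattern="nonmonotone")
        resid = np.abs(system.psi(system.eta_hat).sum(axis=0)).max() / data.n_subjects
        assert resid < 1e-8


def test_bootstrap_zero_variance_on_deterministic_outcome():
    data = make_data([[2.0, 2.0]] * 12)
    ve = mc.bootstrap_variance(data, lambda d: mc.fit_iee(d).beta, B=20, seed=3)
    np.testing.assert_allclose(ve.cov, 0.0, atol=1e-20)


def test_bootstrap_reproducible_and_tracks_failures():
    data = mc.simulate_monotone(mc.SimulationDesign(study="monotone", n=120, seed=14))
    fn = lambda d: mc.fit_iee(d).beta
    ve1 = mc.bootstrap_variance(data, fn, B=30, seed=7)
    ve2 = mc.bootstrap_variance(data, fn, B=30, seed=7)
    np.testing.assert_array_equal(ve1.cov, ve2.cov)
    assert ve1.n_failed == 0
    with pytest.raises(ValueError, match="at least 2"):
        mc.bootstrap_variance(data, fn, B=1, seed=0)


def test_bootstrap_and_sandwich_agree_on_large_dataset():
    """On a well-behaved large simulated dataset the two variance routes
    agree within ~20% (stochastic assertion)."""
    data = mc.simulate_monotone(mc.SimulationDesign(study="monotone", n=4000, seed=15))
    miss, reg = mc.analysis_designs("monotone", "none")
    recipe = mc.FitRecipe(method="ipw", pattern="monotone",
                          qfun=mc.SelectionBiasFunction.linear(-0.2),
                          miss_designs=miss, reg_builder=reg)
    fit_sw = mc.fit_survivor_means(data, recipe, variance="sandwich")
    fit_bs = mc.fit_survivor_means(data, recipe, variance="bootstrap", B=60, seed=1)
    np.testing.assert_allclose(fit_bs.se, fit_sw.se, rtol=0.2)


def test_wald_interval_contains_point_estimate():
    data = mc.simulate_monotone(mc.SimulationDesign(study="monotone", n=300, seed=16))
    fit, system = _system_for(data, "ipw")
    ve = mc.sandwich_variance(system)
    ci = ve.conf_int()
    assert ((ci[:, 0] <= ve.beta) & (ve.beta <= ci[:, 1])).all()
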