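import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logit

import mortalcohort as mc
from mortalcohort.missingness import ObservationModelFit
from mortalcohort.regression import OutcomeRegressionFit
from conftest import make_data


def _trivial_fits(J, mode="monotone"):
    q0 = mc.SelectionBiasFunction.linear(0.0)
    return {t: ObservationModelFit(t, None, q0, mode, None) for t in range(1, J + 1)}


def _empty_regression(mode="monotone"):
    return OutcomeRegressionFit(mode=mode, thetas={}, designs={},
                                qfun=mc.SelectionBiasFunction.linear(0.0))


def test_saturated_iee_gives_survivor_means(complete_two_by_three):
    fit = mc.fit_iee(complete_two_by_three)
    means = complete_two_by_three.y.mean(axis=0)
    np.testing.assert_allclose(fit.beta, [means[0], *(means[1:] - means[0])])


def test_no_missingness_reduction_all_estimators_agree():
    """With nothing missing among the alive, IPW = CMOR = AIPW = IEE exactly."""
    data, yfull = mc.simulate_monotone(
        mc.SimulationDesign(study="monotone", n=200, seed=21), return_oracle=True)
    data.r = data.a.copy()
    data.y = np.where(data.a == 1, yfull, np.nan)
    J = data.n_visits
    iee = mc.fit_iee(data)
    ws = mc.cumulative_weights(data, _trivial_fits(J), "monotone")
    ipw = mc.fit_ipw(data, ws)
    reg, imp = mc.sequential_impute_monotone(data, mc.SelectionBiasFunction.linear(-0.2))
    cmor = mc.fit_iee(data, imputed=imp, method_label="cmor")
    aipw = mc.fit_aipw_monotone(data, ws, _empty_regression())
    aipw_nm = mc.fit_aipw_nonmonotone(data, ws, _empty_regression("nonmonotone"))
    for other in (ipw, cmor, aipw, aipw_nm):
        np.testing.assert_allclose(other.beta, iee.beta, rtol=1e-10)


def test_weighted_stratum_means_by_hand():
    # single visit, 4 subjects, weights (2, 2, 1, 1) via lambda (0.5, 0.5, 1, 1)
    data = make_data([[1.0], [2.0], [4.0], [6.0]])
    lam = np.array([[0.5], [0.5], [1.0], [1.0]])
    ws = mc.WeightSet(pi=lam.copy(), lam=lam, mode="monotone")
    fit = mc.fit_ipw(data, ws)
    assert fit.beta[0] == pytest.approx((2 * 1 + 2 * 2 + 4 + 6) / 6)


def test_linear_solve_equals_brute_force_norm_minimisation():
    """On a 6-subject, 3-visit instance the weighted estimating equation's
    root from the linear solve matches naive minimisation of ||Psi(beta)||^2."""
    data = make_data([
        [4.1, 3.9, 3.0], [5.0, None, None], [3.7, 4.2, "dead"],
        [4.4, 4.0, 3.6], [4.9, None, None], [3.2, 3.1, 2.5]])
    q0 = mc.SelectionBiasFunction.linear(0.0)
    fits = {1: ObservationModelFit(1, None, q0, "monotone", None),
            2: ObservationModelFit(2, mc.HistoryDesign(("intercept",)), q0,
                                   "monotone", np.array([logit(1 - 2 / 3)])),
            3: ObservationModelFit(3, mc.HistoryDesign(("intercept",)), q0,
                                   "monotone", np.array([logit(1 - 0.9)]))}
    ws = mc.cumulative_weights(data, fits, "monotone")
    fit = mc.fit_ipw(data, ws)

    B = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1]], dtype=float)

    def psi_norm(beta):
        total = np.zeros(3)
        for i in range(6):
            for t in range(3):
                if data.r[i, t] == 1 and data.a[i, t] == 1:
                    mu = B[t] @ beta
                    total += B[t] * (data.y[i, t] - mu) / ws.lam[i, t]
        return float(total @ total)

    # coarse grid search then local polish, independent of the linear algebra
    grid = np.arange(-2.0, 2.01, 0.5)
    best, best_val = None, np.inf
    base = np.array([4.0, 0.0, 0.0])
    for d1 in grid:
        for d2 in grid:
            for d3 in grid:
                cand = base + np.array([d1, d2, d3])
                v = psi_norm(cand)
                if v < best_val:
                    best, best_val = cand, v
    res = minimize(psi_norm, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    np.testing.assert_allclose(fit.beta, res.x, atol=1e-5)


def test_cmor_beta_is_iee_on_completed_data():
    data = mc.simulate_monotone(mc.SimulationDesign(study="monotone", n=300, seed=31))
    _, reg_builder = mc.analysis_designs("monotone", "none")
    reg, imp = mc.sequential_impute_monotone(
        data, mc.SelectionBiasFunction.linear(-0.2), reg_builder)
    cmor = mc.fit_iee(data, imputed=imp, method_label="cmor")
    # manual IEE on the completed outcomes
    avail = (data.a == 1)
    y = imp.y_completed
    means = np.array([y[avail[:, t], t].mean() for t in range(5)])
    np.testing.assert_allclose(cmor.beta, [means[0], *(means[1:] - means[0])],
                               rtol=1e-9)


def test_missing_nuisance_level_raises():
    data = mc.simulate_monotone(mc.SimulationDesign(study="monotone", n=300, seed=32))
    q = mc.SelectionBiasFunction.linear(-0.2)
    miss_designs, _ = mc.analysis_designs("monotone", "none")
    fits = mc.fit_missingness_models(data, miss_designs, q, "monotone")
    ws = mc.cumulative_weights(data, fits, "monotone")
    with pytest.raises(ValueError, match="missing outcome-regression fit"):
        mc.fit_aipw_monotone(data, ws, _empty_regression())


def test_aipw_augmentation_coefficient_telescopes_to_one():
    """The total weight on mu in the monotone augmented equations is exactly
    1 for every alive record (cumulative-product telescoping)."""
    from mortalcohort.estimators import _augmentation_terms
    data = mc.simulate_monotone(mc.SimulationDesign(study="monotone", n=300, seed=33))
    q = mc.SelectionBiasFunction.linear(-0.2)
    miss_designs, reg_builder = mc.analysis_designs("monotone", "none")
    fits = mc.fit_missingness_models(data, miss_designs, q, "monotone")
    ws = mc.cumulative_weights(data, fits, "monotone")
    reg, _ = mc.sequential_impute_monotone(data, q, reg_builder, fit_all_levels=True)
    coef, _ = _augmentation_terms(data, ws, reg)
    alive = data.a == 1
    np.testing.assert_allclose(coef[alive], 1.0, rtol=1e-9)
    assert (coef[~alive] == 0).all()
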