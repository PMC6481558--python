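import numpy as np
import pytest

import mortalcohort as mc
from mortalcohort.regression import fit_tilted_regression
from conftest import make_data


def test_zero_tilt_reduces_to_plain_mean_and_ols():
    theta = fit_tilted_regression(np.ones((2, 1)), [1.0, 3.0], [0.0, 0.0])
    assert theta[0] == pytest.approx(2.0)
    # slope model on 3 points equals ordinary least squares
    X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
    y = np.array([1.0, 2.0, 2.5])
    theta = fit_tilted_regression(X, y, np.zeros(3))
    np.testing.assert_allclose(theta, np.linalg.lstsq(X, y, rcond=None)[0],
                               rtol=1e-10)


def test_tilted_intercept_is_exponentially_weighted_mean():
    theta = fit_tilted_regression(np.ones((2, 1)), [1.0, 3.0], [-0.2, -0.6])
    expected = (1 * np.exp(-0.2) + 3 * np.exp(-0.6)) / (np.exp(-0.2) + np.exp(-0.6))
    assert theta[0] == pytest.approx(expected, rel=1e-12)


def test_too_few_rows_and_rank_deficiency_raise():
    with pytest.raises(ValueError, match="fewer rows"):
        fit_tilted_regression(np.ones((1, 2)), [1.0], [0.0])
    X = np.column_stack([np.ones(4), np.ones(4)])
    with pytest.raises(np.linalg.LinAlgError):
        fit_tilted_regression(X, np.arange(4.0), np.zeros(4))


def test_no_missingness_means_no_imputation():
    data = make_data([[1.0, 2.0], [3.0, 4.0], [0.0, 1.0]])
    fit, imp = mc.sequential_impute_monotone(data, mc.SelectionBiasFunction.linear(-0.2))
    assert not imp.imputed_mask.any()
    np.testing.assert_array_equal(imp.y_completed, data.y)


def _mar_sequential_imputer(data, x0col):
    """Independent ignorable-case imputer: per (t, s) OLS of the pseudo
    outcome on (1, Y_s, x0) among survivors observed at s+1, recursing
    downward, imputing dropouts at their last observed level."""
    y = data.y.copy()
    n, J = y.shape
    x = data.baseline(x0col)
    for t in range(2, J + 1):
        for s in range(t - 1, 0, -1):
            pop = (data.a[:, t - 1] == 1) & (data.r[:, s] == 1)
            X = np.column_stack([np.ones(n), np.nan_to_num(data.y[:, s - 1]), x])
            resp = np.where(data.r[:, t - 1] == 1, np.nan_to_num(data.y[:, t - 1]),
                            np.nan_to_num(y[:, t - 1]))
            theta = np.linalg.lstsq(X[pop], resp[pop], rcond=None)[0]
            tgt = (data.a[:, t - 1] == 1) & (data.r[:, s - 1] == 1) & (data.r[:, s] == 0)
            y[tgt, t - 1] = X[tgt] @ theta
    return y


def test_gamma_zero_equals_independent_mar_imputer():
    data = mc.simulate_monotone(mc.SimulationDesign(study="monotone", n=400, seed=9))
    _, reg_builder = mc.analysis_designs("monotone", "none")
    fit, imp = mc.sequential_impute_monotone(
        data, mc.SelectionBiasFunction.linear(0.0), reg_builder)
    oracle = _mar_sequential_imputer(data, "U")
    mask = imp.imputed_mask
    np.testing.assert_allclose(imp.y_completed[mask], oracle[mask], rtol=1e-8)


def test_negative_gamma_imputes_strictly_below_ignorable():
    """A tilt decreasing in y pulls imputations downward: exactly pointwise
    for intercept-only models (exponentially weighted means are monotone in
    gamma), and on average for covariate models, where only the underlying
    conditional means — not every finite-sample fitted prediction — are
    ordered."""
    data = mc.simulate_monotone(mc.SimulationDesign(study="monotone", n=2000, seed=10))
    intercept_only = lambda t, s: mc.HistoryDesign(("intercept",))
    _, imp0 = mc.sequential_impute_monotone(
        data, mc.SelectionBiasFunction.linear(0.0), intercept_only)
    _, imp_neg = mc.sequential_impute_monotone(
        data, mc.SelectionBiasFunction.linear(-0.3), intercept_only)
    mask = imp0.imputed_mask
    assert (imp_neg.y_completed[mask] < imp0.y_completed[mask]).all()

    _, reg_builder = mc.analysis_designs("monotone", "none")
    _, full0 = mc.sequential_impute_monotone(
        data, mc.SelectionBiasFunction.linear(0.0), reg_builder)
    _, full_neg = mc.sequential_impute_monotone(
        data, mc.SelectionBiasFunction.linear(-0.3), reg_builder)
    assert full_neg.y_completed[mask].mean() < full0.y_completed[mask].mean()


def test_nonmonotone_single_visit_imputation_is_tilted_mean():
    data = make_data([[1.0], [3.0], [None]])
    fit, imp = mc.impute_nonmonotone(data, mc.SelectionBiasFunction.linear(-0.2))
    expected = (1 * np.exp(-0.2) + 3 * np.exp(-0.6)) / (np.exp(-0.2) + np.exp(-0.6))
    assert imp.y_completed[2, 0] == pytest.approx(expected, rel=1e-12)


def test_nonmonotone_zero_gamma_is_per_visit_regression_imputation():
    data = mc.simulate_nonmonotone(mc.SimulationDesign(study="nonmonotone",
                                                       n=400, seed=11))
    _, reg_builder = mc.analysis_designs("nonmonotone", "none")
    fit, imp = mc.impute_nonmonotone(data, mc.SelectionBiasFunction.linear(0.0),
                                     reg_builder)
    # oracle: plain WLS with unit weights per visit on the same design
    for t in range(2, 6):
        X = reg_builder(t).matrix(data, t - 1)
        obs = (data.a[:, t - 1] == 1) & (data.r[:, t - 1] == 1)
        theta = np.linalg.lstsq(X[obs], data.y[obs, t - 1], rcond=None)[0]
        tgt = (data.a[:, t - 1] == 1) & (data.r[:, t - 1] == 0)
        np.testing.assert_allclose(imp.y_completed[tgt, t - 1], X[tgt] @ theta,
                                   rtol=1e-8)


def test_imputations_cover_exactly_the_pre_death_gaps():
    data = mc.simulate_monotone(mc.SimulationDesign(study="monotone", n=300, seed=12))
    _, reg_builder = mc.analysis_designs("monotone", "none")
    _, imp = mc.sequential_impute_monotone(
        data, mc.SelectionBiasFunction.linear(-0.2), reg_builder)
    np.testing.assert_array_equal(imp.imputed_mask, (data.a == 1) & (data.r == 0))
    assert np.isnan(imp.y_completed[data.a == 0]).all()
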