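import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import expit, logit

import mortalcohort as mc
from mortalcohort.missingness import ObservationModelFit, observation_probability
from conftest import make_data


def _four_subject_visit2(ys2=(1.0, 3.0)):
    """4 subjects alive through visit 2, observed at visit 1, r2=(1,1,0,0)."""
    return make_data([[0.5, ys2[0]], [0.2, ys2[1]], [0.1, None], [0.9, None]])


def test_intercept_only_untilted_root_is_half():
    data = _four_subject_visit2()
    fit = mc.fit_monotone_missingness(
        data, mc.HistoryDesign(("intercept",)), mc.SelectionBiasFunction.linear(0.0), 2)
    # root of 2 e^{a0} - 2 = 0
    assert fit.alpha[0] == pytest.approx(0.0, abs=1e-8)
    p = observation_probability(fit, np.array([1.0]), y_t=5.0)
    assert p == pytest.approx(0.5)


def test_tilted_intercept_root_matches_bisection_oracle():
    data = _four_subject_visit2((1.0, 3.0))
    q = mc.SelectionBiasFunction.linear(-0.2)
    fit = mc.fit_monotone_missingness(data, mc.HistoryDesign(("intercept",)), q, 2)
    closed = np.log(2) - np.log(np.exp(-0.2) + np.exp(-0.6))
    assert fit.alpha[0] == pytest.approx(closed, abs=1e-9)
    # independent bisection on the score sum_obs e^{a+q} - n_miss
    root = brentq(lambda a: np.exp(a - 0.2) + np.exp(a - 0.6) - 2.0, -5, 5)
    assert fit.alpha[0] == pytest.approx(root, abs=1e-9)


def test_reformulated_score_equals_raw_weighted_score_pointwise():
    """(R - pi)/pi equals R e^{h+q} - (1 - R) for any alpha and full y."""
    rng = np.random.default_rng(0)
    y = rng.normal(size=8)
    robs = np.array([1, 1, 1, 0, 0, 1, 0, 1], dtype=float)
    q = -0.2 * y
    for a0 in (-1.0, 0.0, 0.7):
        pi = 1.0 - expit(a0 + q)
        raw = (robs - pi) / pi
        reform = robs * np.exp(a0 + q) - (1 - robs)
        np.testing.assert_allclose(raw, reform, rtol=1e-12)


def test_no_missingness_signals_separation():
    data = make_data([[1.0, 2.0], [0.5, 1.5], [0.2, 0.3]])
    with pytest.raises(mc.SeparationError, match="no missingness"):
        mc.fit_nonmonotone_missingness(
            data, mc.HistoryDesign(("intercept",), mode="nonmonotone"),
            mc.SelectionBiasFunction.linear(0.0), 2)


def test_symmetric_nonmonotone_intercept_root_is_zero():
    data = make_data([[1.0, 2.0], [0.5, None], [0.2, 0.3], [0.9, None]])
    fit = mc.fit_nonmonotone_missingness(
        data, mc.HistoryDesign(("intercept",), mode="nonmonotone"),
        mc.SelectionBiasFunction.linear(0.0), 2)
    assert fit.alpha[0] == pytest.approx(0.0, abs=1e-8)


def test_observation_probability_hand_substitution():
    fit = ObservationModelFit(t=3, design=mc.HistoryDesign(("intercept", "y_last", "U")),
                              qfun=mc.SelectionBiasFunction.linear(-0.2),
                              mode="monotone", alpha=np.array([-0.75, -0.175, 0.1]))
    p = observation_probability(fit, np.array([1.0, 4.0, 8.0]), y_t=4.0)
    assert p == pytest.approx(1.0 - expit(-0.75 - 0.7 + 0.8 - 0.8))


def test_cumulative_weight_arithmetic():
    # two visits with pi = (0.8, 0.5) via intercept-only coefficients
    data = make_data([[1.0, 2.0]])
    q0 = mc.SelectionBiasFunction.linear(0.0)
    fits = {1: ObservationModelFit(1, mc.HistoryDesign(("intercept",)), q0,
                                   "monotone", np.array([logit(0.2)])),
            2: ObservationModelFit(2, mc.HistoryDesign(("intercept",)), q0,
                                   "monotone", np.array([logit(0.5)]))}
    ws = mc.cumulative_weights(data, fits, "monotone")
    np.testing.assert_allclose(ws.lam[0], [0.8, 0.4])
    np.testing.assert_allclose(ws.weights(data)[0], [1.25, 2.5])


def test_all_probability_one_gives_unit_weights():
    data = make_data([[1.0, 2.0], [3.0, 4.0]])
    q0 = mc.SelectionBiasFunction.linear(0.0)
    fits = {t: ObservationModelFit(t, None, q0, "monotone", None) for t in (1, 2)}
    ws = mc.cumulative_weights(data, fits, "monotone")
    assert (ws.weights(data) == 1.0).all()


def test_monotone_parameter_recovery_and_horvitz_thompson():
    """Correctly specified fits recover the generating coefficients, and
    the mean of R/lambda among the alive is 1 at every visit."""
    design = mc.SimulationDesign(study="monotone", n=100_000, seed=42)
    data = mc.simulate_monotone(design)
    q = mc.SelectionBiasFunction.linear(-0.2)
    miss_designs, _ = mc.analysis_designs("monotone", "none")
    fits = mc.fit_missingness_models(data, miss_designs, q, "monotone")
    # tolerances ~3 sampling SDs at this n (the tilted score is heavy-tailed,
    # so the intercept is much noisier than a plain logistic fit)
    tol = np.array([0.30, 0.08, 0.012])
    for t in range(2, 6):
        assert np.all(np.abs(fits[t].alpha - [-0.75, -0.175, 0.1]) < tol)
    ws = mc.cumulative_weights(data, fits, "monotone")
    inv = np.where(data.r == 1, 1.0 / np.nan_to_num(ws.lam, nan=1.0), 0.0)
    for t in range(5):
        alive = data.a[:, t] == 1
        assert np.mean(inv[alive, t]) == pytest.approx(1.0, abs=0.05)


def test_nonmonotone_parameter_recovery():
    design = mc.SimulationDesign(study="nonmonotone", n=100_000, seed=43)
    data = mc.simulate_nonmonotone(design)
    q = mc.SelectionBiasFunction.linear(-0.2)
    miss_designs, _ = mc.analysis_designs("nonmonotone", "none")
    fits = mc.fit_missingness_models(data, miss_designs, q, "nonmonotone")
    tol = np.array([0.30, 0.08, 0.012])
    for t in range(2, 6):
        assert np.all(np.abs(fits[t].alpha - [0.1, -0.175, 0.1]) < tol)
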