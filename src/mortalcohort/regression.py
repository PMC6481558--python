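"""Tilted outcome regressions and conditional-mean imputation (CMOR).

Among survivors at visit ``t``, the mean outcome of those who are *not*
observed equals an exponentially tilted mean of the observed:

    E[Y_t | hist, R_t=0, alive] = E[Y_t e^{q}| hist, R_t=1, alive]
                                  / E[e^{q} | hist, R_t=1, alive]

so a regression of Y_t on the history, fitted with weights ``exp(q)``
among the observed, consistently predicts the unobserved survivors'
means.  With a tilt that decreases in y (gamma < 0), dropouts are imputed
systematically below their ignorable-case imputations.

Monotone pattern: dropout at ``s+1`` leaves the history ``\\bar{O}_s``, so a
grid of regressions ``m_t(\\bar{O}_s; theta_{t,s})`` is fitted recursively,
``s = t-1`` down to 0.  At level ``s`` the fitting population is
{alive at t, observed at s+1}; the response is the observed ``Y_t`` when
available, else the value already imputed at the subject's own dropout
level; the tilt is ``q_{s+1}(\\bar{O}_s, Y_{s+1})``.  Subjects whose last
observed visit is ``s`` are then imputed from ``theta_{t,s}``.

Non-monotone pattern: the history encoding already carries the response
pattern, so a single regression per visit (fit on the observed survivors,
tilt ``q_t``) imputes all unobserved survivors at that visit.  Post-death
outcomes are never imputed.  The instrument ``d_t`` is the ``m_t`` design
vector, making each fit a closed-form weighted least squares solve.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import MortalCohortData
from .design import HistoryDesign
from .selection import SelectionBiasFunction

__all__ = [
    "OutcomeRegressionFit",
    "ImputedData",
    "fit_tilted_regression",
    "sequential_impute_monotone",
    "impute_nonmonotone",
    "default_monotone_design",
    "default_nonmonotone_design",
]


def fit_tilted_regression(design: np.ndarray, response: np.ndarray,
                          tilt: np.ndarray) -> np.ndarray:
    """Solve the tilted normal equations  sum e^{q} (y - X theta) x = 0.

    This is weighted least squares with weights ``exp(tilt)`` — closed form
    for the identity-link mean models used throughout.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    q = np.asarray(tilt, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < p:
        raise ValueError(f"fewer rows ({n}) than parameters ({p})")
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite tilt values")
    w = np.exp(q)
    Xw = X * w[:, None]
    M = Xw.T @ X
    if np.linalg.matrix_rank(M) < p:
        raise np.linalg.LinAlgError("rank-deficient tilted regression design")
    return np.linalg.solve(M, Xw.T @ y)


def default_monotone_design(data: MortalCohortData):
    """(t, s) -> HistoryDesign using the lagged outcome plus all baselines."""
    base = tuple(data.x0.columns)

    def builder(t: int, s: int) -> HistoryDesign:
        feats = ("intercept",) + (("y_last",) if s >= 1 else ()) + base
        return HistoryDesign(feats, mode="monotone")

    return builder


def default_nonmonotone_design(data: MortalCohortData):
    """t -> HistoryDesign with response-pattern encoding plus baselines."""
    base = tuple(data.x0.columns)

    def builder(t: int) -> HistoryDesign:
        feats = ("intercept",) + (("r_last", "ydag_last") if t >= 2 else ()) + base
        return HistoryDesign(feats, mode="nonmonotone")

    return builder


@dataclasses.dataclass
class OutcomeRegressionFit:
    """Fitted tilted-regression coefficients.

    For the monotone pattern ``thetas`` is keyed by ``(t, s)`` (target
    visit, history horizon); for the non-monotone pattern by ``t`` alone.
    Levels that no subject requires are absent.
    """

    mode: str
    thetas: dict
    designs: dict
    qfun: SelectionBiasFunction
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def predict(self, data: MortalCohortData, key) -> np.ndarray:
        """m(history; theta) for every subject (rows with valid history)."""
        s = key[1] if isinstance(key, tuple) else key - 1
        return self.designs[key].matrix(data, s) @ self.thetas[key]


@dataclasses.dataclass
class ImputedData:
    """Original data plus conditional-mean imputations for pre-death gaps.

    ``y_completed`` holds the observed outcome where available and the
    imputation where the subject was alive but unobserved; post-death
    entries stay NaN.  ``source_level`` records the history horizon ``s``
    of the model that produced each imputation (-1 for observed records).
    """

    data: MortalCohortData
    y_completed: np.ndarray
    imputed_mask: np.ndarray
    source_level: np.ndarray

    def to_long_frame(self):
        from .data import to_long_frame
        frame = to_long_frame(self.data)
        frame["y"] = self.y_completed.ravel()
        frame["imputed"] = self.imputed_mask.astype(int).ravel()
        return frame


def _needs_level(data: MortalCohortData, t: int, s: int) -> np.ndarray:
    """Mask of subjects imputed by level (t, s): alive at t, dropped right after s."""
    r_s = data.r[:, s - 1] if s >= 1 else np.ones(data.n_subjects, dtype=np.int8)
    return (data.a[:, t - 1] == 1) & (r_s == 1) & (data.r[:, s] == 0)


def sequential_impute_monotone(data: MortalCohortData, qfun: SelectionBiasFunction,
                               design_builder=None, fit_all_levels: bool = False):
    """Fit the theta_{t,s} grid and impute every pre-death missing outcome.

    Levels with no subject to impute are skipped unless ``fit_all_levels``
    (the augmented estimator needs every level below a subject's dropout
    point, which the recursion covers: a level (t, s) is fitted whenever
    any subject alive at t has been observed through s with s >= the first
    visit at which observation is uncertain).

    Returns ``(OutcomeRegressionFit, ImputedData)``.
    """
    n, J = data.n_subjects, data.n_visits
    builder = design_builder or default_monotone_design(data)
    thetas: dict = {}
    designs: dict = {}
    y_completed = data.y.copy()
    imputed_mask = np.zeros((n, J), dtype=bool)
    source_level = np.full((n, J), -1, dtype=int)

    # history horizons that can ever be a dropout point
    s_min = 0 if (data.r[:, 0] == 0).any() else 1

    for t in range(1, J + 1):
        any_missing_t = ((data.a[:, t - 1] == 1) & (data.r[:, t - 1] == 0)).any()
        if not (any_missing_t or fit_all_levels):
            continue
        for s in range(t - 1, s_min - 1, -1):
            fit_pop = (data.a[:, t - 1] == 1) & (data.r[:, s] == 1)  # observed at s+1
            need = _needs_level(data, t, s)
            if not need.any() and not fit_all_levels:
                # still fit: deeper levels recurse through this one only via
                # subjects observed at s+1, whose pseudo-outcomes are already
                # defined; the level itself is required by the augmentation
                # term whenever observation at s+1 is uncertain.
                pass
            design = builder(t, s)
            X = design.matrix(data, s)
            if fit_pop.sum() < design.dim:
                raise ValueError(f"empty/deficient fitting population at (t={t}, s={s})")
            # response: observed Y_t, or the imputation made at the subject's
            # own dropout level (> s, already processed)
            resp = np.where(data.r[:, t - 1] == 1, np.nan_to_num(data.y[:, t - 1]),
                            np.nan_to_num(y_completed[:, t - 1]))
            if np.isnan(y_completed[fit_pop, t - 1]).any():
                raise RuntimeError("recursion order violated: pseudo-outcome missing")
            r_prev_s = data.r[:, s - 1] if s >= 1 else np.ones(n, dtype=np.int8)
            tilt = qfun(np.nan_to_num(data.y[:, s]), r_prev=r_prev_s)
            theta = fit_tilted_regression(X[fit_pop], resp[fit_pop], tilt[fit_pop])
            thetas[(t, s)] = theta
            designs[(t, s)] = design
            if need.any():
                pred = X[need] @ theta
                y_completed[need, t - 1] = pred
                imputed_mask[need, t - 1] = True
                source_level[need, t - 1] = s

    fit = OutcomeRegressionFit(mode="monotone", thetas=thetas, designs=designs,
                               qfun=qfun)
    pre_death_missing = (data.a == 1) & (data.r == 0)
    if not np.array_equal(imputed_mask, pre_death_missing):
        raise RuntimeError("imputation did not cover exactly the pre-death gaps")
    return fit, ImputedData(data=data, y_completed=y_completed,
                            imputed_mask=imputed_mask, source_level=source_level)


def impute_nonmonotone(data: MortalCohortData, qfun: SelectionBiasFunction,
                       design_builder=None):
    """One tilted regression per visit; impute all unobserved survivors.

    The non-monotone history encoding (R, R*Y products) already carries the
    response pattern, so no recursion is needed and imputed values are
    never fed back into later fits.
    """
    n, J = data.n_subjects, data.n_visits
    builder = design_builder or default_nonmonotone_design(data)
    thetas: dict = {}
    designs: dict = {}
    y_completed = data.y.copy()
    imputed_mask = np.zeros((n, J), dtype=bool)
    source_level = np.full((n, J), -1, dtype=int)

    for t in range(1, J + 1):
        alive = data.a[:, t - 1] == 1
        need = alive & (data.r[:, t - 1] == 0)
        if not need.any():
            continue
        obs = alive & (data.r[:, t - 1] == 1)
        design = builder(t)
        X = design.matrix(data, t - 1)
        if obs.sum() < design.dim:
            raise ValueError(f"empty/deficient fitting population at visit {t}")
        r_prev = data.r[:, t - 2] if t >= 2 else np.ones(n, dtype=np.int8)
        tilt = qfun(np.nan_to_num(data.y[:, t - 1]), r_prev=r_prev)
        theta = fit_tilted_regression(X[obs], data.y[obs, t - 1], tilt[obs])
        thetas[t] = theta
        designs[t] = design
        y_completed[need, t - 1] = X[need] @ theta
        imputed_mask[need, t - 1] = True
        source_level[need, t - 1] = t - 1

    fit = OutcomeRegressionFit(mode="nonmonotone", thetas=thetas, designs=designs,
                               qfun=qfun)
    return fit, ImputedData(data=data, y_completed=y_completed,
                            imputed_mask=imputed_mask, source_level=source_level)
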