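"""Per-visit observation-probability models and inverse-probability weights.

The observation model is a tilted logistic regression:

    P(unobserved) = expit{ h_t(history; alpha_t) + q_t(history, y_t; gamma) }

with ``h_t`` linear in a history design and ``q_t`` a fixed selection-bias
function.  In the monotone pattern the model is for dropout among the
previously observed (``pi_t = P(R_t=1 | R_{t-1}=1, alive)``) and weights
are cumulative products ``lambda_t = prod_{l<=t} pi_l``; in the
non-monotone pattern the model is per-visit (``lambda_t = P(R_t=1 |
history, alive)``) with no product.

``alpha_t`` solves the estimating equation

    sum_i phi_t * A_t * R_{t-1} / pi_t * (R_t - pi_t) = 0

whose summand, after dividing through by ``pi_t``, becomes

    phi_t * A_t * R_{t-1} * [ R_t * exp(h + q) - (1 - R_t) ]

— crucially, the current outcome only enters through records where it is
observed, so positivity is the only requirement.  This score is the
gradient of the strictly convex function ``sum_obs exp(h+q) - sum_miss h``,
which is minimised by damped Newton (with a derivative-free fallback).
The instrument ``phi_t`` is fixed to the ``h_t`` design vector.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize, special

from .data import MortalCohortData
from .design import HistoryDesign
from .selection import SelectionBiasFunction

__all__ = [
    "ObservationModelFit",
    "WeightSet",
    "SeparationError",
    "fit_monotone_missingness",
    "fit_nonmonotone_missingness",
    "fit_missingness_models",
    "observation_probability",
    "cumulative_weights",
]

expit = special.expit


class SeparationError(RuntimeError):
    """The tilted score has no finite root (e.g. no missingness to fit)."""


def _logistic_start(X: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Plain logistic regression of z on X (ignoring the tilt), by IRLS."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(25):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X + 1e-8 * np.eye(p)
        g = X.T @ (z - mu)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
        if np.max(np.abs(beta)) > 50:  # separation in the starting fit; Newton below copes
            break
    return beta


def _solve_tilted_score(X: np.ndarray, robs: np.ndarray, q: np.ndarray,
                        tol: float = 1e-10, max_iter: int = 100):
    """Root of sum_i x_i [r_i e^{x_i a + q_i} - (1 - r_i)] over contributing rows.

    Returns (alpha, iterations, scaled score norm).
    """
    n_rows, p = X.shape
    if n_rows == 0:
        raise SeparationError("no contributing subjects")
    n_miss = int((robs == 0).sum())
    if n_miss == 0:
        raise SeparationError("no missingness to fit: every contributing record observed")
    if int(robs.sum()) == 0:
        raise SeparationError("no observed records among contributors")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix rank-deficient")

    target = X[robs == 0].sum(axis=0)  # sum over missing of x
    Xo = X[robs == 1]
    qo = q[robs == 1]

    def objective(a):
        return np.exp(Xo @ a + qo).sum() - target @ a

    def score(a):
        return Xo.T @ np.exp(Xo @ a + qo) - target

    alpha = _logistic_start(X, 1.0 - robs)
    scale = float(n_rows)
    f = objective(alpha)
    it = 0
    for it in range(1, max_iter + 1):
        g = score(alpha)
        if np.max(np.abs(g)) / scale <= tol:
            return alpha, it, np.max(np.abs(g)) / scale
        w = np.exp(Xo @ alpha + qo)
        H = (Xo * w[:, None]).T @ Xo
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # backtracking line search on the convex objective
        lam = 1.0
        for _ in range(60):
            cand = alpha - lam * step
            fc = objective(cand)
            if fc < f:
                alpha, f = cand, fc
                break
            lam *= 0.5
        else:
            break
        if np.max(np.abs(alpha)) > 1e3:
            raise SeparationError("divergent solution: separation in the observation model")
    g = score(alpha)
    if np.max(np.abs(g)) / scale <= tol:
        return alpha, it, np.max(np.abs(g)) / scale
    sol = optimize.root(score, alpha, method="hybr", tol=1e-12)
    g = score(sol.x)
    if np.max(np.abs(g)) / scale > 1e2 * tol:
        raise RuntimeError(
            f"observation model did not converge (scaled score {np.max(np.abs(g)) / scale:.2e})")
    return sol.x, max_iter, np.max(np.abs(g)) / scale


@dataclasses.dataclass
class ObservationModelFit:
    """Fitted per-visit observation model.

    ``alpha`` is ``None`` for the trivial always-observed visit-1 model
    (probability identically 1).
    """

    t: int
    design: HistoryDesign | None
    qfun: SelectionBiasFunction
    mode: str
    alpha: np.ndarray | None
    iterations: int = 0
    score_norm: float = 0.0
    n_contributing: int = 0

    @property
    def trivial(self) -> bool:
        return self.alpha is None

    def linear_predictor(self, data: MortalCohortData) -> np.ndarray:
        """h_t for every subject (valid wherever the design is)."""
        if self.trivial:
            return np.full(data.n_subjects, -np.inf)
        return self.design.matrix(data, self.t - 1) @ self.alpha

    def prob_observed(self, data: MortalCohortData,
                      y_t: np.ndarray | None = None) -> np.ndarray:
        """pi_t (monotone) or lambda_t (non-monotone) per subject.

        Requires the visit-t outcome; by default taken from the data (NaN
        where unobserved), or overridden by ``y_t`` in simulation oracles.
        """
        if self.trivial:
            return np.ones(data.n_subjects)
        y = data.y[:, self.t - 1] if y_t is None else np.asarray(y_t, dtype=float)
        r_prev = data.r[:, self.t - 2] if self.t >= 2 else np.ones(data.n_subjects)
        h = self.linear_predictor(data)
        q = self.qfun(np.nan_to_num(y), r_prev=r_prev)
        p = 1.0 - expit(h + q)
        return np.where(np.isnan(y), np.nan, p)


def _fit_visit(data: MortalCohortData, design: HistoryDesign,
               qfun: SelectionBiasFunction, t: int, mode: str) -> ObservationModelFit:
    if mode == "monotone":
        mask = (data.a[:, t - 1] == 1)
        if t >= 2:
            mask &= (data.r[:, t - 2] == 1)
    else:
        mask = data.a[:, t - 1] == 1
    X = design.matrix(data, t - 1)
    robs = data.r[:, t - 1].astype(float)
    r_prev = data.r[:, t - 2] if t >= 2 else np.ones(data.n_subjects)
    q = qfun(np.nan_to_num(data.y[:, t - 1]), r_prev=r_prev)
    q = np.where(robs == 1, q, 0.0)  # tilt only enters through observed records
    alpha, it, norm = _solve_tilted_score(X[mask], robs[mask], q[mask])
    return ObservationModelFit(t=t, design=design, qfun=qfun, mode=mode,
                               alpha=alpha, iterations=it, score_norm=norm,
                               n_contributing=int(mask.sum()))


def fit_monotone_missingness(data: MortalCohortData, design: HistoryDesign,
                             qfun: SelectionBiasFunction, t: int) -> ObservationModelFit:
    """Fit the dropout-hazard model pi_t among {alive, observed at t-1}."""
    return _fit_visit(data, design, qfun, t, "monotone")


def fit_nonmonotone_missingness(data: MortalCohortData, design: HistoryDesign,
                                qfun: SelectionBiasFunction, t: int) -> ObservationModelFit:
    """Fit the per-visit observation model lambda_t among the alive."""
    return _fit_visit(data, design, qfun, t, "nonmonotone")


def fit_missingness_models(data: MortalCohortData, designs, qfun: SelectionBiasFunction,
                           mode: str) -> dict[int, ObservationModelFit]:
    """Fit every visit's model; visit 1 is trivial when nobody is missing there.

    ``designs`` maps visit -> HistoryDesign (visit 1 may be absent if its
    observation is certain in the data).
    """
    J = data.n_visits
    fits: dict[int, ObservationModelFit] = {}
    for t in range(1, J + 1):
        if t == 1 and (data.r[:, 0] == 1).all():
            fits[1] = ObservationModelFit(t=1, design=None, qfun=qfun, mode=mode,
                                          alpha=None)
            continue
        if t not in designs:
            raise ValueError(f"no design supplied for visit {t}")
        fits[t] = _fit_visit(data, designs[t], qfun, t, mode)
    return fits


def observation_probability(fit: ObservationModelFit, history_row: np.ndarray,
                            y_t: float, r_prev: int = 1) -> float:
    """1 - expit(h + q) for a single evaluated history row."""
    if fit.trivial:
        return 1.0
    h = float(np.asarray(history_row, dtype=float) @ fit.alpha)
    q = float(fit.qfun(y_t, r_prev=r_prev))
    lin = h + q
    if not np.isfinite(lin):
        raise ValueError("non-finite linear predictor")
    return float(1.0 - expit(lin))


@dataclasses.dataclass
class WeightSet:
    """Observation probabilities and inverse-probability weights.

    ``pi`` holds the per-visit model probabilities; ``lam`` the cumulative
    product (monotone) or a copy of ``pi`` (non-monotone).  Entries are NaN
    where undefined (outcome unobserved).  ``lambda_0 = 1`` by convention.
    """

    pi: np.ndarray
    lam: np.ndarray
    mode: str
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def weights(self, data: MortalCohortData) -> np.ndarray:
        """1/lambda_t on observed survivor records, 0 elsewhere."""
        ok = (data.r == 1) & (data.a == 1)
        w = np.zeros_like(self.lam)
        w[ok] = 1.0 / self.lam[ok]
        return w


def cumulative_weights(data: MortalCohortData, fits: dict[int, ObservationModelFit],
                       mode: str = "monotone", floor_warn: float = 0.01) -> WeightSet:
    """Assemble per-subject observation probabilities into a WeightSet.

    Emits a diagnostic summary (min/max probability, effective sample size)
    and warns when any probability falls below ``floor_warn``.  No
    truncation is applied.
    """
    n, J = data.n_subjects, data.n_visits
    pi = np.full((n, J), np.nan)
    for t in range(1, J + 1):
        if t not in fits:
            raise ValueError(f"missing observation-model fit for visit {t}")
        pi[:, t - 1] = fits[t].prob_observed(data)
    obs = (data.r == 1) & (data.a == 1)
    if np.isnan(pi[obs]).any():
        raise ValueError("observation probability undefined at an observed record")
    if mode == "monotone":
        lam = np.cumprod(np.where(data.r == 1, pi, 1.0), axis=1)
        lam = np.where(data.r == 1, lam, np.nan)
    else:
        lam = np.where(data.r == 1, pi, np.nan)
    pmin = float(np.nanmin(lam[obs])) if obs.any() else np.nan
    w = 1.0 / lam[obs]
    ess = float(w.sum() ** 2 / (w ** 2).sum()) if obs.any() else 0.0
    if obs.any() and pmin < floor_warn:
        warnings.warn(f"minimum observation probability {pmin:.4f} below {floor_warn}",
                      RuntimeWarning)
    diags = {"min_prob": pmin,
             "max_weight": float(np.max(w)) if obs.any() else np.nan,
             "ess": ess}
    return WeightSet(pi=pi, lam=lam, mode=mode, diagnostics=diags)
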