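"""Marginal (partly conditional) mean-model estimators.

The estimand is the identity-link marginal model ``mu_t(Z; beta)`` for the
mean outcome among survivors at each visit, fitted by independence
estimating equations (IEE) in four flavours:

* ``iee``  — unweighted, on whatever outcomes are available;
* ``ipw``  — observed survivor records weighted by 1/lambda_t;
* ``cmor`` — IEE applied to the tilted-imputation completed data;
* ``aipw`` — the augmented equations combining both nuisances, doubly
  robust (all-visits robustness in the monotone pattern, per-visit in the
  non-monotone pattern).

With an identity link every equation is linear in beta, so each estimator
is a single weighted linear solve — no iterative GEE loop is needed.
Subjects contribute at visit t only while alive (the A_t factor).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import MortalCohortData
from .missingness import WeightSet
from .regression import ImputedData, OutcomeRegressionFit

__all__ = [
    "MarginalModel",
    "MarginalFit",
    "fit_iee",
    "fit_ipw",
    "fit_aipw_monotone",
    "fit_aipw_nonmonotone",
]


class MarginalModel:
    """Identity-link design for mu_t(Z; beta).

    Terms: ``"intercept"``, ``"visit:k"`` (indicator of visit k),
    ``"year"`` (2*(t-1)), ``"year2"``, a baseline covariate name, or
    ``"year*<name>"`` interactions.  The default is the saturated time
    model: intercept plus indicators for visits 2..J, whose coefficients
    are the visit-1 survivor mean and the survivor-mean contrasts.
    """

    def __init__(self, J: int, terms: tuple[str, ...] | None = None):
        self.J = J
        if terms is None:
            terms = ("intercept",) + tuple(f"visit:{t}" for t in range(2, J + 1))
        self.terms = tuple(terms)

    @classmethod
    def saturated(cls, J: int) -> "MarginalModel":
        return cls(J)

    @property
    def dim(self) -> int:
        return len(self.terms)

    def design(self, data: MortalCohortData) -> np.ndarray:
        """(n, J, p) design array (broadcast when subject-invariant)."""
        n, J = data.n_subjects, self.J
        t_idx = np.arange(1, J + 1, dtype=float)
        year = 2.0 * (t_idx - 1)
        cols = []
        for term in self.terms:
            if term == "intercept":
                cols.append(np.broadcast_to(np.ones(J), (n, J)))
            elif term.startswith("visit:"):
                k = int(term.split(":")[1])
                cols.append(np.broadcast_to((t_idx == k).astype(float), (n, J)))
            elif term == "year":
                cols.append(np.broadcast_to(year, (n, J)))
            elif term == "year2":
                cols.append(np.broadcast_to(year ** 2, (n, J)))
            elif term.startswith("year*"):
                z = data.baseline(term.split("*", 1)[1])
                cols.append(z[:, None] * year[None, :])
            else:
                z = data.baseline(term)
                cols.append(np.broadcast_to(z[:, None], (n, J)))
        return np.stack(cols, axis=-1)


@dataclasses.dataclass
class MarginalFit:
    """beta estimates with provenance and (optionally attached) covariance."""

    beta: np.ndarray
    model: MarginalModel
    method: str
    mode: str
    cov: np.ndarray | None = None
    cov_method: str | None = None
    diagnostics: dict = dataclasses.field(default_factory=dict)

    @property
    def se(self) -> np.ndarray | None:
        return None if self.cov is None else np.sqrt(np.diag(self.cov))

    def conf_int(self, level: float = 0.95) -> np.ndarray | None:
        if self.cov is None:
            return None
        from scipy import stats
        zq = stats.norm.ppf(0.5 + level / 2)
        se = self.se
        return np.column_stack([self.beta - zq * se, self.beta + zq * se])


def _solve(B: np.ndarray, coef: np.ndarray, ypart: np.ndarray) -> np.ndarray:
    """Solve sum_it B_it' (ypart_it - coef_it * B_it beta) = 0."""
    M = np.einsum("ntp,ntq,nt->pq", B, B, coef)
    v = np.einsum("ntp,nt->p", B, ypart)
    if np.linalg.matrix_rank(M) < M.shape[0]:
        raise np.linalg.LinAlgError("rank-deficient marginal design")
    return np.linalg.solve(M, v)


def fit_iee(data: MortalCohortData, model: MarginalModel | None = None,
            imputed: ImputedData | None = None, method_label: str = "iee") -> MarginalFit:
    """Unweighted independence estimating equations on available outcomes.

    With ``imputed`` supplied, runs on the completed outcomes — which *is*
    the CMOR estimator of beta.
    """
    model = model or MarginalModel.saturated(data.n_visits)
    if imputed is not None:
        y = imputed.y_completed
        avail = (data.a == 1) & ~np.isnan(y)
    else:
        y = data.y
        avail = (data.a == 1) & (data.r == 1)
    B = model.design(data)
    w = avail.astype(float)
    beta = _solve(B, w, w * np.nan_to_num(y))
    return MarginalFit(beta=beta, model=model, method=method_label,
                       mode="any", diagnostics={"n_records": int(avail.sum())})


def fit_ipw(data: MortalCohortData, weights: WeightSet,
            model: MarginalModel | None = None) -> MarginalFit:
    """Inverse-probability-weighted equations on observed survivor records."""
    model = model or MarginalModel.saturated(data.n_visits)
    B = model.design(data)
    w = weights.weights(data)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite inverse-probability weight")
    obs = (data.r == 1) & (data.a == 1)
    if np.any(obs & (w == 0)):
        raise ValueError("missing weight at an observed survivor record")
    beta = _solve(B, w, w * np.nan_to_num(data.y))
    return MarginalFit(beta=beta, model=model, method="ipw", mode=weights.mode,
                       diagnostics=dict(weights.diagnostics))


def _augmentation_terms(data: MortalCohortData, weights: WeightSet,
                        regression: OutcomeRegressionFit):
    """Per-(subject, visit) coefficient and outcome parts of the monotone
    augmented equations.

    For visit t the bracket is

        R_t (Y_t - mu) / lambda_t
        + sum_{l=0}^{t-1} (R_l/lambda_l) (1 - R_{l+1}/pi_{l+1}) (m_{t,l} - mu)

    computed so that an unobserved Y_{l+1} is never touched: the factor is
    exactly 1 when R_{l+1} = 0.  Conventions R_0 = 1, lambda_0 = 1.
    """
    n, J = data.n_subjects, data.n_visits
    R = data.r.astype(float)
    A = data.a.astype(float)
    pi = np.where(R == 1, np.nan_to_num(weights.pi, nan=1.0), 1.0)
    lam_run = np.cumprod(pi, axis=1)  # = lambda_t along each observed prefix

    # F[:, l] for l = 0..J-1 (l visits, 0 = baseline): (R_l/lam_l)(1 - R_{l+1}/pi_{l+1})
    F = np.zeros((n, J))
    for l in range(0, J):
        if l == 0:
            r_l = np.ones(n)
            lam_l = np.ones(n)
        else:
            r_l = R[:, l - 1]
            lam_l = lam_run[:, l - 1]
        r_next = R[:, l]
        inner = np.where(r_next == 1, 1.0 - 1.0 / pi[:, l], 1.0)
        F[:, l] = np.where(r_l == 1, inner / lam_l, 0.0)

    coef = np.zeros((n, J))
    ypart = np.zeros((n, J))
    for t in range(1, J + 1):
        alive = A[:, t - 1]
        r_t = R[:, t - 1]
        inv_lam = np.where(r_t == 1, 1.0 / lam_run[:, t - 1], 0.0)
        c = r_t * inv_lam
        yp = r_t * inv_lam * np.nan_to_num(data.y[:, t - 1])
        for l in range(0, t):
            f = F[:, l] * alive  # A_t multiplies the whole bracket
            if not np.any(f):
                continue
            key = (t, l)
            if key not in regression.thetas:
                raise ValueError(f"missing outcome-regression fit for level {key}")
            m = regression.predict(data, key)
            c = c + f
            yp = yp + f * m
        coef[:, t - 1] = alive * c
        ypart[:, t - 1] = alive * yp
    return coef, ypart


def fit_aipw_monotone(data: MortalCohortData, weights: WeightSet,
                      regression: OutcomeRegressionFit,
                      model: MarginalModel | None = None) -> MarginalFit:
    """Doubly robust augmented equations for the monotone pattern.

    Consistent when either the missingness models (all visits) or the
    outcome regressions (all levels) are correctly specified, given the
    selection-bias function.  Reduces exactly to IEE when nothing is
    missing among the alive.
    """
    model = model or MarginalModel.saturated(data.n_visits)
    coef, ypart = _augmentation_terms(data, weights, regression)
    beta = _solve(model.design(data), coef, ypart)
    return MarginalFit(beta=beta, model=model, method="aipw", mode="monotone",
                       diagnostics=dict(weights.diagnostics))


def fit_aipw_nonmonotone(data: MortalCohortData, weights: WeightSet,
                         regression: OutcomeRegressionFit,
                         model: MarginalModel | None = None) -> MarginalFit:
    """Per-visit doubly robust augmented equations (non-monotone pattern).

    The visit-t bracket is R_t(Y_t - mu)/lambda_t + (1 - R_t/lambda_t)
    (m_t - mu); when R_t = 0 the first term vanishes and lambda_t is never
    evaluated at the unobserved outcome.
    """
    model = model or MarginalModel.saturated(data.n_visits)
    n, J = data.n_subjects, data.n_visits
    R, A = data.r.astype(float), data.a.astype(float)
    lam = np.where(R == 1, weights.lam, 1.0)
    coef = np.zeros((n, J))
    ypart = np.zeros((n, J))
    for t in range(1, J + 1):
        alive = A[:, t - 1]
        r_t = R[:, t - 1]
        inv = np.where(r_t == 1, 1.0 / lam[:, t - 1], 0.0)
        aug = 1.0 - r_t * inv
        if t in regression.thetas:
            m = regression.predict(data, t)
        elif np.any((alive == 1) & (aug != 0.0)):
            raise ValueError(f"missing outcome-regression fit for visit {t}")
        else:
            m = np.zeros(n)
        coef[:, t - 1] = alive * (r_t * inv + aug)
        ypart[:, t - 1] = alive * (r_t * inv * np.nan_to_num(data.y[:, t - 1]) + aug * m)
    beta = _solve(model.design(data), coef, ypart)
    return MarginalFit(beta=beta, model=model, method="aipw", mode="nonmonotone",
                       diagnostics=dict(weights.diagnostics))
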