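"""Variance estimation: stacked M-estimation sandwich and the bootstrap.

Every estimator in this package is the root of a stack of per-subject
estimating functions — observation-model scores (alpha blocks), tilted
regression scores (theta blocks) and the marginal equations (beta block).
The sandwich covariance is the generic M-estimator form

    cov = A^{-1} B A^{-T} / n,

with A the Jacobian of the mean stacked estimating function (numeric
central differences) and B the empirical outer product of the per-subject
stack; the beta block of the full covariance accounts for the estimation
of all nuisance parameters.  Robust variances of this kind are known to
undercover at small n; the subject-resampling bootstrap is the
recommended alternative and reruns the entire pipeline per replicate.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy import special, stats

from .data import MortalCohortData
from .estimators import MarginalFit, MarginalModel
from .missingness import ObservationModelFit
from .regression import OutcomeRegressionFit
from .selection import SelectionBiasFunction

__all__ = [
    "VarianceEstimate",
    "StackedSystem",
    "build_stacked_system",
    "sandwich_variance",
    "bootstrap_variance",
]

expit = special.expit


@dataclasses.dataclass
class VarianceEstimate:
    """Covariance for beta with Wald-type intervals."""

    cov: np.ndarray
    method: str
    beta: np.ndarray | None = None
    B: int | None = None
    seed: int | None = None
    n_failed: int = 0
    full_cov: np.ndarray | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        if self.beta is None:
            raise ValueError("no point estimate attached")
        zq = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.beta - zq * self.se, self.beta + zq * self.se])


class StackedSystem:
    """Per-subject stacked estimating functions with named parameter blocks.

    ``psi(eta)`` returns an (n, p) array; the fitted parameter vector
    ``eta_hat`` should make its column sums (numerically) zero.
    """

    def __init__(self, data: MortalCohortData, method: str, mode: str,
                 qfun: SelectionBiasFunction, model: MarginalModel,
                 beta: np.ndarray,
                 miss_fits: dict[int, ObservationModelFit] | None,
                 regression: OutcomeRegressionFit | None):
        self.n = data.n_subjects
        self.J = data.n_visits
        self.method = method
        self.mode = mode
        n, J = self.n, self.J
        self.R = data.r.astype(float)
        self.A = data.a.astype(float)
        self.yfill = np.nan_to_num(data.y)
        self.Bdes = model.design(data)

        use_alpha = method in ("ipw", "aipw")
        use_theta = method in ("cmor", "aipw")

        # --- alpha blocks ------------------------------------------------
        self.alpha_visits: list[int] = []
        self.alpha_X: dict[int, np.ndarray] = {}
        self.alpha_mask: dict[int, np.ndarray] = {}
        self.alpha_q: dict[int, np.ndarray] = {}
        eta_parts: list[np.ndarray] = []
        blocks: list[tuple[str, int]] = []
        if use_alpha:
            for t in sorted(miss_fits):
                fit = miss_fits[t]
                if fit.trivial:
                    continue
                self.alpha_visits.append(t)
                X = fit.design.matrix(data, t - 1)
                if mode == "monotone":
                    mask = self.A[:, t - 1] == 1
                    if t >= 2:
                        mask &= self.R[:, t - 2] == 1
                else:
                    mask = self.A[:, t - 1] == 1
                r_prev = data.r[:, t - 2] if t >= 2 else np.ones(n)
                q = qfun(self.yfill[:, t - 1], r_prev=r_prev)
                q = np.where(self.R[:, t - 1] == 1, q, 0.0)
                self.alpha_X[t] = np.where(mask[:, None], X, 0.0)
                self.alpha_mask[t] = mask.astype(float)
                self.alpha_q[t] = q
                blocks.append((f"alpha_{t}", X.shape[1]))
                eta_parts.append(np.asarray(fit.alpha, dtype=float))
        self.trivial_visits = ({t for t, f in miss_fits.items() if f.trivial}
                               if miss_fits else set())

        # --- theta blocks ------------------------------------------------
        self.theta_keys: list = []
        self.theta_D: dict = {}
        self.theta_fitmask: dict = {}
        self.theta_w: dict = {}
        if use_theta:
            keys = sorted(regression.thetas,
                          key=lambda k: (k if isinstance(k, tuple) else (k, -1)))
            for key in keys:
                if isinstance(key, tuple):
                    t, s = key
                    fitmask = (self.A[:, t - 1] == 1) & (self.R[:, s] == 1)
                    r_prev = data.r[:, s - 1] if s >= 1 else np.ones(n)
                    tilt = qfun(self.yfill[:, s], r_prev=r_prev)
                    smat = s
                else:
                    t = key
                    fitmask = (self.A[:, t - 1] == 1) & (self.R[:, t - 1] == 1)
                    r_prev = data.r[:, t - 2] if t >= 2 else np.ones(n)
                    tilt = qfun(self.yfill[:, t - 1], r_prev=r_prev)
                    smat = t - 1
                D = regression.designs[key].matrix(data, smat)
                self.theta_keys.append(key)
                # rows outside the fitting mask carry zero weight in the
                # score but the design stays usable for predictions
                self.theta_D[key] = D
                self.theta_fitmask[key] = fitmask.astype(float)
                self.theta_w[key] = np.where(fitmask, np.exp(tilt), 0.0)
                blocks.append((f"theta_{key}", D.shape[1]))
                eta_parts.append(np.asarray(regression.thetas[key], dtype=float))
        # last observed visit per subject (1-based); needed for monotone
        # pseudo-outcomes
        robs = data.r == 1
        self.lastobs = np.where(robs.any(axis=1),
                                J - np.argmax(robs[:, ::-1], axis=1), 0)

        blocks.append(("beta", model.dim))
        eta_parts.append(np.asarray(beta, dtype=float))
        self.blocks = blocks
        self.eta_hat = np.concatenate(eta_parts)
        self.slices: dict[str, slice] = {}
        pos = 0
        for name, size in blocks:
            self.slices[name] = slice(pos, pos + size)
            pos += size
        self.p = pos
        self.beta_slice = self.slices["beta"]

    # -- parameter unpacking helpers --------------------------------------
    def _alphas(self, eta):
        return {t: eta[self.slices[f"alpha_{t}"]] for t in self.alpha_visits}

    def _thetas(self, eta):
        return {k: eta[self.slices[f"theta_{k}"]] for k in self.theta_keys}

    # -- model components at arbitrary parameter values --------------------
    def _pi(self, alphas):
        """(n, J) observation probabilities, 1 where not modelled/observed."""
        n, J = self.n, self.J
        pi = np.ones((n, J))
        for t in self.alpha_visits:
            lin = self.alpha_X[t] @ alphas[t] + self.alpha_q[t]
            p = 1.0 - expit(lin)
            pi[:, t - 1] = np.where(self.R[:, t - 1] == 1, p, 1.0)
        return pi

    def _preds(self, thetas):
        """m predictions per theta key (valid on each fitting mask)."""
        return {k: self.theta_D[k] @ thetas[k] for k in self.theta_keys}

    def _pseudo_by_t(self, preds):
        """Monotone completed outcome per visit: observed Y_t or the
        imputation from the subject's own dropout level."""
        out = {}
        by_t: dict[int, list] = {}
        for k in self.theta_keys:
            if isinstance(k, tuple):
                by_t.setdefault(k[0], []).append(k[1])
        for t, levels in by_t.items():
            m_last = np.zeros(self.n)
            miss = (self.R[:, t - 1] == 0) & (self.A[:, t - 1] == 1)
            for s in levels:
                sel = miss & (self.lastobs == s)
                if sel.any():
                    m_last[sel] = preds[(t, s)][sel]
            out[t] = np.where(self.R[:, t - 1] == 1, self.yfill[:, t - 1], m_last)
        return out

    def psi(self, eta: np.ndarray) -> np.ndarray:
        """(n, p) per-subject stacked estimating functions at ``eta``."""
        n, J = self.n, self.J
        out = np.zeros((n, self.p))
        alphas = self._alphas(eta) if self.alpha_visits else {}
        thetas = self._thetas(eta) if self.theta_keys else {}

        for t in self.alpha_visits:
            X = self.alpha_X[t]
            lin = X @ alphas[t] + self.alpha_q[t]
            r_t = self.R[:, t - 1]
            val = self.alpha_mask[t] * (r_t * np.exp(np.where(r_t == 1, lin, 0.0))
                                        - (1.0 - r_t))
            out[:, self.slices[f"alpha_{t}"]] = X * val[:, None]

        preds = self._preds(thetas) if self.theta_keys else {}
        pseudo = (self._pseudo_by_t(preds)
                  if self.theta_keys and self.mode == "monotone" else {})
        for k in self.theta_keys:
            if isinstance(k, tuple):
                resid = pseudo[k[0]] - preds[k]
            else:
                resid = self.yfill[:, k - 1] - preds[k]
            val = self.theta_w[k] * resid
            out[:, self.slices[f"theta_{k}"]] = self.theta_D[k] * val[:, None]

        beta = eta[self.beta_slice]
        mu = np.einsum("ntp,p->nt", self.Bdes, beta)
        coef = np.zeros((n, J))
        ypart = np.zeros((n, J))
        R, A, y = self.R, self.A, self.yfill
        if self.method == "ipw" or self.method == "aipw":
            pi = self._pi(alphas)
            lam = np.cumprod(pi, axis=1) if self.mode == "monotone" else pi
        if self.method == "ipw":
            inv = np.where(R == 1, 1.0 / lam, 0.0)
            coef = A * R * inv
            ypart = coef * y
        elif self.method == "cmor":
            for t in range(1, J + 1):
                yc = pseudo.get(t) if self.mode == "monotone" else None
                if self.mode == "nonmonotone":
                    if t in self.theta_keys:
                        yc = np.where(R[:, t - 1] == 1, y[:, t - 1], preds[t])
                    else:
                        yc = y[:, t - 1]
                if yc is None:
                    yc = y[:, t - 1]
                    avail = A[:, t - 1] * R[:, t - 1]
                else:
                    avail = A[:, t - 1]
                coef[:, t - 1] = avail
                ypart[:, t - 1] = avail * yc
        elif self.method == "aipw":
            if self.mode == "monotone":
                F = np.zeros((n, J))
                for l in range(J):
                    r_l = np.ones(n) if l == 0 else R[:, l - 1]
                    lam_l = np.ones(n) if l == 0 else lam[:, l - 1]
                    inner = np.where(R[:, l] == 1, 1.0 - 1.0 / pi[:, l], 1.0)
                    F[:, l] = np.where(r_l == 1, inner / lam_l, 0.0)
                for t in range(1, J + 1):
                    r_t = R[:, t - 1]
                    inv = np.where(r_t == 1, 1.0 / lam[:, t - 1], 0.0)
                    c = r_t * inv
                    yp = c * y[:, t - 1]
                    for l in range(t):
                        key = (t, l)
                        f = F[:, l]
                        if key in self.theta_D:
                            c = c + f
                            yp = yp + f * preds[key]
                        # keys absent only where F is identically zero
                    coef[:, t - 1] = A[:, t - 1] * c
                    ypart[:, t - 1] = A[:, t - 1] * yp
            else:
                inv = np.where(R == 1, 1.0 / lam, 0.0)
                for t in range(1, J + 1):
                    r_t = R[:, t - 1]
                    aug = 1.0 - r_t * inv[:, t - 1]
                    m = preds[t] if t in self.theta_D else np.zeros(n)
                    coef[:, t - 1] = A[:, t - 1]
                    ypart[:, t - 1] = A[:, t - 1] * (
                        r_t * inv[:, t - 1] * y[:, t - 1] + aug * m)
        else:  # plain iee
            avail = A * R
            coef = avail
            ypart = avail * y
        out[:, self.beta_slice] = np.einsum("ntp,nt->np", self.Bdes, ypart - coef * mu)
        return out


def build_stacked_system(data: MortalCohortData, method: str, mode: str,
                         qfun: SelectionBiasFunction, model: MarginalModel,
                         fit: MarginalFit,
                         miss_fits: dict[int, ObservationModelFit] | None = None,
                         regression: OutcomeRegressionFit | None = None) -> StackedSystem:
    """Assemble the stacked per-subject system for a fitted estimator."""
    if method in ("ipw", "aipw") and miss_fits is None:
        raise ValueError(f"{method} requires missingness fits")
    if method in ("cmor", "aipw") and regression is None:
        raise ValueError(f"{method} requires outcome-regression fits")
    return StackedSystem(data, method, mode, qfun, model, fit.beta,
                         miss_fits, regression)


def sandwich_variance(system: StackedSystem, step: float = 1e-6) -> VarianceEstimate:
    """A^{-1} B A^{-T} / n for the stacked system; returns the beta block.

    A is computed by central differences of the mean estimating function
    with per-coordinate step ``step * max(1, |eta_j|)``.
    """
    eta = system.eta_hat
    n, p = system.n, system.p
    psi0 = system.psi(eta)
    Bmat = psi0.T @ psi0 / n
    A = np.empty((p, p))
    for j in range(p):
        h = step * max(1.0, abs(eta[j]))
        ep = eta.copy(); ep[j] += h
        em = eta.copy(); em[j] -= h
        A[:, j] = (system.psi(ep).sum(axis=0) - system.psi(em).sum(axis=0)) / (2 * h * n)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular Jacobian in sandwich variance") from exc
    full = Ainv @ Bmat @ Ainv.T / n
    full = 0.5 * (full + full.T)
    bsl = system.beta_slice
    return VarianceEstimate(cov=full[bsl, bsl], method="sandwich",
                            beta=eta[bsl].copy(), full_cov=full)


def bootstrap_variance(data: MortalCohortData, fit_fn: Callable[[MortalCohortData], np.ndarray],
                       B: int = 1000, seed: int = 0,
                       max_fail_frac: float = 0.05) -> VarianceEstimate:
    """Subject-level nonparametric bootstrap of the full pipeline.

    ``fit_fn`` must rerun every nuisance fit and return the beta vector.
    Replicates where any solver fails are dropped and counted; more than
    ``max_fail_frac`` failures is an error.  Replicate streams are seeded
    by (seed, replicate index) so any single replicate is re-runnable.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    n = data.n_subjects
    betas = []
    failed = 0
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        idx = rng.integers(0, n, n)
        try:
            betas.append(np.asarray(fit_fn(data.take(idx)), dtype=float))
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failed += 1
    if failed > max_fail_frac * B:
        raise RuntimeError(f"{failed}/{B} bootstrap replicates failed")
    mat = np.vstack(betas)
    cov = np.cov(mat, rowvar=False)
    cov = np.atleast_2d(cov)
    return VarianceEstimate(cov=cov, method="bootstrap", B=B, seed=seed,
                            n_failed=failed)
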