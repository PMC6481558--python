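"""Benchmark data-generating processes and the Monte-Carlo harness.

Two five-visit (biennial, ``year_t = 2(t-1)``) mortal-cohort designs with
non-ignorable missingness are implemented, one with absorbing dropout
(monotone) and one with intermittent missingness (non-monotone).  Both
share a baseline covariate ``X ~ Normal(2, sd 4)``, its transform
``U = |X|^1.5``, outcome noise of unit variance, a survival process
depending on the previous outcome, and a missingness process depending on
the *current* outcome through a linear tilt with gamma = -0.2:

* first outcome:  Y_1 | X ~ Normal(5 - 0.1 U, 1); R_1 = A_1 = 1 surely;
* survival:       P(A_t=1 | A_{t-1}=1) = expit(1.5 + 0.15 Y_{t-1} - 0.05 U);
* monotone:       Y_t ~ Normal(5 - 0.2 year_t - 0.1 U + 0.05 Y_{t-1}, 1),
                  P(R_t=0 | R_{t-1}=1) = expit(-0.75 - 0.175 Y_{t-1}
                                               + 0.1 U - 0.2 Y_t);
* non-monotone:   Y_t ~ Normal(5 + a_r year_t - 0.1 U + 0.05 Y_{t-1}, 1)
                  with a_1 = -0.2 when the previous outcome was observed
                  and a_0 = -0.4 otherwise, and
                  P(R_t=0) = expit(0.1 - 0.175 Ydag_{t-1} + 0.1 U - 0.2 Y_t)
                  where Ydag is the observed-or-zero previous outcome.

Because the non-monotone outcome mean depends on the previous response,
outcomes and response indicators must be generated jointly visit by
visit.  The marginal estimand is the saturated survivor-mean model, whose
true parameters are obtained by oracle simulation with the missingness
mask never applied (or 1-D quadrature for the first visit).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special

from .data import MortalCohortData
from .design import HistoryDesign
from .estimators import MarginalModel
from .pipeline import FitRecipe, fit_survivor_means
from .selection import SelectionBiasFunction

__all__ = [
    "SimulationDesign",
    "simulate_monotone",
    "simulate_nonmonotone",
    "true_beta",
    "run_replication_study",
    "sensitivity_grid",
    "ReplicationSummary",
    "analysis_designs",
]

expit = special.expit


@dataclasses.dataclass
class SimulationDesign:
    """Full parameterisation of one benchmark study.

    The defaults are the study conditions; ``scenario`` names which model
    designs the *analysis* misspecifies (the data generation never
    changes): monotone — ``"missingness"``/``"regression"``/``"all"``
    replace U by X in the named models; non-monotone — ``"m4h5"`` omits U
    from the visit-4 regression and visit-5 missingness models, ``"all"``
    omits U everywhere.
    """

    study: str = "monotone"
    n: int = 500
    J: int = 5
    x_mean: float = 2.0
    x_sd: float = 4.0
    y1_coef: tuple = (5.0, -0.1)              # intercept, U
    surv_coef: tuple = (1.5, 0.15, -0.05)     # intercept, Y_{t-1}, U
    out_year: float = -0.2                    # monotone year slope
    out_coef: tuple = (5.0, -0.1, 0.05)       # intercept, U, Y_{t-1}
    dgp_alpha1: float = -0.2                  # non-monotone year slope, prev observed
    dgp_alpha0: float = -0.4                  # non-monotone year slope, prev missing
    miss_coef_monotone: tuple = (-0.75, -0.175, 0.1)   # intercept, Y_{t-1}, U
    miss_coef_nonmonotone: tuple = (0.1, -0.175, 0.1)  # intercept, Ydag_{t-1}, U
    gamma_true: float = -0.2
    scenario: str = "none"
    seed: int = 0

    def __post_init__(self):
        if self.study not in ("monotone", "nonmonotone"):
            raise ValueError(f"unknown study {self.study!r}")

    def year(self, t: int) -> float:
        return 2.0 * (t - 1)


def _simulate(design: SimulationDesign, rng: np.random.Generator):
    """Shared generator; returns (X, U, Yfull, A, R) with Yfull unmasked."""
    n, J = design.n, design.J
    X = rng.normal(design.x_mean, design.x_sd, n)
    U = np.abs(X) ** 1.5
    Y = np.empty((n, J))
    A = np.ones((n, J), dtype=np.int8)
    R = np.ones((n, J), dtype=np.int8)
    b0, bU = design.y1_coef
    Y[:, 0] = rng.normal(b0 + bU * U, 1.0)
    s0, sY, sU = design.surv_coef
    monotone = design.study == "monotone"
    for t in range(2, J + 1):
        j = t - 1
        alive_prev = A[:, j - 1] == 1
        p_surv = expit(s0 + sY * Y[:, j - 1] + sU * U)
        A[:, j] = np.where(alive_prev, (rng.random(n) < p_surv), 0).astype(np.int8)
        alive = A[:, j] == 1
        o0, oU, oY = design.out_coef
        if monotone:
            mean = o0 + design.out_year * design.year(t) + oU * U + oY * Y[:, j - 1]
        else:
            slope = np.where(R[:, j - 1] == 1, design.dgp_alpha1, design.dgp_alpha0)
            mean = o0 + slope * design.year(t) + oU * U + oY * Y[:, j - 1]
        Y[:, j] = np.where(alive, rng.normal(mean, 1.0), np.nan)
        if monotone:
            m0, mY, mU = design.miss_coef_monotone
            p_miss = expit(m0 + mY * Y[:, j - 1] + mU * U
                           + design.gamma_true * Y[:, j])
            at_risk = alive & (R[:, j - 1] == 1)
        else:
            m0, mY, mU = design.miss_coef_nonmonotone
            ydag = np.where(R[:, j - 1] == 1, Y[:, j - 1], 0.0)
            p_miss = expit(m0 + mY * ydag + mU * U + design.gamma_true * Y[:, j])
            at_risk = alive
        R[:, j] = np.where(at_risk, (rng.random(n) >= p_miss), 0).astype(np.int8)
    return X, U, Y, A, R


def _package(X, U, Y, A, R) -> MortalCohortData:
    J = Y.shape[1]
    y_masked = np.where(R == 1, Y, np.nan)
    d = A.sum(axis=1)
    x0 = pd.DataFrame({"X": X, "U": U})
    return MortalCohortData(y=y_masked, r=R, a=A, d=d, x0=x0,
                            ids=np.arange(len(X)))


def simulate_monotone(design: SimulationDesign | None = None,
                      seed: int | None = None, return_oracle: bool = False):
    """Monotone study dataset; outcomes masked wherever unobserved.

    With ``return_oracle=True`` also returns the unmasked (n, J) outcome
    grid (NaN after death) for truth computations.
    """
    design = design or SimulationDesign(study="monotone")
    if design.study != "monotone":
        raise ValueError("design is not a monotone study")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    X, U, Y, A, R = _simulate(design, rng)
    data = _package(X, U, Y, A, R)
    return (data, Y) if return_oracle else data


def simulate_nonmonotone(design: SimulationDesign | None = None,
                         seed: int | None = None, return_oracle: bool = False):
    """Non-monotone study dataset (response indicators non-absorbing)."""
    design = design or SimulationDesign(study="nonmonotone")
    if design.study != "nonmonotone":
        raise ValueError("design is not a nonmonotone study")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    X, U, Y, A, R = _simulate(design, rng)
    data = _package(X, U, Y, A, R)
    return (data, Y) if return_oracle else data


def true_beta(study: str = "monotone", method: str = "montecarlo",
              n_oracle: int = 2_000_000, seed: int = 12345,
              design: SimulationDesign | None = None) -> np.ndarray:
    """True saturated-model parameters (visit-1 mean, contrasts vs visit 1).

    ``montecarlo`` simulates the full process unmasked and takes survivor
    means; ``quadrature`` returns only the visit-1 mean, computed by
    Gauss-Hermite integration of 5 - 0.1 E|X|^1.5 (visit-1 survival and
    observation are certain, so no simulation is involved).
    """
    design = design or SimulationDesign(study=study)
    if method == "quadrature":
        z, w = np.polynomial.hermite_e.hermegauss(201)
        w = w / w.sum()
        x = design.x_mean + design.x_sd * z
        b0, bU = design.y1_coef
        return np.array([b0 + bU * np.sum(w * np.abs(x) ** 1.5)])
    if method != "montecarlo":
        raise ValueError(f"unknown method {method!r}")
    d = dataclasses.replace(design, n=int(n_oracle), seed=seed)
    rng = np.random.default_rng(seed)
    _, _, Y, A, _ = _simulate(d, rng)
    means = np.array([np.nanmean(Y[A[:, j] == 1, j]) for j in range(d.J)])
    return np.concatenate([[means[0]], means[1:] - means[0]])


# ---------------------------------------------------------------------------
# analysis model designs per misspecification scenario
# ---------------------------------------------------------------------------

def analysis_designs(study: str, scenario: str = "none", J: int = 5):
    """Missingness designs and regression builder used by the analysis.

    Returns ``(miss_designs, reg_builder)``; the scenario controls which
    models swap the correct covariate U for X (monotone) or drop U
    (non-monotone), exactly as in the benchmark misspecification rows.
    """
    if study == "monotone":
        if scenario not in ("none", "missingness", "regression", "all"):
            raise ValueError(f"unknown monotone scenario {scenario!r}")
        miss_cov = "X" if scenario in ("missingness", "all") else "U"
        reg_cov = "X" if scenario in ("regression", "all") else "U"
        miss_designs = {t: HistoryDesign(("intercept", "y_last", miss_cov))
                        for t in range(2, J + 1)}

        def reg_builder(t: int, s: int) -> HistoryDesign:
            feats = ("intercept",) + (("y_last",) if s >= 1 else ()) + (reg_cov,)
            return HistoryDesign(feats)

        return miss_designs, reg_builder

    if scenario not in ("none", "m4h5", "all"):
        raise ValueError(f"unknown nonmonotone scenario {scenario!r}")
    miss_wrong = {5} if scenario == "m4h5" else set(range(2, J + 1)) if scenario == "all" else set()
    reg_wrong = {4} if scenario == "m4h5" else set(range(2, J + 1)) if scenario == "all" else set()
    miss_designs = {}
    for t in range(2, J + 1):
        feats = ("intercept", "ydag_last") + (() if t in miss_wrong else ("U",))
        miss_designs[t] = HistoryDesign(feats, mode="nonmonotone")

    def reg_builder(t: int) -> HistoryDesign:
        # R_{t-1} is constant at t=2 (first visit always observed), so the
        # indicator column enters only from t=3 on
        feats = (("intercept",) + (("r_last",) if t >= 3 else ())
                 + (("ydag_last",) if t >= 2 else ())
                 + (() if t in reg_wrong else ("U",)))
        return HistoryDesign(feats, mode="nonmonotone")

    return miss_designs, reg_builder


# ---------------------------------------------------------------------------
# replication harness
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReplicationSummary:
    """Bias / empirical SE / coverage summary of a replication study.

    ``table`` has one row per (method, parameter) with columns
    ``bias100``, ``se100`` (both scaled by 100), ``cp`` (percent coverage,
    NaN when no variance was computed), ``mcse_bias100`` (Monte-Carlo
    standard error of the bias).
    """

    table: pd.DataFrame
    n_reps: int
    truth: np.ndarray
    failures: int = 0

    def value(self, method: str, param: int, col: str) -> float:
        row = self.table[(self.table["method"] == method)
                         & (self.table["parameter"] == param)]
        return float(row[col].iloc[0])


def _study_recipes(design: SimulationDesign, methods, gamma_assumed, J):
    qfun = SelectionBiasFunction.linear(
        design.gamma_true if gamma_assumed is None else gamma_assumed)
    pattern = "monotone" if design.study == "monotone" else "nonmonotone"
    miss_designs, reg_builder = analysis_designs(design.study, design.scenario, J)
    return {m: FitRecipe(method=m, pattern=pattern, qfun=qfun,
                         miss_designs=miss_designs, reg_builder=reg_builder)
            for m in methods}


def run_replication_study(design: SimulationDesign,
                          methods=("ipw", "cmor", "aipw"),
                          n_reps: int = 1000,
                          gamma_assumed: float | None = None,
                          seed: int = 0,
                          coverage_methods=(),
                          truth: np.ndarray | None = None,
                          n_truth: int = 2_000_000,
                          max_fail_frac: float = 0.01) -> ReplicationSummary:
    """Simulate-and-fit replication study summarised as bias/SE/coverage.

    Each replicate draws a fresh dataset from ``design`` (replicate r is
    seeded by (seed, r), so any single replicate is re-runnable), fits all
    requested estimators under the design's misspecification scenario and
    the assumed gamma, and, for methods in ``coverage_methods``, computes
    stacked-sandwich Wald 95% intervals.  Bias and SE are reported on the
    x100 scale; coverage in percent.
    """
    J = design.J
    if truth is None:
        truth = true_beta(design.study, "montecarlo", n_truth,
                          seed=np.random.default_rng([seed, 999_983]).integers(2**31),
                          design=design)
    recipes = _study_recipes(design, methods, gamma_assumed, J)
    simulate = simulate_monotone if design.study == "monotone" else simulate_nonmonotone
    est = {m: [] for m in methods}
    hits = {m: [] for m in methods}
    failures = 0
    import warnings as _warnings
    for rep in range(n_reps):
        rep_seed = np.random.default_rng([seed, rep]).integers(2**31)
        data = simulate(dataclasses.replace(design, seed=int(rep_seed)))
        try:
            rep_est, rep_hits = {}, {}
            with _warnings.catch_warnings():
                # extreme-weight diagnostics are expected noise across
                # thousands of replicates
                _warnings.simplefilter("ignore", RuntimeWarning)
                for m in methods:
                    var = "sandwich" if m in coverage_methods else None
                    fit = fit_survivor_means(data, recipes[m], variance=var)
                    rep_est[m] = fit.beta
                    if var:
                        ci = fit.beta[:, None] + np.array([-1.0, 1.0]) \
                            * 1.959963984540054 * np.sqrt(np.diag(fit.cov))[:, None]
                        rep_hits[m] = (ci[:, 0] <= truth) & (truth <= ci[:, 1])
            for m in methods:
                est[m].append(rep_est[m])
            for m, h in rep_hits.items():
                hits[m].append(h)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failures += 1
            if failures > max_fail_frac * n_reps:
                raise RuntimeError(
                    f"{failures} replicate failures in {rep + 1} replicates")
    rows = []
    for m in methods:
        bmat = np.vstack(est[m])
        bias = bmat.mean(axis=0) - truth
        se = bmat.std(axis=0, ddof=1)
        cp = (100.0 * np.vstack(hits[m]).mean(axis=0) if hits[m]
              else np.full(len(truth), np.nan))
        for k in range(len(truth)):
            rows.append({"method": m, "parameter": k + 1,
                         "bias100": 100 * bias[k], "se100": 100 * se[k],
                         "cp": cp[k], "mcse_bias100": 100 * se[k] / np.sqrt(len(bmat))})
    return ReplicationSummary(table=pd.DataFrame(rows), n_reps=n_reps,
                              truth=truth, failures=failures)


def sensitivity_grid(data: MortalCohortData, grid, methods=("ipw", "cmor", "aipw"),
                     pattern: str = "monotone", miss_designs=None, reg_builder=None,
                     model: MarginalModel | None = None,
                     variance: str | None = None, B: int = 200,
                     seed: int = 0) -> pd.DataFrame:
    """Refit every method at each selection-bias function in ``grid``.

    Returns a long table (gamma label, gamma value where applicable,
    method, parameter, estimate, se) ordered as the grid is, from the
    ignorable end toward the extreme.  Fit errors are annotated with the
    gamma at which they occurred.
    """
    rows = []
    for qfun in grid:
        for m in methods:
            recipe = FitRecipe(method=m, pattern=pattern, qfun=qfun,
                               miss_designs=miss_designs, reg_builder=reg_builder,
                               model=model)
            try:
                fit = fit_survivor_means(data, recipe, variance=variance, B=B,
                                         seed=seed)
            except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
                raise RuntimeError(f"fit failed at {qfun.label()}: {exc}") from exc
            se = fit.se if fit.cov is not None else [np.nan] * len(fit.beta)
            for k, (b, s) in enumerate(zip(fit.beta, se)):
                rows.append({"gamma": qfun.label(),
                             "gamma_value": qfun.gamma if qfun.form == "linear" else np.nan,
                             "method": m, "parameter": k + 1,
                             "estimate": b, "se": s})
    return pd.DataFrame(rows)
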