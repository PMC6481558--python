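"""End-to-end fitting pipeline: nuisance models, estimator, variance.

This is the high-level entry point tying the modules together: given a
dataset, a missingness pattern, a selection-bias function and model
designs, it fits whatever nuisances the requested estimator needs and
solves for beta, optionally attaching a sandwich or bootstrap variance.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

from .data import MortalCohortData
from .design import HistoryDesign
from .estimators import (MarginalFit, MarginalModel, fit_aipw_monotone,
                         fit_aipw_nonmonotone, fit_iee, fit_ipw)
from .inference import (VarianceEstimate, bootstrap_variance,
                        build_stacked_system, sandwich_variance)
from .missingness import cumulative_weights, fit_missingness_models
from .regression import impute_nonmonotone, sequential_impute_monotone
from .selection import SelectionBiasFunction

__all__ = ["FitRecipe", "fit_survivor_means"]


@dataclasses.dataclass
class FitRecipe:
    """Reproducible configuration of one marginal fit.

    ``miss_designs`` maps visit -> HistoryDesign (ignored for cmor);
    ``reg_builder`` is ``(t, s) -> HistoryDesign`` for the monotone
    pattern or ``t -> HistoryDesign`` for the non-monotone one (ignored
    for ipw).
    """

    method: str
    pattern: str
    qfun: SelectionBiasFunction
    miss_designs: dict[int, HistoryDesign] | None = None
    reg_builder: Callable | None = None
    model: MarginalModel | None = None

    def __post_init__(self):
        if self.method not in ("iee", "ipw", "cmor", "aipw"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.pattern not in ("monotone", "nonmonotone"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


def _fit_once(data: MortalCohortData, recipe: FitRecipe):
    """Fit nuisances + beta; returns (MarginalFit, miss_fits, regression)."""
    model = recipe.model or MarginalModel.saturated(data.n_visits)
    method, pattern = recipe.method, recipe.pattern
    miss_fits = regression = weights = None

    if method in ("ipw", "aipw"):
        miss_fits = fit_missingness_models(data, recipe.miss_designs or {},
                                           recipe.qfun, pattern)
        weights = cumulative_weights(data, miss_fits, pattern)
    if method in ("cmor", "aipw"):
        if pattern == "monotone":
            regression, imputed = sequential_impute_monotone(
                data, recipe.qfun, recipe.reg_builder,
                fit_all_levels=(method == "aipw"))
        else:
            regression, imputed = impute_nonmonotone(data, recipe.qfun,
                                                     recipe.reg_builder)

    if method == "iee":
        fit = fit_iee(data, model)
    elif method == "ipw":
        fit = fit_ipw(data, weights, model)
    elif method == "cmor":
        fit = fit_iee(data, model, imputed=imputed, method_label="cmor")
    elif pattern == "monotone":
        fit = fit_aipw_monotone(data, weights, regression, model)
    else:
        fit = fit_aipw_nonmonotone(data, weights, regression, model)
    fit.mode = recipe.pattern
    return fit, miss_fits, regression


def fit_survivor_means(data: MortalCohortData, recipe: FitRecipe,
                       variance: str | None = None, B: int = 1000,
                       seed: int = 0) -> MarginalFit:
    """Fit the marginal survivor-mean model by the requested estimator.

    ``variance`` may be ``None``, ``"sandwich"`` (stacked M-estimation,
    accounting for nuisance estimation) or ``"bootstrap"`` (subject
    resampling of the whole pipeline, B replicates).
    """
    fit, miss_fits, regression = _fit_once(data, recipe)
    if variance == "sandwich":
        model = fit.model
        system = build_stacked_system(data, recipe.method, recipe.pattern,
                                      recipe.qfun, model, fit,
                                      miss_fits=miss_fits, regression=regression)
        ve = sandwich_variance(system)
        fit.cov, fit.cov_method = ve.cov, "sandwich"
    elif variance == "bootstrap":
        ve = bootstrap_variance(data, lambda d: _fit_once(d, recipe)[0].beta,
                                B=B, seed=seed)
        fit.cov, fit.cov_method = ve.cov, "bootstrap"
        fit.diagnostics["bootstrap_failed"] = ve.n_failed
    elif variance is not None:
        raise ValueError(f"unknown variance method {variance!r}")
    return fit
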