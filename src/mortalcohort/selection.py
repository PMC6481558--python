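"""Selection-bias (exponential tilt) functions.

Non-ignorability of missingness is encoded by a *known* function
``q_t(\\bar{O}_{t-1}, Y_t; gamma)``: the residual log-odds effect of the
current outcome on being unobserved, after conditioning on the observed
history.  ``gamma`` is a sensitivity parameter — it is fixed a priori,
never estimated, and swept over a grid in sensitivity analysis.
``q = 0`` recovers the ignorable (sequentially explainable) case.

Two standard classes are built in:

* linear: ``q = gamma * y_t``;
* two-part: ``q = gamma1 * r_prev * y_t + gamma2 * (1 - r_prev) * y_t``,
  letting the tilt differ between subjects observed and unobserved at the
  previous visit (commonly parameterised as ``gamma2 = c * gamma1``).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

__all__ = ["SelectionBiasFunction", "evaluate_q", "gamma_grid"]


@dataclasses.dataclass(frozen=True)
class SelectionBiasFunction:
    """The tilt ``q_t`` with its sensitivity parameter(s).

    ``custom`` forms supply an evaluator over ``(history_row, y_t, r_prev)``
    and must declare ``depends_on_r_prev`` so monotone code paths (where
    ``r_prev = 1`` at every evaluation point) can ignore the flag.
    """

    form: str = "linear"
    gamma: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    evaluator: Callable | None = None
    depends_on_r_prev: bool = False

    def __post_init__(self):
        if self.form not in ("linear", "two_part", "custom"):
            raise ValueError(f"unknown selection-bias form {self.form!r}")
        if self.form == "custom" and self.evaluator is None:
            raise ValueError("custom form requires an evaluator")
        for g in (self.gamma, self.gamma1, self.gamma2):
            if not np.isfinite(g):
                raise ValueError("selection-bias parameters must be finite")

    @classmethod
    def linear(cls, gamma: float) -> "SelectionBiasFunction":
        return cls(form="linear", gamma=gamma)

    @classmethod
    def two_part(cls, gamma1: float, gamma2: float) -> "SelectionBiasFunction":
        return cls(form="two_part", gamma1=gamma1, gamma2=gamma2,
                   depends_on_r_prev=True)

    @property
    def is_zero(self) -> bool:
        if self.form == "linear":
            return self.gamma == 0.0
        if self.form == "two_part":
            return self.gamma1 == 0.0 and self.gamma2 == 0.0
        return False

    def __call__(self, y, r_prev=1, history=None):
        """Vectorised tilt value; exp of this is the downstream weight."""
        y = np.asarray(y, dtype=float)
        if self.form == "linear":
            return self.gamma * y
        if self.form == "two_part":
            r_prev = np.asarray(r_prev, dtype=float)
            return self.gamma1 * r_prev * y + self.gamma2 * (1.0 - r_prev) * y
        out = np.asarray(self.evaluator(history, y, r_prev), dtype=float)
        if not np.all(np.isfinite(out)):
            raise ValueError("custom selection-bias evaluator returned non-finite value")
        return out

    def label(self) -> str:
        if self.form == "linear":
            return f"gamma={self.gamma:g}"
        if self.form == "two_part":
            return f"gamma1={self.gamma1:g},gamma2={self.gamma2:g}"
        return "custom"


def evaluate_q(qfun: SelectionBiasFunction, history, y_t, r_prev=1):
    """Evaluate the tilt for one (or a vector of) record(s)."""
    return qfun(y_t, r_prev=r_prev, history=history)


def gamma_grid(form: str = "linear", *, start: float = 0.0, stop: float | None = None,
               step: float | None = None, values: Sequence[float] | None = None,
               gamma1_values: Sequence[float] | None = None,
               c_values: Sequence[float] | None = None) -> list[SelectionBiasFunction]:
    """Ordered grid of tilt functions for a sensitivity sweep.

    Linear grids run from ``start`` (usually 0) toward ``stop`` inclusive in
    increments of ``step`` (a positive magnitude), or take explicit
    ``values``.  Two-part grids are the product of ``gamma1_values`` with
    multipliers ``c_values`` (``gamma2 = c * gamma1``).
    """
    if form == "linear":
        if values is None:
            if stop is None or step is None:
                raise ValueError("linear grid needs stop and step (or explicit values)")
            if step <= 0:
                raise ValueError("step must be positive")
            span = stop - start
            n_steps = int(round(abs(span) / step))
            if abs(n_steps * step - abs(span)) > 1e-9:
                raise ValueError("step does not divide the range")
            values = [start + np.sign(span) * k * step for k in range(n_steps + 1)]
        values = list(values)
        if not values:
            raise ValueError("empty gamma grid")
        return [SelectionBiasFunction.linear(g) for g in values]
    if form == "two_part":
        if not gamma1_values or not c_values:
            raise ValueError("two_part grid needs gamma1_values and c_values")
        return [SelectionBiasFunction.two_part(g1, c * g1)
                for g1 in gamma1_values for c in c_values]
    raise ValueError(f"unknown form {form!r}")
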