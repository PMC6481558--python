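"""History-measurable design vectors.

Every model in this package (observation models ``h_t``, outcome
regressions ``m_t``) is linear in a design vector computed only from
information available in the observed history up to some visit ``s``
(written ``\\bar{O}_s``).  Two encodings exist:

* monotone — the history is ``(X_0, Y_1..Y_s)``; the lagged outcome is the
  actual value (always observed for the subjects the model is fitted on);
* non-monotone — the history is ``(X_0, R_1, R_1 Y_1, ..., R_s, R_s Y_s)``;
  unobserved past outcomes are encoded as 0 through the ``R Y`` products,
  and the response indicators themselves may enter.

Feature tokens: ``"intercept"``, ``"y_last"`` (``Y_s``, monotone),
``"ydag_last"`` (``R_s Y_s`` with 0 for unobserved), ``"r_last"``
(``R_s``), ``"d"`` (death visit, only when known), ``"visit"`` (the target
visit index t = s+1), or the name of a baseline covariate column.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import MortalCohortData

__all__ = ["HistoryDesign"]

_LAG_TOKENS = {"y_last", "ydag_last", "r_last"}


@dataclasses.dataclass(frozen=True)
class HistoryDesign:
    """Feature specification mapping (data, history visit s) to a matrix.

    Evaluating the design never touches an unobserved outcome: ``y_last``
    rows are only meaningful where ``R_s = 1`` (callers mask to such rows),
    and ``ydag_last`` substitutes 0 for unobserved values by construction.
    """

    features: tuple[str, ...]
    mode: str = "monotone"

    def __post_init__(self):
        if self.mode not in ("monotone", "nonmonotone"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def dim(self) -> int:
        return len(self.features)

    def matrix(self, data: MortalCohortData, s: int) -> np.ndarray:
        """(n, dim) design over the history through visit ``s`` (0 = baseline).

        Rows whose lagged outcome is unobserved get 0 in the ``y_last``
        column; such rows must be excluded by the caller's fitting mask.
        """
        n = data.n_subjects
        cols = []
        for tok in self.features:
            if tok == "intercept":
                cols.append(np.ones(n))
            elif tok in _LAG_TOKENS:
                if s < 1:
                    raise ValueError(f"{tok!r} undefined at baseline history (s=0)")
                ylag = data.y[:, s - 1]
                rlag = data.r[:, s - 1].astype(float)
                if tok == "y_last":
                    cols.append(np.where(rlag == 1, np.nan_to_num(ylag), 0.0))
                elif tok == "ydag_last":
                    cols.append(np.nan_to_num(ylag) * rlag)
                else:
                    cols.append(rlag)
            elif tok == "d":
                if not data.death_time_known:
                    raise ValueError("design requests D but death_time_known is False")
                cols.append(data.d.astype(float))
            elif tok == "visit":
                cols.append(np.full(n, float(s + 1)))
            elif tok in data.x0.columns:
                cols.append(data.baseline(tok))
            else:
                raise ValueError(f"unknown design feature {tok!r}")
        return np.column_stack(cols)
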