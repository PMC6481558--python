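"""Mortal-cohort longitudinal data container and long-CSV round-trip IO.

A *mortal cohort* is a longitudinal study in which death truncates the
outcome process: a subject scheduled for visits ``1..J`` contributes an
outcome ``Y_t`` only while alive (``A_t = 1``), and among the alive the
outcome may additionally be unobserved (``R_t = 0``).  Post-death outcomes
are not merely missing — they are undefined — so all estimands downstream
are *partly conditional*: means among the survivors at each visit.

Conventions used throughout the package: visits are integer-indexed
``1..J``; ``A_0 = R_0 = 1``; ``D`` is the last scheduled visit at which the
subject is alive, so ``A_t = 1`` iff ``t <= D``.
"""

from __future__ import annotations

import dataclasses
import numpy as np
import pandas as pd

__all__ = [
    "MortalCohortData",
    "DEFAULT_SCHEMA",
    "load_long_csv",
    "write_long_csv",
    "from_long_frame",
    "to_long_frame",
    "validate",
    "is_monotone",
]

#: Default column-name mapping for the long CSV dialect.  ``alive_or_death``
#: may name either a per-row 0/1 vital-status column or a per-subject death
#: visit column (detected by values outside {0, 1}).
DEFAULT_SCHEMA = {
    "id": "id",
    "visit": "visit",
    "outcome": "y",
    "response": "r",
    "alive_or_death": "alive",
    "baseline_covariates": [],
    "timevarying_covariates": [],
}


@dataclasses.dataclass
class MortalCohortData:
    """Per-subject visit grid of outcomes, response and vital status.

    Attributes
    ----------
    y : ndarray, shape (n, J)
        Outcome values; ``NaN`` exactly where ``r == 0``.
    r : ndarray, shape (n, J)
        Response indicators ``R_it`` in {0, 1}.
    a : ndarray, shape (n, J)
        Vital-status indicators ``A_it`` in {0, 1}, nonincreasing per row.
    d : ndarray, shape (n,)
        Last scheduled visit alive, ``D_i`` in ``1..J``.
    x0 : DataFrame, n rows
        Fully observed baseline covariates (covariates of interest plus
        auxiliaries).
    xt : dict of str -> ndarray (n, J)
        Optional time-varying auxiliary columns.
    ids : ndarray, shape (n,)
        Subject identifiers.
    death_time_known : bool
        Whether ``d`` may be used as a model covariate.
    """

    y: np.ndarray
    r: np.ndarray
    a: np.ndarray
    d: np.ndarray
    x0: pd.DataFrame
    ids: np.ndarray
    xt: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    death_time_known: bool = True

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_visits(self) -> int:
        return self.y.shape[1]

    def baseline(self, name: str) -> np.ndarray:
        """Baseline covariate column as a float array."""
        return self.x0[name].to_numpy(dtype=float)

    def take(self, indices: np.ndarray) -> "MortalCohortData":
        """Row-subset (with repetition allowed) — used by the bootstrap."""
        idx = np.asarray(indices)
        return MortalCohortData(
            y=self.y[idx].copy(),
            r=self.r[idx].copy(),
            a=self.a[idx].copy(),
            d=self.d[idx].copy(),
            x0=self.x0.iloc[idx].reset_index(drop=True),
            ids=np.arange(len(idx)),
            xt={k: v[idx].copy() for k, v in self.xt.items()},
            death_time_known=self.death_time_known,
        )


def _as_grid(frame: pd.DataFrame, col: str, n: int, J: int) -> np.ndarray:
    return frame[col].to_numpy().reshape(n, J)


def from_long_frame(frame: pd.DataFrame, schema: dict | None = None) -> MortalCohortData:
    """Build a :class:`MortalCohortData` from a long-format DataFrame.

    One row per (subject, visit); rows after death may be absent and are
    reconstructed as ``a = 0, r = 0``.  Validity rules are enforced: see
    :func:`validate` for the full list.
    """
    sc = dict(DEFAULT_SCHEMA, **(schema or {}))
    idc, vc, yc, rc, ac = (sc["id"], sc["visit"], sc["outcome"], sc["response"],
                           sc["alive_or_death"])
    for col in (idc, vc, rc, ac):
        if col not in frame.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    if yc not in frame.columns:
        raise ValueError(f"missing mandatory column: {yc!r}")
    if frame.duplicated([idc, vc]).any():
        dup = frame[frame.duplicated([idc, vc])].iloc[0]
        raise ValueError(f"duplicate (id, visit): ({dup[idc]}, {dup[vc]})")

    J = int(frame[vc].max())
    if int(frame[vc].min()) < 1:
        raise ValueError("visit indices must start at 1")
    subject_ids = frame[idc].drop_duplicates().to_numpy()
    n = len(subject_ids)

    # dense (subject, visit) grid; absent rows become a=0, r=0 below
    full = pd.MultiIndex.from_product([subject_ids, range(1, J + 1)],
                                      names=[idc, vc])
    dense = frame.set_index([idc, vc]).reindex(full).reset_index()

    r = np.nan_to_num(_as_grid(dense, rc, n, J), nan=0.0)
    if not np.isin(r, (0.0, 1.0)).all():
        raise ValueError(f"non-{{0,1}} indicator in column {rc!r}")
    r = r.astype(np.int8)

    alive_raw = _as_grid(dense, ac, n, J)
    vals = alive_raw[~np.isnan(alive_raw)]
    if np.isin(vals, (0.0, 1.0)).all():
        a = np.nan_to_num(alive_raw, nan=0.0)
        # vital status must be known at every visit up to min(D, J)
        d = np.where(a.any(axis=1), J - np.argmax(a[:, ::-1], axis=1), 0)
        known = ~np.isnan(alive_raw)
        for i in range(n):
            if not known[i, : int(d[i])].all():
                raise ValueError(
                    f"subject {subject_ids[i]}: vital status unknown before death")
    else:
        # per-subject death-visit column
        dcol = alive_raw.copy()
        d = np.nanmax(dcol, axis=1)
        if np.isnan(d).any():
            raise ValueError("death visit column has all-missing subject")
        a = (np.arange(1, J + 1)[None, :] <= d[:, None]).astype(np.int8)
    a = a.astype(np.int8)
    d = d.astype(int)
    if (d < 1).any():
        raise ValueError("subject dead before visit 1")

    y = _as_grid(dense, yc, n, J).astype(float)
    present = ~np.isnan(y)
    if (present & (r == 0)).any():
        i, t = np.argwhere(present & (r == 0))[0]
        if a[i, t] == 0:
            raise ValueError(
                f"subject {subject_ids[i]}, visit {t + 1}: observation after death")
        raise ValueError(
            f"subject {subject_ids[i]}, visit {t + 1}: outcome present with r=0")
    if ((r == 1) & ~present).any():
        i, t = np.argwhere((r == 1) & ~present)[0]
        raise ValueError(f"subject {subject_ids[i]}, visit {t + 1}: r=1 but outcome absent")
    if ((r == 1) & (a == 0)).any():
        i, t = np.argwhere((r == 1) & (a == 0))[0]
        raise ValueError(f"subject {subject_ids[i]}, visit {t + 1}: observation after death")
    if (r.sum(axis=1) == 0).any():
        i = int(np.argmax(r.sum(axis=1) == 0))
        raise ValueError(f"subject {subject_ids[i]}: no observed outcome at any visit")

    base_cols = list(sc["baseline_covariates"])
    x0 = pd.DataFrame(index=range(n))
    for col in base_cols:
        grid = _as_grid(dense, col, n, J)
        first = grid[:, 0]
        if np.isnan(first).any():
            raise ValueError(f"baseline covariate {col!r} incomplete")
        x0[col] = first
    xt = {}
    for col in sc["timevarying_covariates"]:
        xt[col] = _as_grid(dense, col, n, J).astype(float)

    data = MortalCohortData(y=y, r=r, a=a, d=d, x0=x0, ids=subject_ids, xt=xt)
    problems = validate(data)
    if problems:
        raise ValueError("invalid data: " + "; ".join(problems[:3]))
    return data


def load_long_csv(path, schema: dict | None = None) -> MortalCohortData:
    """Read the long CSV dialect (one row per subject-visit) and validate."""
    return from_long_frame(pd.read_csv(path), schema)


def to_long_frame(data: MortalCohortData, schema: dict | None = None) -> pd.DataFrame:
    """Long-format DataFrame with one row per (subject, visit)."""
    sc = dict(DEFAULT_SCHEMA, **(schema or {}))
    n, J = data.n_subjects, data.n_visits
    out = pd.DataFrame({
        sc["id"]: np.repeat(data.ids, J),
        sc["visit"]: np.tile(np.arange(1, J + 1), n),
        sc["outcome"]: data.y.ravel(),
        sc["response"]: data.r.ravel(),
        sc["alive_or_death"]: data.a.ravel(),
    })
    for col in data.x0.columns:
        out[col] = np.repeat(data.x0[col].to_numpy(), J)
    for col, grid in data.xt.items():
        out[col] = grid.ravel()
    return out


def write_long_csv(data: MortalCohortData, path, schema: dict | None = None) -> None:
    """Write the same dialect :func:`load_long_csv` reads (empty y cell <=> r=0)."""
    to_long_frame(data, schema).to_csv(path, index=False)


def validate(data: MortalCohortData, monotone: bool = False) -> list[str]:
    """Check all container invariants; return one descriptor per violation.

    An empty list means the data are valid.  With ``monotone=True`` the
    absorbing-dropout rule (r nonincreasing among the alive) is also checked.
    """
    problems: list[str] = []
    n, J = data.n_subjects, data.n_visits
    visits = np.arange(1, J + 1)
    for i in range(n):
        a, r, y, d = data.a[i], data.r[i], data.y[i], data.d[i]
        if np.any(np.diff(a) > 0):
            t = int(np.argmax(np.diff(a) > 0)) + 2
            problems.append(f"subject {data.ids[i]}, visit {t}: resurrection")
        if not np.array_equal(a == 1, visits <= d):
            problems.append(f"subject {data.ids[i]}: a inconsistent with d={d}")
        if np.any(r > a):
            t = int(np.argmax(r > a)) + 1
            problems.append(f"subject {data.ids[i]}, visit {t}: observation after death")
        if np.any((r == 1) & np.isnan(y)) or np.any((r == 0) & ~np.isnan(y)):
            problems.append(f"subject {data.ids[i]}: y presence inconsistent with r")
        if monotone:
            alive_r = r[data.a[i] == 1]
            if np.any(np.diff(alive_r) > 0):
                problems.append(f"subject {data.ids[i]}: non-monotone response")
    return problems


def is_monotone(data: MortalCohortData) -> bool:
    """True iff every subject's response is nonincreasing among alive visits."""
    for i in range(data.n_subjects):
        alive_r = data.r[i][data.a[i] == 1]
        if np.any(np.diff(alive_r) > 0):
            return False
    return True
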