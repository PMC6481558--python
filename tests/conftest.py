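import numpy as np
import pandas as pd
import pytest

from mortalcohort import MortalCohortData


def make_data(y_rows, d=None, x0=None, ids=None):
    """Build a small MortalCohortData directly from a ragged outcome spec.

    ``y_rows`` is a list of per-subject visit lists where a number means an
    observed outcome, None means alive-but-missing and "dead" means the
    subject has died by that visit.
    """
    n = len(y_rows)
    J = len(y_rows[0])
    y = np.full((n, J), np.nan)
    r = np.zeros((n, J), dtype=np.int8)
    a = np.ones((n, J), dtype=np.int8)
    for i, row in enumerate(y_rows):
        for t, val in enumerate(row):
            if val == "dead":
                a[i, t] = 0
            elif val is None:
                pass
            else:
                y[i, t] = float(val)
                r[i, t] = 1
    if d is None:
        d = a.sum(axis=1)
    x0 = pd.DataFrame(x0 if x0 is not None else {}, index=range(n))
    ids = np.arange(n) if ids is None else np.asarray(ids)
    return MortalCohortData(y=y, r=r, a=a, d=np.asarray(d), x0=x0, ids=ids)


@pytest.fixture
def complete_two_by_three():
    """2 subjects x 3 visits, everyone alive and observed."""
    return make_data([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
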