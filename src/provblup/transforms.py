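"""Normal-score transformation of ordinal trait scores.

Subjectively scored class traits (stem straightness, malformation,
branching, needle retention) live on bounded ordinal scales whose
increments carry no metric meaning.  Before mixed-model analysis each
observation is replaced by its Blom normal score

    z_i = Phi^{-1}((r_i - 3/8) / (n + 1/4)),

where ``r_i`` is the mid-rank of the observation among the ``n``
non-missing values.  Ties share a mid-rank and therefore an identical
score; missing values stay missing.  The result is monotone in the
original codes, has mean approximately zero, and is invariant to any
strictly increasing relabelling of the ordinal codes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateTraitError(ValueError):
    """Raised for a constant (or effectively empty) trait vector."""


def normal_score(values) -> pd.Series:
    """Blom normal scores of an ordinal trait vector.

    Accepts any 1-d sequence (list, ndarray, Series); missing values
    (NaN) are preserved.  Requires at least two distinct observed values.
    """
    s = pd.Series(values, dtype=float)
    obs = s.dropna()
    if obs.nunique() < 2:
        raise DegenerateTraitError(
            "normal score needs at least two distinct observed values"
        )
    n = len(obs)
    ranks = stats.rankdata(obs.to_numpy(), method="average")
    scores = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    out = s.copy()
    out[obs.index] = scores
    return out


class NormalScoreTransformer:
    """Column-wise Blom normal scoring, sklearn transformer style.

    Parameters
    ----------
    columns : list of str or None
        Columns of the input frame to transform; ``None`` transforms all.

    The transform is rank-based and stateless; ``fit`` only validates and
    records the column list (``columns_``).
    """

    def __init__(self, columns=None):
        self.columns = columns

    def get_params(self, deep=True):
        return {"columns": self.columns}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.columns_ = list(self.columns) if self.columns is not None else list(X.columns)
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise KeyError(f"columns not present: {missing}")
        return self

    def transform(self, X):
        X = pd.DataFrame(X).copy()
        for c in self.columns_:
            X[c] = normal_score(X[c])
        return X

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
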