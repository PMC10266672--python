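"""Rank-based transforms shared by expression modelling and scoring.

Two conventions are used throughout the package and deliberately share one
implementation:

* ``normalized_rank`` maps values to ``rank / (n + 1)`` with tie-averaged
  ranks, so every output lies strictly inside (0, 1).
* ``inverse_normal_transform`` (INT) maps those normalized ranks through the
  standard normal quantile function, yielding an approximately N(0, 1)
  vector whose ordering equals the input ordering.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .exceptions import DegenerateInputError, ParameterError

__all__ = ["normalized_rank", "inverse_normal_transform"]


def normalized_rank(values) -> np.ndarray:
    """Tie-averaged ranks scaled to (0, 1) via the rank/(n+1) convention."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ParameterError("normalized_rank expects a 1-D vector")
    n = x.size
    if n == 0:
        raise ParameterError("normalized_rank requires a non-empty vector")
    ranks = stats.rankdata(x, method="average")
    return ranks / (n + 1.0)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^{-1}(rank / (n + 1)).

    Parameters
    ----------
    values
        1-D numeric vector with at least 3 entries and at least two
        distinct values.

    Returns
    -------
    numpy.ndarray
        Vector of normal quantiles; monotone in the input, mean ~0 (exactly
        0 for tie-free input by symmetry of the quantile grid).

    Raises
    ------
    ParameterError
        If fewer than 3 values are supplied.
    DegenerateInputError
        If all values are identical (the rank transform is undefined up to
        an arbitrary constant).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ParameterError("inverse_normal_transform expects a 1-D vector")
    if x.size < 3:
        raise ParameterError(
            f"inverse_normal_transform requires length >= 3, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant input has no rank ordering")
    return ndtri(normalized_rank(x))
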