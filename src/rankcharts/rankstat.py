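"""Two-sample Wilcoxon rank-sum statistic and its in-control moments.

The monitoring schemes in this package plot functions of the Wilcoxon
rank-sum statistic ``W``: the sum of the ranks that the phase-II (test)
subgroup occupies in the combined, ascending ordering of the phase-I
(reference) sample and the test subgroup.  Under identical continuous
distributions (the in-control state) the distribution of ``W`` depends
only on the sample sizes ``m`` and ``n``, which is what makes the charts
distribution-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.stats import rankdata

__all__ = ["WMoments", "w_moments", "wilcoxon_rank_sum", "TiesWarning"]


class TiesWarning(UserWarning):
    """Tied observations were midranked; moments assume no ties."""


@dataclass(frozen=True)
class WMoments:
    """In-control mean and variance of the test-sample rank sum.

    For reference size ``m`` and test size ``n`` (``N = m + n``)::

        mu_w  = n (m + n + 1) / 2
        var_w = m n (m + n + 1) / 12

    Both are exact rational numbers; they are stored as floats after
    exact ``Fraction`` evaluation.
    """

    m: int
    n: int
    mu_w: float
    var_w: float

    @property
    def N(self) -> int:
        return self.m + self.n

    @property
    def sigma_w(self) -> float:
        return float(np.sqrt(self.var_w))


def w_moments(m: int, n: int) -> WMoments:
    """In-control moments of the Wilcoxon rank-sum statistic.

    Parameters
    ----------
    m, n : int
        Phase-I (reference) and phase-II (test) sample sizes, both >= 1.
    """
    m, n = int(m), int(n)
    if m < 1 or n < 1:
        raise ValueError(f"sample sizes must be >= 1, got m={m}, n={n}")
    mu = Fraction(n * (m + n + 1), 2)
    var = Fraction(m * n * (m + n + 1), 12)
    return WMoments(m=m, n=n, mu_w=float(mu), var_w=float(var))


def _validate(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} sample is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} sample contains non-finite values")
    return arr


def wilcoxon_rank_sum(ref, test) -> float:
    """Rank sum of the test subgroup in the combined ordering.

    Ranks run from 1 (smallest) to ``N = m + n`` (largest); tied values
    receive midranks (the chart moments assume no ties, so a
    :class:`TiesWarning` is emitted when ties occur).

    Returns
    -------
    float
        ``W`` with ``n(n+1)/2 <= W <= n(2m+n+1)/2``.
    """
    ref = _validate(ref, "reference")
    test = _validate(test, "test")
    combined = np.concatenate([ref, test])
    ranks = rankdata(combined, method="average")
    if np.unique(combined).size < combined.size:
        warnings.warn(
            "tied observations midranked; in-control moments assume no ties",
            TiesWarning,
            stacklevel=2,
        )
    return float(ranks[ref.size:].sum())


def rank_sums_against_reference(ref_sorted: np.ndarray, subgroups: np.ndarray) -> np.ndarray:
    """Vectorised W for many test subgroups against one fixed reference.

    Assumes continuous data (no ties), which holds almost surely for the
    simulated families.  For each subgroup the combined rank of a test
    value equals its rank within the subgroup plus the count of smaller
    reference values, so::

        W = n(n+1)/2 + sum_j #{ref < y_j}

    Parameters
    ----------
    ref_sorted : ndarray, shape (m,)
        Reference sample, pre-sorted ascending.
    subgroups : ndarray, shape (B, n)
        Block of B test subgroups.

    Returns
    -------
    ndarray, shape (B,)
    """
    b, n = subgroups.shape
    below = np.searchsorted(ref_sorted, subgroups.ravel(), side="left")
    return below.reshape(b, n).sum(axis=1) + n * (n + 1) / 2.0
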