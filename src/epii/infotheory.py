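"""Plug-in estimators for entropy, MI, conditional MI and interaction information.

All estimators use base-2 logarithms (bits) and maximum-likelihood
probabilities ``p = count / total`` with the ``0 * log 0 = 0`` convention.
No small-sample bias correction is applied; downstream permutation nulls
absorb estimator bias.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import xlogy

_LN2 = math.log(2.0)

__all__ = [
    "InfoValue",
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "interaction_information",
]


class InfoValue(float):
    """A float (in bits) tagged with the kind of statistic it estimates."""

    __slots__ = ("kind",)

    def __new__(cls, value: float, kind: str) -> "InfoValue":
        obj = super().__new__(cls, value)
        obj.kind = kind
        return obj

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"InfoValue({float(self)!r}, kind={self.kind!r})"


def _as_counts(counts, ndim: int | None = None) -> np.ndarray:
    c = np.asarray(counts, dtype=np.float64)
    if ndim is not None and c.ndim != ndim:
        raise ValueError(f"expected a {ndim}-axis count table, got {c.ndim} axes")
    if c.size == 0:
        raise ValueError("empty count table")
    if (c < 0).any():
        raise ValueError("count table contains negative entries")
    total = c.sum()
    if total <= 0:
        raise ValueError("count table total must be positive")
    return c


def _H(counts: np.ndarray) -> float:
    """Entropy in bits of the normalized count array (any shape).

    Counts are sorted before the log-sum so the result depends only on the
    multiset of cell counts; axis permutations of a table therefore yield
    bit-identical entropies (and interaction information is exactly
    symmetric on integer inputs).
    """
    c = np.sort(counts, axis=None)
    p = c / c.sum()
    return -float(xlogy(p, p).sum()) / _LN2


def entropy(counts) -> InfoValue:
    """Shannon entropy H(X) of a count table, marginalizing nothing.

    ``counts`` may have any number of axes; the entropy of the joint
    distribution over all axes is returned.
    """
    c = _as_counts(counts)
    return InfoValue(max(0.0, _H(c)), "entropy")


def mutual_information(counts) -> InfoValue:
    """I(X;C) = H(X) + H(C) - H(X,C) from a 2-axis count table."""
    c = _as_counts(counts, ndim=2)
    v = _H(c.sum(1)) + _H(c.sum(0)) - _H(c)
    return InfoValue(max(0.0, v), "mi")


def conditional_mutual_information(counts) -> InfoValue:
    """CMI I(Y;X|Z) from a 3-axis count table with axes ordered (Y, X, Z).

    Computed as ``H(Y,Z) + H(X,Z) - H(X,Y,Z) - H(Z)``, equal to
    ``H(Y|Z) - H(Y|X,Z)``.  Always non-negative.
    """
    c = _as_counts(counts, ndim=3)
    v = _H(c.sum(1)) + _H(c.sum(0)) - _H(c) - _H(c.sum((0, 1)))
    return InfoValue(max(0.0, v), "cmi")


def interaction_information(counts) -> InfoValue:
    """Interaction information I(X1;X2;C) from a 3-axis count table.

    Signed so that pure synergy (e.g. C = XOR(X1, X2) with independent
    uniform inputs) is +1 bit and pure redundancy is negative:

        I(X1;X2;C) = I(C;X1|X2) - I(C;X1)
                   = H(X1,X2) + H(X1,C) + H(X2,C)
                     - H(X1) - H(X2) - H(C) - H(X1,X2,C)

    Symmetric under any permutation of the three axes.
    """
    c = _as_counts(counts, ndim=3)
    # sorted group sums keep the result bit-identical under axis permutation
    pairs = sorted((_H(c.sum(2)), _H(c.sum(1)), _H(c.sum(0))))
    singles = sorted((_H(c.sum((1, 2))), _H(c.sum((0, 2))), _H(c.sum((0, 1)))))
    v = math.fsum(pairs) - math.fsum(singles) - _H(c)
    return InfoValue(v, "interaction")
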