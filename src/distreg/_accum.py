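"""Compensated (double-double) accumulation for partition-invariant sums.

Every additive quantity that crosses a site boundary — moment matrices,
gradients, information matrices, log-likelihood terms, risk-set sums — is
accumulated with an error-free transformation (Knuth two-sum) and carried as
an unevaluated pair of doubles ``(hi, lo)``.  Site-level partial sums and the
analysis center's cross-site aggregation both use the same representation, so
the aggregate agrees with a one-pass pooled computation to O(eps^2) relative
error (~1e-31) regardless of how the rows are split across sites.  Collapsing
the pair back to a single double therefore yields the *same* double for the
distributed and the pooled path (up to a vanishing probability of landing on
a rounding boundary), which is what makes the downstream solves, standard
errors and fit statistics partition-invariant at full double precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["two_sum", "DDArray", "dd_sum"]


def two_sum(a, b):
    """Error-free addition: returns (s, e) with s = fl(a+b) and s + e = a + b exactly."""
    s = a + b
    bb = s - a
    e = (a - (s - bb)) + (b - bb)
    return s, e


class DDArray:
    """An array of double-double values (elementwise hi + lo, |lo| <= ulp(hi)/2).

    Supports exactly the operations the payload protocol needs: elementwise
    addition (for cross-site aggregation) and collapse to float64.
    """

    __slots__ = ("hi", "lo")

    def __init__(self, hi, lo=None):
        self.hi = np.array(hi, dtype=np.float64)
        if lo is None:
            self.lo = np.zeros_like(self.hi)
        else:
            self.lo = np.array(lo, dtype=np.float64)
            if self.lo.shape != self.hi.shape:
                raise ValueError("hi/lo shape mismatch")

    @property
    def shape(self):
        return self.hi.shape

    @property
    def value(self):
        """Collapse to float64.  ``hi`` is the correctly rounded double of hi+lo."""
        return self.hi.copy()

    def item(self) -> float:
        return float(self.hi)

    def __add__(self, other: "DDArray") -> "DDArray":
        if not isinstance(other, DDArray):
            return NotImplemented
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch {self.shape} vs {other.shape}")
        s, e = two_sum(self.hi, other.hi)
        e = e + (self.lo + other.lo)
        hi, lo = two_sum(s, e)
        return DDArray(hi, lo)

    def copy(self) -> "DDArray":
        return DDArray(self.hi.copy(), self.lo.copy())

    @classmethod
    def zeros(cls, shape=()) -> "DDArray":
        return cls(np.zeros(shape))

    def __repr__(self):  # pragma: no cover
        return f"DDArray(shape={self.shape})"


def dd_sum(terms, axis: int = 0) -> DDArray:
    """Sum ``terms`` along ``axis`` into a DDArray via an exact two-sum tree.

    All per-level rounding errors are retained and folded into the low word,
    so the result is independent of pairing/grouping to O(eps^2) — summing
    per-site subsets and adding the partials gives the same collapsed double
    as one pooled pass.
    """
    x = np.asarray(terms, dtype=np.float64)
    x = np.moveaxis(x, axis, 0)
    out_shape = x.shape[1:]
    if x.shape[0] == 0:
        return DDArray(np.zeros(out_shape))
    level_errors = []
    while x.shape[0] > 1:
        m = x.shape[0] // 2
        s, e = two_sum(x[:m], x[m : 2 * m])
        if x.shape[0] % 2:
            s = np.concatenate([s, x[2 * m :]], axis=0)
        level_errors.append(e.sum(axis=0))
        x = s
    if level_errors:
        lo = np.sum(np.stack(level_errors), axis=0)
    else:
        lo = np.zeros(out_shape)
    hi, lo = two_sum(x[0], lo)
    return DDArray(hi, lo)
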