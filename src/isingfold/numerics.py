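"""Overflow-safe numeric primitives.

Partition functions here mix Boltzmann factors of order exp(70) per
disulfide contact with bins of order 1, so every accumulation is done in
the log domain.  Two primitives are provided:

* :class:`LogPoly` -- a polynomial in one or two order-parameter
  indeterminates whose coefficients are *non-negative* numbers stored as
  logarithms (``-inf`` encodes zero).  All restricted-partition
  bookkeeping (native-count generating functions) uses these.
* signed log scalars/arrays (``logaddexp_signed``) -- used at the table
  level where ensemble combinations may subtract partition functions.
"""

from __future__ import annotations

import numpy as np

NEG_INF = -np.inf


def logsumexp(a, axis=None):
    """Log-sum-exp that tolerates all-``-inf`` input without warnings."""
    a = np.asarray(a, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.max(a, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        out = np.log(np.sum(np.exp(a - m), axis=axis)) + np.squeeze(m, axis=axis)
    if np.ndim(out) == 0:
        return float(out)
    return out


def logaddexp_signed(la, sa, lb, sb):
    """Add two signed log-magnitude numbers.

    Parameters are log-magnitudes (``-inf`` = zero) and signs in
    {-1, 0, +1}; arrays broadcast.  Returns ``(log_mag, sign)``.
    """
    la = np.asarray(la, dtype=float)
    lb = np.asarray(lb, dtype=float)
    sa = np.asarray(sa)
    sb = np.asarray(sb)
    la, lb, sa, sb = np.broadcast_arrays(la, lb, sa, sb)
    la = np.where(sa == 0, NEG_INF, la)
    lb = np.where(sb == 0, NEG_INF, lb)

    hi = np.maximum(la, lb)
    lo = np.minimum(la, lb)
    s_hi = np.where(la >= lb, sa, sb)
    same = sa * sb >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = lo - hi
        add = hi + np.log1p(np.exp(diff))
        sub = np.where(diff < 0, hi + np.log1p(-np.exp(diff)), NEG_INF)
    out_log = np.where(same, np.where(np.isneginf(hi), NEG_INF, add), sub)
    # exact cancellation or both zero
    cancel = (~same) & (la == lb)
    out_log = np.where(cancel, NEG_INF, out_log)
    out_sign = np.where(np.isneginf(out_log), 0, s_hi)
    if out_log.ndim == 0:
        return float(out_log), int(out_sign)
    return out_log, out_sign.astype(np.int8)


class LogPoly:
    """Polynomial with non-negative coefficients stored as logs.

    The coefficient array is 1D (single order parameter) or 2D (two
    order parameters); index = number of native residues per axis.
    Instances are immutable by convention.
    """

    __slots__ = ("c",)

    def __init__(self, c):
        self.c = np.asarray(c, dtype=float)

    # -- constructors -------------------------------------------------
    @classmethod
    def zero(cls, ndim=1):
        return cls(np.full((1,) * ndim, NEG_INF))

    @classmethod
    def monomial(cls, logval, index):
        """``exp(logval) * lambda^index`` with ``index`` int or pair."""
        if np.isscalar(index):
            index = (int(index),)
        index = tuple(int(i) for i in index)
        c = np.full(tuple(i + 1 for i in index), NEG_INF)
        c[index] = logval
        return cls(c)

    @property
    def ndim(self):
        return self.c.ndim

    def is_zero(self):
        return bool(np.all(np.isneginf(self.c)))

    # -- arithmetic ---------------------------------------------------
    def _pad_to(self, shape):
        pad = [(0, s - cur) for s, cur in zip(shape, self.c.shape)]
        if any(p[1] for p in pad):
            return np.pad(self.c, pad, constant_values=NEG_INF)
        return self.c

    def add(self, other):
        shape = tuple(
            max(a, b) for a, b in zip(self.c.shape, other.c.shape)
        )
        return LogPoly(np.logaddexp(self._pad_to(shape), other._pad_to(shape)))

    def scale(self, logfactor):
        if logfactor == 0.0:
            return self
        return LogPoly(self.c + logfactor)

    def shift(self, index, logfactor=0.0):
        """Multiply by a monomial: shift indices, add ``logfactor``."""
        if np.isscalar(index):
            index = (int(index),)
        index = tuple(int(i) for i in index)
        pad = [(i, 0) for i in index]
        c = np.pad(self.c, pad, constant_values=NEG_INF)
        if logfactor:
            c = c + logfactor
        return LogPoly(c)

    def mul(self, other):
        """Full polynomial product (log-domain convolution)."""
        a, b = self.c, other.c
        if a.size > b.size:
            a, b = b, a
        out_shape = tuple(sa + sb - 1 for sa, sb in zip(a.shape, b.shape))
        out = np.full(out_shape, NEG_INF)
        if a.ndim == 1:
            for i in np.flatnonzero(~np.isneginf(a)):
                seg = out[i:i + b.shape[0]]
                out[i:i + b.shape[0]] = np.logaddexp(seg, a[i] + b)
        else:
            idx = np.argwhere(~np.isneginf(a))
            for i, j in idx:
                seg = out[i:i + b.shape[0], j:j + b.shape[1]]
                out[i:i + b.shape[0], j:j + b.shape[1]] = np.logaddexp(
                    seg, a[i, j] + b
                )
        return LogPoly(out)

    def padded(self, shape):
        """Log-coefficients padded with ``-inf`` up to ``shape``."""
        return self._pad_to(tuple(shape))

    def total(self):
        """Log of the sum of all coefficients (lambda -> 1)."""
        return logsumexp(self.c)

    def __repr__(self):  # pragma: no cover
        return f"LogPoly(shape={self.c.shape})"
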