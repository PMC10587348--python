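"""Restricted partition tables and ensemble combination.

A :class:`PartitionTable` stores ``Z`` restricted by one or two order
parameters, indexed by integer native counts (never by floating ``n``;
``n = k / N`` only at the presentation layer).  Values are kept as
(log-magnitude, sign) pairs: plain partitions are positive, but the
linker-ensemble combination subtracts tables and intermediate bins may
transiently go negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .numerics import NEG_INF, logaddexp_signed, logsumexp

__all__ = ["OrderParameterSpec", "PartitionTable", "linked_ensemble"]


@dataclass(frozen=True)
class OrderParameterSpec:
    """One or two disjoint residue sets defining the reaction coordinates.

    The union of the sets must cover residues 1..N; each axis counts the
    native residues of its set.  Sets may be non-contiguous.
    """

    n: int
    sets: tuple

    def __post_init__(self):
        sets = tuple(tuple(sorted(int(r) for r in s)) for s in self.sets)
        object.__setattr__(self, "sets", sets)
        if len(sets) not in (1, 2):
            raise ValueError("spec needs one or two residue sets")
        flat = [r for s in sets for r in s]
        if sorted(flat) != list(range(1, self.n + 1)):
            raise ValueError(
                "residue sets must be disjoint and cover 1..N exactly"
            )

    @classmethod
    def single(cls, n: int) -> "OrderParameterSpec":
        return cls(n=n, sets=(tuple(range(1, n + 1)),))

    @classmethod
    def split(cls, n: int, set1) -> "OrderParameterSpec":
        set1 = tuple(sorted(set(int(r) for r in set1)))
        set2 = tuple(r for r in range(1, n + 1) if r not in set(set1))
        return cls(n=n, sets=(set1, set2))

    @property
    def ndim(self) -> int:
        return len(self.sets)

    @property
    def sizes(self) -> tuple:
        return tuple(len(s) for s in self.sets)

    @property
    def shape(self) -> tuple:
        return tuple(len(s) + 1 for s in self.sets)

    def axis_of(self) -> np.ndarray:
        """Axis tag per residue, shape (N+1,); entry 0 unused."""
        tags = np.zeros(self.n + 1, dtype=int)
        for ax, s in enumerate(self.sets):
            for r in s:
                tags[r] = ax
        return tags

    def total_counts(self) -> np.ndarray:
        """Total native count k (or k1+k2) per bin, shaped like a table."""
        if self.ndim == 1:
            return np.arange(self.shape[0])
        k1 = np.arange(self.shape[0])[:, None]
        k2 = np.arange(self.shape[1])[None, :]
        return k1 + k2

    def n_pathway(self) -> np.ndarray:
        """Blended order parameter (N1 n1 + N2 n2) / N per bin."""
        return self.total_counts() / self.n


@dataclass
class PartitionTable:
    """Z restricted by native counts, as signed log magnitudes."""

    spec: OrderParameterSpec
    temperature: float
    logz: np.ndarray
    sign: np.ndarray = None

    def __post_init__(self):
        self.logz = np.asarray(self.logz, dtype=float)
        if self.logz.shape != self.spec.shape:
            raise ValueError(
                f"table shape {self.logz.shape} != spec shape {self.spec.shape}"
            )
        if self.sign is None:
            self.sign = np.where(np.isneginf(self.logz), 0, 1).astype(np.int8)
        else:
            self.sign = np.asarray(self.sign).astype(np.int8)

    # -- queries ------------------------------------------------------
    def value(self, index) -> float:
        """Linear-scale Z at a bin (may overflow to inf for huge bins)."""
        return float(self.sign[index] * np.exp(self.logz[index]))

    def total_log(self) -> float:
        if np.any(self.sign < 0):
            raise ValueError("total of a signed table is not supported")
        return logsumexp(self.logz)

    def require_positive(self):
        bad = (self.sign < 0) | ((self.sign == 0) & False)
        if np.any(self.sign < 0):
            idx = np.argwhere(self.sign < 0)[0]
            raise ValueError(
                f"negative partition bin at index {tuple(idx)}: "
                "model misconfiguration (ensemble subtraction exceeded base)"
            )
        return self

    def marginal(self, axis: int) -> "PartitionTable":
        """Sum a 2D table over one axis, yielding a 1D table."""
        if self.spec.ndim != 2:
            raise ValueError("marginal requires a 2D table")
        self.require_positive()
        keep = 1 - axis
        logz = logsumexp(self.logz, axis=axis)
        # relabel kept axis as a 1D spec over its own residue set
        spec = _SubsetSpec(self.spec.n, self.spec.sets[keep])
        return PartitionTable(spec=spec, temperature=self.temperature,
                              logz=np.asarray(logz))

    def max_rel_deviation(self, other: "PartitionTable") -> float:
        """max over bins of |Z_self/Z_other - 1| (inf on zero mismatch)."""
        if self.logz.shape != other.logz.shape:
            raise ValueError("shape mismatch")
        a_zero = self.sign == 0
        b_zero = other.sign == 0
        if np.any(a_zero != b_zero):
            return float("inf")
        mask = ~a_zero
        if not np.any(mask):
            return 0.0
        ratio = (self.sign[mask] * other.sign[mask]) * np.exp(
            self.logz[mask] - other.logz[mask]
        )
        return float(np.max(np.abs(ratio - 1.0)))

    # -- signed arithmetic -------------------------------------------
    def _binary(self, other, sb_factor=1):
        if self.logz.shape != other.logz.shape:
            raise ValueError("table shape mismatch")
        if self.temperature != other.temperature:
            raise ValueError("table temperature mismatch")
        logz, sign = logaddexp_signed(
            self.logz, self.sign, other.logz, sb_factor * other.sign
        )
        return PartitionTable(spec=self.spec, temperature=self.temperature,
                              logz=np.asarray(logz), sign=np.asarray(sign))

    def add(self, other):
        return self._binary(other, +1)

    def subtract(self, other):
        return self._binary(other, -1)

    def scale_log(self, log_factors: np.ndarray):
        """Multiply bins by exp(log_factors) (broadcast over bin shape)."""
        return PartitionTable(
            spec=self.spec, temperature=self.temperature,
            logz=self.logz + np.asarray(log_factors),
            sign=self.sign.copy(),
        )


class _SubsetSpec(OrderParameterSpec):
    """1D spec over a subset axis kept from a marginalised 2D table."""

    def __init__(self, n, subset):
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "sets", (tuple(subset),))

    def __post_init__(self):  # pragma: no cover - bypassed
        pass


def linked_ensemble(base: PartitionTable, linked, strict: bool = True
                    ) -> PartitionTable:
    """Combine base and linked partitions into the linker ensemble.

    ``linked`` is an iterable of ``(table, log_penalty_by_count)`` pairs:
    ``Z_L = Z + sum (Z_uv - Z) * exp(S'(n)/k_B)`` with the penalty looked
    up by the total native count of each bin.  A negative resulting bin
    is a hard configuration error when ``strict``.
    """
    counts = base.spec.total_counts()
    out = base
    for table, log_pen in linked:
        log_pen = np.asarray(log_pen, dtype=float)
        diff = table.subtract(base).scale_log(log_pen[counts])
        out = out.add(diff)
    if strict:
        out.require_positive()
    return out
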