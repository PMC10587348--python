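"""Exact polynomial-time evaluation of restricted partition functions.

Matches the enumeration oracle bin for bin while scaling polynomially
with chain length.  The solver works with the native-stretch
decomposition that underlies the transfer-matrix solution: every
microstate factorises into maximal native stretches separated by
unfolded residues, each stretch carrying a Boltzmann weight

    w[i, j] = exp(-(E_intra(i, j) - T * sum S_k) / k_B T) * lambda^len

where the indeterminate ``lambda`` tracks native counts per order
parameter axis.  Restricted partitions are the coefficient arrays of
the resulting generating polynomial; all coefficients are accumulated
in the log domain (see :mod:`isingfold.numerics`).

With a linker at (u, v), a microstate in which u and v are native in
two *distinct* stretches [a, b] and [c, d] acquires the cross-stretch
weight exp(-sum_{k in [a,b], l in [c,d]} E[k, l] / k_B T); the solver
sums over the stretch containing v and evaluates linker-modified prefix
partitions, exactly mirroring the generating-function expansion with an
inserted unit matrix.  The double-linker variant enumerates the
(polynomially many) joint stretch assignments of all linker endpoints.
"""

from __future__ import annotations

import numpy as np

from .constants import KB_CAL, KB_KCAL
from .numerics import LogPoly
from .partition import OrderParameterSpec, PartitionTable

__all__ = [
    "restricted_partition_tm",
    "linked_partition_tm",
    "double_linked_partition_tm",
    "perturbed_partition_tm",
    "partition_tm",
]


class _StretchMachine:
    """Precomputed stretch weights and cached segment partitions."""

    def __init__(self, energy: np.ndarray, s_residue, temperature: float,
                 spec: OrderParameterSpec):
        n = energy.shape[0] - 1
        if n != spec.n:
            raise ValueError("energy matrix size does not match spec")
        if n < 3:
            raise ValueError("need N >= 3")
        self.n = n
        self.spec = spec
        self.beta = 1.0 / (KB_KCAL * temperature)
        self.temperature = temperature

        # 2D prefix sums of the energy matrix for O(1) rectangle sums
        e = np.asarray(energy, dtype=float)
        self._pre = np.zeros((n + 1, n + 1))
        self._pre[1:, 1:] = np.cumsum(np.cumsum(e[1:, 1:], axis=0), axis=1)

        # intra-stretch energies tri[i, j] = sum_{i<=k<l<=j} E[k, l]
        tri = np.zeros((n + 2, n + 2))
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                tri[i, j] = tri[i, j - 1] + self.rect(i, j - 1, j, j)
        self._tri = tri

        s = np.asarray(s_residue, dtype=float) / KB_CAL
        self._scum = np.concatenate([[0.0], np.cumsum(s[1:])])

        counts = np.zeros((len(spec.sets), n + 1))
        for ax, residues in enumerate(spec.sets):
            tags = np.zeros(n + 1)
            tags[list(residues)] = 1.0
            counts[ax] = np.cumsum(tags)
        self._ccum = counts.astype(int)

        self._one = LogPoly.monomial(0.0, (0,) * spec.ndim)
        self._rows: dict[int, list] = {}

    # -- scalar precomputations --------------------------------------
    def rect(self, a, b, c, d) -> float:
        """sum of E[k, l] over k in [a, b], l in [c, d] (clipped)."""
        a, c = max(a, 1), max(c, 1)
        b, d = min(b, self.n), min(d, self.n)
        if a > b or c > d:
            return 0.0
        p = self._pre
        return p[b, d] - p[a - 1, d] - p[b, c - 1] + p[a - 1, c - 1]

    def stretch_log(self, i, j) -> float:
        """log Boltzmann weight of the native stretch [i, j]."""
        return (-self.beta * self._tri[i, j]
                + self._scum[j] - self._scum[i - 1])

    def stretch_idx(self, i, j):
        """Order-parameter exponent(s) of the stretch [i, j]."""
        return tuple(int(c[j] - c[i - 1]) for c in self._ccum)

    # -- segment partitions ------------------------------------------
    @property
    def one(self) -> LogPoly:
        return self._one

    def seg(self, a: int, b: int) -> LogPoly:
        """Partition polynomial of free residues a..b (1 when empty).

        Stretches inside the segment are maximal runs; callers must
        guarantee that residues a-1 and b+1 are unfolded (or absent).
        """
        if b < a:
            return self._one
        row = self._rows.get(a)
        if row is None:
            row = self._build_row(a)
            self._rows[a] = row
        return row[b - a]

    def _build_row(self, a: int):
        row = []
        prev = self._one
        for b in range(a, self.n + 1):
            acc = prev                      # m_b unfolded
            for i in range(a, b + 1):
                pre = row[i - 2 - a] if i - 2 >= a else self._one
                acc = acc.add(
                    pre.shift(self.stretch_idx(i, b), self.stretch_log(i, b))
                )
            row.append(acc)
            prev = acc
        return row

    def table(self, poly: LogPoly, log_offset: float = 0.0) -> PartitionTable:
        logz = poly.padded(self.spec.shape) + log_offset
        return PartitionTable(spec=self.spec, temperature=self.temperature,
                              logz=logz)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def restricted_partition_tm(energy: np.ndarray, s_residue,
                            temperature: float, spec: OrderParameterSpec
                            ) -> PartitionTable:
    """Restricted partition function without linkers, O(N^2) stretch ops."""
    m = _StretchMachine(energy, s_residue, temperature, spec)
    return m.table(m.seg(1, m.n))


def linked_partition_tm(energy: np.ndarray, s_residue, temperature: float,
                        spec: OrderParameterSpec, u: int, v: int,
                        gain: float = 0.0) -> PartitionTable:
    """Restricted partition with one linker at (u, v).

    ``energy`` must already carry the double-counting mask around
    (u, v); ``gain`` (kcal/mol) is the state-independent linker energy
    multiplied into every bin.  Sums over the stretch [c, d] containing
    v; prefixes are re-evaluated with the cross-stretch weight applied
    to every stretch containing u.
    """
    if v <= u:
        raise ValueError("linker needs u < v")
    m = _StretchMachine(energy, s_residue, temperature, spec)
    n = m.n

    # configurations with v unfolded: no linker contribution
    total = m.seg(1, v - 1).mul(m.seg(v + 1, n))

    # prefix-with-stretch [a, b] ending before the v-stretch
    pref_stretch = {}
    for b in range(u, v - 1):
        for a in range(1, u + 1):
            pref_stretch[(a, b)] = m.seg(1, a - 2).shift(
                m.stretch_idx(a, b), m.stretch_log(a, b)
            )

    for d in range(v, n + 1):
        suffix = m.seg(d + 2, n)
        for c in range(1, v + 1):
            if c <= u:
                # u lies inside the v-stretch: plain prefix, no cross term
                prefix = m.seg(1, c - 2)
            else:
                # u unfolded ...
                prefix = m.seg(1, u - 1).mul(m.seg(u + 1, c - 2))
                # ... or u native in a stretch [a, b] left of [c, d]
                for b in range(u, c - 1):
                    inner = None
                    for a in range(1, u + 1):
                        cross = -m.beta * m.rect(a, b, c, d)
                        piece = pref_stretch[(a, b)].scale(cross)
                        inner = piece if inner is None else inner.add(piece)
                    if inner is not None:
                        prefix = prefix.add(inner.mul(m.seg(b + 2, c - 2)))
            term = prefix.shift(m.stretch_idx(c, d), m.stretch_log(c, d))
            total = total.add(term.mul(suffix))

    return m.table(total, log_offset=-m.beta * gain)


def double_linked_partition_tm(energy: np.ndarray, s_residue,
                               temperature: float, spec: OrderParameterSpec,
                               linker1, linker2, gain: float = 0.0
                               ) -> PartitionTable:
    """Restricted partition with two linkers.

    ``gain`` carries only the first linker's energy (the second linker
    is typically a covalent disulfide whose contact energy has been
    removed from the weights).  Implemented by enumerating the joint
    assignment of the four linker endpoints to native stretches; the
    cross-stretch weight of a stretch pair shared by both linkers is
    counted once.
    """
    (u1, v1), (u2, v2) = tuple(linker1), tuple(linker2)
    if v1 <= u1 or v2 <= u2:
        raise ValueError("each linker needs u < v")
    if (u1, v1) == (u2, v2):
        raise ValueError("identical linkers: use the single-linker solver")
    m = _StretchMachine(energy, s_residue, temperature, spec)
    n = m.n
    specials = sorted({u1, v1, u2, v2})
    result = [None]

    def link_log(runmap) -> float:
        out = 0.0
        seen = set()
        for (p, q) in ((u1, v1), (u2, v2)):
            rp, rq = runmap[p], runmap[q]
            if rp is None or rq is None or rp == rq:
                continue
            if (rp, rq) in seen:
                continue
            seen.add((rp, rq))
            out += -m.beta * m.rect(rp[0], rp[1], rq[0], rq[1])
        return out

    def rec(t, free_from, poly, runmap):
        if t == len(specials):
            leaf = poly.mul(m.seg(free_from, n)).scale(link_log(runmap))
            result[0] = leaf if result[0] is None else result[0].add(leaf)
            return
        p = specials[t]
        # p unfolded
        rec(t + 1, p + 1, poly.mul(m.seg(free_from, p - 1)),
            {**runmap, p: None})
        # p native in a stretch [a, b] also covering specials[t..t+c]
        for c in range(len(specials) - t):
            last = specials[t + c]
            nxt = specials[t + c + 1] if t + c + 1 < len(specials) else n + 1
            for a in range(free_from, p + 1):
                base = (poly if a == free_from
                        else poly.mul(m.seg(free_from, a - 2)))
                for b in range(last, nxt):
                    stretch = base.shift(m.stretch_idx(a, b),
                                         m.stretch_log(a, b))
                    newmap = {**runmap}
                    for s in specials[t:t + c + 1]:
                        newmap[s] = (a, b)
                    rec(t + c + 1, b + 2, stretch, newmap)

    rec(0, 1, m.one, {})
    return m.table(result[0], log_offset=-m.beta * gain)


def partition_tm(energy: np.ndarray, s_residue, temperature: float,
                 spec: OrderParameterSpec, linkers=(), gain: float = 0.0
                 ) -> PartitionTable:
    """Dispatch on the number of linkers (0, 1 or 2).

    More than two simultaneous linkers are not implemented in the
    transfer-matrix path; use the enumeration oracle for those.
    """
    linkers = [tuple(l) for l in linkers]
    if not linkers:
        table = restricted_partition_tm(energy, s_residue, temperature, spec)
        if gain:
            table = table.scale_log(-gain / (KB_KCAL * temperature))
        return table
    if len(linkers) == 1:
        (u, v) = linkers[0]
        return linked_partition_tm(energy, s_residue, temperature, spec,
                                   u, v, gain)
    if len(linkers) == 2:
        return double_linked_partition_tm(energy, s_residue, temperature,
                                          spec, linkers[0], linkers[1], gain)
    raise NotImplementedError(
        ">2 simultaneous linkers: served by the enumeration oracle only"
    )


def perturbed_partition_tm(energy: np.ndarray, eta: np.ndarray, s_residue,
                           temperature: float, spec: OrderParameterSpec,
                           linkers=(), gain: float = 0.0,
                           gain_delta: float = 0.0) -> PartitionTable:
    """Partition with pseudo-mutation perturbations.

    The perturbation adds ``eta`` to the contact energies (applied to
    *all* connectivity routes, i.e. the same OR semantics, and to masked
    pairs as well) and ``gain_delta`` to the linker gain -- exactly the
    weight replacements w -> w exp(-sum eta / k_B T) of the perturbed
    transfer matrices.
    """
    return partition_tm(np.asarray(energy) + np.asarray(eta), s_residue,
                        temperature, spec, linkers=linkers,
                        gain=gain + gain_delta)
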