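"""Ground-truth oracle: brute-force 2^N evaluation of all Hamiltonians
and restricted partition functions.

Every residue carries a binary native/unfolded variable; a native
contact (i, j) contributes its energy when all residues between i and j
are native, or -- in linked Hamiltonians -- when the two residues are
joined into one native stretch through a linker shortcut (logical OR of
the connectivity indicators; the ceiling-function form in the model
definition is exactly this OR).  Deliberately exponential; guarded at
N <= 22.  This module defines the microstate semantics that the
transfer-matrix solver must match bit for bit.
"""

from __future__ import annotations

import numpy as np

from .constants import KB_CAL, KB_KCAL
from .contact_model import EnergyModel, linker_gain, masked_model
from .entropy_model import EntropyModel
from .numerics import NEG_INF
from .partition import OrderParameterSpec, PartitionTable, linked_ensemble

ENUMERATION_GUARD = 22

__all__ = [
    "hamiltonian",
    "linked_indicator",
    "hamiltonian_linked",
    "enumerate_partition",
    "wsme_l_ensemble",
    "ss_intact_ensemble",
    "contact_occupancy",
]


# ---------------------------------------------------------------------------
# per-microstate semantics (scalar, used directly in unit tests)
# ---------------------------------------------------------------------------

def _segment_native(state, a: int, b: int) -> bool:
    """All of m_a..m_b native; empty segments (b < a) count as native."""
    return all(state[k - 1] for k in range(a, b + 1))


def hamiltonian(state, energy: np.ndarray) -> float:
    """H({m}) = sum over i<j of E[i, j] * m_{i,j}, kcal/mol."""
    n = energy.shape[0] - 1
    if len(state) != n:
        raise ValueError(f"state length {len(state)} != N {n}")
    h = 0.0
    for i in range(1, n):
        for j in range(i + 1, n + 1):
            if energy[i, j] != 0.0 and _segment_native(state, i, j):
                h += energy[i, j]
    return h


def linked_indicator(state, i: int, j: int, u: int, v: int) -> int:
    """1 when residues i and j are joined through the (u, v) linker."""
    left = _segment_native(state, min(i, u), max(i, u))
    right = _segment_native(state, min(j, v), max(j, v))
    return int(left and right)


def hamiltonian_linked(state, energy: np.ndarray, linkers) -> float:
    """OR-semantics Hamiltonian with any number of linkers, kcal/mol.

    ``energy`` must already have any double-counting masks applied; the
    state-independent linker gains are *not* included here.
    """
    n = energy.shape[0] - 1
    h = 0.0
    for i in range(1, n):
        for j in range(i + 1, n + 1):
            if energy[i, j] == 0.0:
                continue
            connected = _segment_native(state, i, j) or any(
                linked_indicator(state, i, j, u, v) for (u, v) in linkers
            )
            if connected:
                h += energy[i, j]
    return h


# ---------------------------------------------------------------------------
# vectorised enumeration
# ---------------------------------------------------------------------------

def _state_bits(n: int, offset: int, count: int) -> np.ndarray:
    """States offset..offset+count-1 as a (count, n) 0/1 array."""
    idx = np.arange(offset, offset + count, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(np.int8)


def _enumerate_core(energy, s_residue, temperature, spec, linkers, gain,
                    indicator_pair=None, chunk=1 << 16):
    """Per-bin log sums of (optionally indicator-weighted) Boltzmann
    factors over all 2^N microstates."""
    n = energy.shape[0] - 1
    if n > ENUMERATION_GUARD:
        raise ValueError(
            f"N={n} exceeds the enumeration guard ({ENUMERATION_GUARD}); "
            "use the transfer-matrix solver"
        )
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    beta = 1.0 / (KB_KCAL * temperature)
    s_over_kb = np.asarray(s_residue, dtype=float)[1:] / KB_CAL

    pairs = [(i, j) for i in range(1, n) for j in range(i + 1, n + 1)
             if energy[i, j] != 0.0]
    shape = spec.shape
    nbins = int(np.prod(shape))
    set0 = np.array(spec.sets[0]) - 1
    set1 = np.array(spec.sets[1]) - 1 if spec.ndim == 2 else None

    xs, bin_ids = [], []
    total = 1 << n
    for off in range(0, total, chunk):
        cnt = min(chunk, total - off)
        bits = _state_bits(n, off, cnt)          # residue i -> column i-1
        cs = np.zeros((cnt, n + 1), dtype=np.int32)
        np.cumsum(bits, axis=1, out=cs[:, 1:])

        def seg(a, b):
            # all of m_a..m_b native (empty segment -> all True)
            return cs[:, b] - cs[:, a - 1] == (b - a + 1)

        def or_connected(i, j):
            conn = seg(i, j)
            for (u, v) in linkers:
                conn = conn | (
                    seg(min(i, u), max(i, u)) & seg(min(j, v), max(j, v))
                )
            return conn

        h = np.zeros(cnt)
        for (i, j) in pairs:
            h += energy[i, j] * or_connected(i, j)

        x = -beta * (h + gain) + bits @ s_over_kb
        if indicator_pair is not None:
            x = np.where(or_connected(*indicator_pair), x, NEG_INF)

        k0 = bits[:, set0].sum(axis=1)
        ids = k0 if spec.ndim == 1 else k0 * shape[1] + bits[:, set1].sum(axis=1)
        keep = ~np.isneginf(x)
        xs.append(x[keep])
        bin_ids.append(ids[keep])

    x = np.concatenate(xs)
    ids = np.concatenate(bin_ids)
    binmax = np.full(nbins, NEG_INF)
    np.maximum.at(binmax, ids, x)
    binacc = np.zeros(nbins)
    if x.size:
        np.add.at(binacc, ids, np.exp(x - binmax[ids]))
    with np.errstate(divide="ignore"):
        logz = np.where(binacc > 0, binmax + np.log(binacc), NEG_INF)
    return logz.reshape(shape)


def enumerate_partition(energy: np.ndarray, s_residue, temperature: float,
                        spec: OrderParameterSpec, linkers=(),
                        gain: float = 0.0) -> PartitionTable:
    """Restricted partition function by direct summation over 2^N states.

    ``energy`` is the (N+1, N+1) contact-energy matrix in kcal/mol
    (double-counting masks already applied for linked variants);
    ``gain`` is the state-independent linker energy added inside the
    exponent of every microstate.
    """
    logz = _enumerate_core(energy, s_residue, temperature, spec,
                           list(linkers), gain)
    return PartitionTable(spec=spec, temperature=temperature, logz=logz)


def wsme_l_ensemble(base: PartitionTable, linked, strict: bool = True
                    ) -> PartitionTable:
    """Linker-ensemble combination (alias of the table-level operation)."""
    return linked_ensemble(base, linked, strict=strict)


def ss_intact_ensemble(model: EnergyModel, entropy: EntropyModel,
                       temperature: float, spec: OrderParameterSpec,
                       ss_pairs, virtual_linkers) -> PartitionTable:
    """Disulfide-intact ensemble by enumeration.

    For each disulfide (u2, v2): the single-linker partition (no gain,
    weights already zeroed around the bond) plus the inner ensemble over
    virtual linkers (u1, v1), each a double-linker partition carrying
    only the (u1, v1) gain and its entropy penalty.  Outer terms are
    summed over all disulfides.
    """
    ss_pairs = list(ss_pairs)
    if not ss_pairs:
        raise ValueError("disulfide-intact ensemble needs >= 1 SS pair")
    energy = model.energy_matrix()
    s = entropy.s_residue
    out = None
    for (u2, v2) in ss_pairs:
        z2 = enumerate_partition(energy, s, temperature, spec,
                                 linkers=[(u2, v2)])
        inner = []
        for (u1, v1) in virtual_linkers:
            gain, mask = linker_gain(model, u1, v1)
            e1 = masked_model(model, mask).energy_matrix()
            z12 = enumerate_partition(
                e1, s, temperature, spec,
                linkers=[(u1, v1), (u2, v2)], gain=gain,
            )
            inner.append((z12, entropy.log_penalty_factors(u1, v1)))
        term = linked_ensemble(z2, inner)
        out = term if out is None else out.add(term)
    return out.require_positive()


def contact_occupancy(energy: np.ndarray, s_residue, temperature: float,
                      spec: OrderParameterSpec, pair, linkers=(),
                      gain: float = 0.0) -> PartitionTable:
    """Numerator table: Boltzmann-weighted OR-connectivity of ``pair``.

    Dividing bin-wise by :func:`enumerate_partition` on the same inputs
    gives the thermal probability that the contact is formed in each
    bin (the quantity the degree-of-disulfide-formation estimator
    approximates to first order in the perturbation).
    """
    logz = _enumerate_core(energy, s_residue, temperature, spec,
                           list(linkers), gain, indicator_pair=tuple(pair))
    return PartitionTable(spec=spec, temperature=temperature, logz=logz)
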