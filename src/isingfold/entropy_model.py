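"""Conformational entropy costs and linker ring-closure penalties.

Each residue pays a (negative) entropy ``S_i`` on becoming native.  A
virtual linker between residues u and v additionally pays a ring-closure
entropy: the Gaussian-chain cost of closing a loop of ``L`` virtual
bonds whose endpoints sit ``r`` Angstrom apart in the native structure,
averaged hypergeometrically over how many of the spanned residues are
already native at a given order parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .constants import CA_STEP, KB_CAL, PERSISTENCE_LENGTH, S_RESIDUE_DEFAULTS

__all__ = ["EntropyModel", "ring_closure_entropy", "linker_entropy_penalty"]


def ring_closure_entropy(L: int, r: float, a: float = CA_STEP,
                         persistence: float = PERSISTENCE_LENGTH) -> float:
    """Entropy cost of closing a Gaussian loop, cal/(mol.K).

    ``s'(L) = -(3/2) k_B (ln L + (r^2 - a^2) / (2 A a L))`` with the
    chain length ``L`` in virtual bonds and endpoint distance ``r`` in
    Angstrom.  ``L < 1`` is clamped to 1 (a single virtual bond is the
    physical minimum loop).
    """
    if r < 0:
        raise ValueError("endpoint distance r must be non-negative")
    L = max(int(L), 1)
    return -1.5 * KB_CAL * (np.log(L) + (r * r - a * a)
                            / (2.0 * persistence * a * L))


def _hypergeom_weights(n_total: int, n_span: int, k: int) -> np.ndarray:
    """Weights C(N', i) C(N - N', k - i) / C(N, k) for i = 0..k."""
    i = np.arange(k + 1)
    w = hypergeom.pmf(i, n_total, n_span, k)
    s = w.sum()
    if abs(s - 1.0) > 1e-12:
        raise AssertionError(
            f"hypergeometric weights sum to {s}, expected 1"
        )
    return w


def linker_entropy_penalty(u: int, v: int, k: int, n_total: int,
                           r: float, h_scale: float = 1.0,
                           a: float = CA_STEP,
                           persistence: float = PERSISTENCE_LENGTH) -> float:
    """Mean ring-closure entropy at ``k`` native residues, cal/(mol.K).

    Averages ``s'(N' - i)`` over the hypergeometric number ``i`` of
    native residues falling inside the span ``[u, v]`` (``N' = v-u+1``)
    when ``k`` of the ``n_total`` residues are native.  The ``s'``
    argument is clamped to >= 1.
    """
    if not (1 <= u < v <= n_total):
        raise ValueError("need 1 <= u < v <= N")
    if not (0 <= k <= n_total):
        raise ValueError("native count k outside 0..N")
    n_span = v - u + 1
    w = _hypergeom_weights(n_total, n_span, k)
    s = np.array([
        ring_closure_entropy(n_span - i, r, a, persistence)
        for i in range(k + 1)
    ])
    return h_scale * float(np.dot(w, s))


@dataclass
class EntropyModel:
    """Per-residue entropy costs plus linker ring-closure parameters."""

    n: int
    s_residue: np.ndarray = None         # (N+1,), cal/(mol.K), each < 0
    h_scale: float = 1.0
    a: float = CA_STEP
    persistence: float = PERSISTENCE_LENGTH
    ca: np.ndarray | None = None         # (N, 3) for endpoint distances

    def __post_init__(self):
        if self.s_residue is None:
            self.s_residue = np.full(self.n + 1, S_RESIDUE_DEFAULTS["linker"])
        elif np.isscalar(self.s_residue):
            self.s_residue = np.full(self.n + 1, float(self.s_residue))
        else:
            arr = np.asarray(self.s_residue, dtype=float)
            if arr.shape == (self.n,):
                arr = np.concatenate([[0.0], arr])
            if arr.shape != (self.n + 1,):
                raise ValueError("s_residue must have length N (or N+1)")
            self.s_residue = arr
        self.s_residue[0] = 0.0
        if np.any(self.s_residue[1:] >= 0):
            raise ValueError("all per-residue entropy costs must be < 0")

    @classmethod
    def for_variant(cls, n, variant, ca=None, h_scale=1.0):
        return cls(n=n, s_residue=S_RESIDUE_DEFAULTS[variant], ca=ca,
                   h_scale=h_scale)

    def endpoint_distance(self, u: int, v: int) -> float:
        """Native Calpha-Calpha distance of the linker endpoints."""
        if self.ca is None:
            raise ValueError("no Calpha coordinates available for r(u, v)")
        return float(np.linalg.norm(self.ca[u - 1] - self.ca[v - 1]))

    def penalty(self, u: int, v: int, k: int) -> float:
        """``S'(u,v)(n)`` at native count ``k``, cal/(mol.K)."""
        return linker_entropy_penalty(
            u, v, k, self.n, self.endpoint_distance(u, v),
            self.h_scale, self.a, self.persistence,
        )

    def penalty_table(self, u: int, v: int) -> np.ndarray:
        """``S'(u,v)`` for every native count 0..N, cal/(mol.K)."""
        return np.array([self.penalty(u, v, k) for k in range(self.n + 1)])

    def log_penalty_factors(self, u: int, v: int) -> np.ndarray:
        """``S'(u,v)(n) / k_B`` per native count (log Boltzmann factor)."""
        return self.penalty_table(u, v) / KB_CAL
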