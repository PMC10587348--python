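"""Synthetic chains, contact maps and fixture PDB files.

Everything the test-suite and examples need is generated here, seeded
and deterministic: a beta-hairpin-like toy, a discontinuous-domain toy
(attractive contacts only between an N-terminal and a C-terminal block
bridging an inert middle block -- the scenario where linker shortcuts
qualitatively change the landscape), and random compact chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import CA_STEP
from .contact_model import (
    Chain,
    EnergyModel,
    apply_disulfide_bonus,
    weighted_energy_model,
    zero_disulfide_neighborhood,
)
from .entropy_model import EntropyModel

__all__ = ["ToySpec", "make_toy_model", "make_disulfide_fixture",
           "chain_to_pdb"]

#: Inter-strand spacing used by the designed topologies (A); close
#: enough that paired residues sit inside a 5 A Calpha cutoff while
#: diagonal neighbours stay outside.
STRAND_GAP = 4.5


@dataclass
class ToySpec:
    """Recipe for a deterministic toy chain + energy model."""

    n: int
    topology: str = "hairpin"        # hairpin | discontinuous | compact
    seed: int = 0
    energy_range: tuple = (-3.0, -0.5)
    disulfides: list = field(default_factory=list)
    variant: str = "linker"
    epsilon: float = 1.0
    h_scale: float = 1.0

    def __post_init__(self):
        if self.n < 6:
            raise ValueError("toy chains need N >= 6")
        if self.n > 30:
            raise ValueError("toy fixtures are capped at N = 30 "
                             "(oracle compatibility)")
        if self.topology not in ("hairpin", "discontinuous", "compact"):
            raise ValueError(f"unknown topology {self.topology!r}")


def _hairpin_coords(n):
    half = n // 2
    coords = []
    for i in range(half):
        coords.append((0.0, i * CA_STEP, 0.0))
    top = (half - 1) * CA_STEP
    for i in range(n - half):
        coords.append((STRAND_GAP, top - i * CA_STEP, 0.0))
    return np.array(coords)


def _discontinuous_coords(n):
    nb = max(3, n // 3)
    n_mid = n - 2 * nb
    coords = []
    for i in range(nb):                       # N-terminal strand
        coords.append((0.0, i * CA_STEP, 0.0))
    top = (nb - 1) * CA_STEP
    for i in range(n_mid):                    # excursion away from the sheet
        coords.append((0.0, top + CA_STEP, (i + 1) * CA_STEP))
    for i in range(nb):                       # C-terminal strand, paired
        coords.append((STRAND_GAP, top - i * CA_STEP, 0.0))
    return np.array(coords), nb, n_mid


def _compact_coords(n, rng):
    # seeded self-avoiding walk on a cubic lattice with step CA_STEP
    steps = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                      [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    for _attempt in range(200):
        pos = [(0, 0, 0)]
        occupied = {pos[0]}
        ok = True
        for _ in range(n - 1):
            frees = [tuple(np.array(pos[-1]) + s) for s in steps]
            frees = [c for c in frees if c not in occupied]
            if not frees:
                ok = False
                break
            # bias toward the centroid so the walk collapses on itself
            centroid = np.mean(pos, axis=0)
            d2 = np.array([np.sum((np.array(c) - centroid) ** 2)
                           for c in frees])
            w = np.exp(-0.8 * (d2 - d2.min()))
            cand = frees[int(rng.choice(len(frees), p=w / w.sum()))]
            pos.append(cand)
            occupied.add(cand)
        if ok:
            coords = np.array(pos, dtype=float) * CA_STEP
            if _designed_pairs(coords):
                return coords
    raise RuntimeError("self-avoiding walk failed; infeasible topology")


def _designed_pairs(coords, cutoff=5.0):
    n = len(coords)
    pairs = []
    for i in range(1, n - 2):
        for j in range(i + 3, n + 1):
            d = np.linalg.norm(coords[i - 1] - coords[j - 1])
            if d <= cutoff:
                pairs.append((i, j))
    return pairs


def make_toy_model(spec: ToySpec):
    """Deterministic (Chain, EnergyModel, EntropyModel) triple.

    Contact pairs are read off the designed geometry (Calpha pairs
    within 5 A, |i-j| > 2) and receive seeded random raw energies from
    ``spec.energy_range``, then are normalised into weights.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if spec.topology == "hairpin":
        coords = _hairpin_coords(n)
    elif spec.topology == "discontinuous":
        coords, nb, n_mid = _discontinuous_coords(n)
    else:
        coords = _compact_coords(n, rng)

    pairs = _designed_pairs(coords)
    if not pairs:
        raise RuntimeError(f"topology produced no contacts for N={n}")
    if spec.topology == "discontinuous":
        nb = max(3, n // 3)
        blocks = (set(range(1, nb + 1)), set(range(n - nb + 1, n + 1)))
        pairs = [(i, j) for (i, j) in pairs
                 if i in blocks[0] and j in blocks[1]]
    lo, hi = spec.energy_range
    raw = {p: float(rng.uniform(lo, hi)) for p in sorted(pairs)}
    for (a, b) in spec.disulfides:
        raw.setdefault((min(a, b), max(a, b)), float(rng.uniform(lo, hi)))
    model = weighted_energy_model(raw, n)
    model.epsilon = spec.epsilon
    chain = Chain(ca=coords, heavy=[coords[i:i + 1] for i in range(n)],
                  labels=[f"ALA{i + 1}" for i in range(n)])
    entropy = EntropyModel.for_variant(n, spec.variant, ca=coords,
                                       h_scale=spec.h_scale)
    return chain, model, entropy


def make_disulfide_fixture(spec: ToySpec):
    """Base model plus oxidative and disulfide-intact variants.

    Returns ``(chain, entropy, variants)`` where ``variants`` maps
    ``"base"`` to the unmodified model, ``"ss"`` to the model with the
    disulfide raw-energy bonus applied, and ``"ss_intact"`` to the model
    with the contact neighbourhood of each bond zeroed.
    """
    if not spec.disulfides:
        raise ValueError("disulfide fixture needs >= 1 disulfide pair")
    for (a, b) in spec.disulfides:
        if abs(a - b) <= 2:
            raise ValueError(f"disulfide pair ({a}, {b}) too local")
    chain, model, entropy = make_toy_model(spec)
    variants = {
        "base": model,
        "ss": apply_disulfide_bonus(model, spec.disulfides),
        "ss_intact": zero_disulfide_neighborhood(model, spec.disulfides),
    }
    return chain, entropy, variants


def chain_to_pdb(chain: Chain) -> str:
    """Minimal single-chain PDB text (Calpha-only ALA trace)."""
    lines = []
    for i in range(chain.n):
        x, y, z = chain.ca[i]
        lines.append(
            f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
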