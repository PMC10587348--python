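"""Native contact maps and contact energies.

Builds the symmetric contact-weight matrix ``e[i, j]`` either from a
structure (uniform weighting by a heavy-atom distance cutoff) or from a
supplied residue-pair energy table in kcal/mol (normalised by the
maximum absolute retained value).  Also implements the disulfide
conventions: a large negative raw-energy bonus for oxidative folding,
and zeroing of the contact neighbourhood for disulfide-intact folding.

All residue indices in the public API are 1-based; matrices are stored
with shape ``(N+1, N+1)`` so that index ``i`` means residue ``i``.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import CONTACT_CUTOFF, DISULFIDE_BONUS, LINKER_THRESHOLD

log = logging.getLogger(__name__)

__all__ = [
    "Chain",
    "EnergyModel",
    "read_structure",
    "geometric_contact_map",
    "weighted_energy_model",
    "apply_disulfide_bonus",
    "zero_disulfide_neighborhood",
    "linker_set",
    "linker_gain",
    "mask_region",
    "masked_model",
    "read_energy_table",
    "write_contact_map",
]


@dataclass
class Chain:
    """A single protein chain: Calpha trace plus optional heavy atoms."""

    ca: np.ndarray                       # (N, 3) Calpha coordinates, A
    heavy: list | None = None            # per-residue (k_i, 3) arrays
    labels: list | None = None           # original residue identifiers

    def __post_init__(self):
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.ndim != 2 or self.ca.shape[1] != 3:
            raise ValueError("ca must be an (N, 3) array")
        if self.n < 3:
            raise ValueError("chain must have at least 3 residues")

    @property
    def n(self) -> int:
        return self.ca.shape[0]

    def ca_of(self, i: int) -> np.ndarray:
        """Calpha coordinates of residue ``i`` (1-based)."""
        return self.ca[i - 1]

    def ca_distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.ca_of(i) - self.ca_of(j)))


@dataclass
class EnergyModel:
    """Contact weights, scale and disulfide bookkeeping.

    ``weights[i, j]`` is the dimensionless contact weight ``e_{i,j}``;
    the physical contact energy is ``epsilon * weights[i, j]`` kcal/mol.
    ``raw`` holds the unnormalised pairwise energies (kcal/mol) when the
    model was built from an energy table.  Weights of flagged disulfide
    pairs may exceed 1 in magnitude (documented exception).
    """

    n: int
    weights: np.ndarray                  # (N+1, N+1)
    epsilon: float = 1.0
    raw: np.ndarray | None = None        # (N+1, N+1), kcal/mol
    normalization: float | None = None   # max |raw| over retained pairs
    disulfides: list = field(default_factory=list)

    def copy(self) -> "EnergyModel":
        return replace(
            self,
            weights=self.weights.copy(),
            raw=None if self.raw is None else self.raw.copy(),
            disulfides=list(self.disulfides),
        )

    def energy_matrix(self) -> np.ndarray:
        """Contact energies ``epsilon * e`` in kcal/mol, (N+1, N+1)."""
        return self.epsilon * self.weights

    def contact_pairs(self):
        """Sorted (i, j) with i < j and nonzero weight."""
        iu, ju = np.nonzero(np.triu(self.weights))
        return sorted(zip(iu.tolist(), ju.tolist()))

    def validate(self):
        w = self.weights
        if not np.allclose(w, w.T, atol=0.0):
            raise ValueError("weight matrix must be exactly symmetric")
        n = self.n
        ii, jj = np.indices(w.shape)
        local = np.abs(ii - jj) <= 2
        if np.any(w[local] != 0.0):
            raise ValueError("weights must vanish for |i-j| <= 2")
        ss = np.zeros_like(w, dtype=bool)
        for (a, b) in self.disulfides:
            ss[a, b] = ss[b, a] = True
        if np.any(np.abs(w[~ss]) > 1.0 + 1e-12):
            raise ValueError("|e| must not exceed 1 for non-disulfide pairs")
        for (a, b) in self.disulfides:
            if abs(a - b) <= 2 or not (1 <= a <= n and 1 <= b <= n):
                raise ValueError(f"invalid disulfide pair ({a}, {b})")
        return self


def _check_pairs(pairs, n):
    for (a, b) in pairs:
        if not (1 <= a <= n and 1 <= b <= n):
            raise ValueError(f"residue pair ({a}, {b}) outside 1..{n}")
        if abs(a - b) <= 2:
            raise ValueError(f"pair ({a}, {b}) too local (|i-j| <= 2)")


# ---------------------------------------------------------------------------
# structure input
# ---------------------------------------------------------------------------

def read_structure(pdb_text: str, chain_id: str | None = None) -> Chain:
    """Parse a PDB-format string into a :class:`Chain`.

    Uses model 1 (a notice is logged for multi-model files) and the
    first chain, or the chain selected by ``chain_id``.  Residues are
    renumbered 1..N in sequence order; the first altloc wins.  A residue
    without a Calpha atom is a hard error.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("input", io.StringIO(pdb_text))

    models = list(structure)
    if not models:
        raise ValueError("no models found in PDB input")
    if len(models) > 1:
        log.info("multi-model PDB: using model 1 of %d", len(models))
    model = models[0]

    chain = None
    for ch in model:
        if chain_id is None or ch.id == chain_id:
            chain = ch
            break
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not found")

    ca, heavy, labels = [], [], []
    mapping = []
    for res in chain:
        if res.id[0] != " ":       # skip waters / heteroatoms
            continue
        atoms = {}
        for atom in res.get_atoms():
            if atom.element == "H":
                continue
            atoms.setdefault(atom.get_name(), atom)  # first altloc wins
        if "CA" not in atoms:
            raise ValueError(
                f"residue {res.get_resname()} {res.id[1]} lacks a CA atom"
            )
        ca.append(atoms["CA"].get_coord())
        heavy.append(np.array([a.get_coord() for a in atoms.values()]))
        labels.append(f"{res.get_resname()}{res.id[1]}{res.id[2].strip()}")
        mapping.append((len(ca), res.id[1]))
    if len(ca) < 3:
        raise ValueError("selected chain has fewer than 3 residues with CA")
    log.info(
        "renumbered %d residues 1..%d (author numbering %s..%s)",
        len(ca), len(ca), mapping[0][1], mapping[-1][1],
    )
    return Chain(ca=np.array(ca), heavy=heavy, labels=labels)


# ---------------------------------------------------------------------------
# energy models
# ---------------------------------------------------------------------------

def geometric_contact_map(chain: Chain, cutoff: float = CONTACT_CUTOFF,
                          ca_fallback: bool = False) -> EnergyModel:
    """Uniform contact map: ``e = -1`` for heavy-atom pairs within cutoff.

    Pairs with ``|i - j| <= 2`` are excluded.  Without heavy atoms, an
    error directs the caller to the Calpha-only fallback (non-standard
    behaviour, logged).
    """
    n = chain.n
    if chain.heavy is None:
        if not ca_fallback:
            raise ValueError(
                "no heavy-atom coordinates; pass ca_fallback=True to use "
                "Calpha-Calpha distances (non-standard)"
            )
        log.warning("using Calpha-Calpha distances for contacts (fallback)")
        coords = [chain.ca[i:i + 1] for i in range(n)]
    else:
        coords = chain.heavy
    w = np.zeros((n + 1, n + 1))
    for i in range(1, n):
        for j in range(i + 3, n + 1):
            d = np.linalg.norm(
                coords[i - 1][:, None, :] - coords[j - 1][None, :, :], axis=-1
            )
            if d.min() <= cutoff:
                w[i, j] = w[j, i] = -1.0
    return EnergyModel(n=n, weights=w).validate()


def weighted_energy_model(raw, n: int) -> EnergyModel:
    """Normalise a raw pairwise energy table (kcal/mol) into weights.

    ``raw`` may be a ``{(i, j): energy}`` mapping or an ``(N+1, N+1)``
    array (1-based).  Pairs with ``|i - j| <= 2`` are dropped *before*
    normalisation; weights are ``raw / max|raw|`` over retained pairs.
    Asymmetric tables are symmetrised by averaging with a warning.
    """
    mat = np.zeros((n + 1, n + 1))
    if isinstance(raw, dict):
        for (i, j), e in raw.items():
            if not (1 <= i <= n and 1 <= j <= n):
                raise ValueError(f"pair ({i}, {j}) outside 1..{n}")
            mat[i, j] += e
            if i != j:
                mat[j, i] += e
    else:
        arr = np.asarray(raw, dtype=float)
        if arr.shape != (n + 1, n + 1):
            raise ValueError("raw array must have shape (N+1, N+1)")
        if not np.allclose(arr, arr.T):
            warnings.warn("asymmetric energy table symmetrised by averaging")
            arr = 0.5 * (arr + arr.T)
        mat = arr.copy()
    ii, jj = np.indices(mat.shape)
    mat[np.abs(ii - jj) <= 2] = 0.0
    norm = float(np.max(np.abs(mat)))
    if norm == 0.0:
        raise ValueError("all retained raw energies are zero; "
                         "normalisation undefined")
    return EnergyModel(
        n=n, weights=mat / norm, raw=mat, normalization=norm
    ).validate()


def apply_disulfide_bonus(model: EnergyModel, pairs,
                          bonus: float = DISULFIDE_BONUS,
                          weight_increment: float = -10.0) -> EnergyModel:
    """Add the disulfide stabilisation to the raw energy of each pair.

    The normalising maximum is *not* recomputed, so disulfide weights
    may exceed 1 in magnitude; such pairs are flagged in
    ``model.disulfides``.  For models without raw energies the bonus is
    applied directly to the weights as ``weight_increment`` (logged,
    non-paper convention scaled to the uniform weighting).
    """
    _check_pairs(pairs, model.n)
    out = model.copy()
    for (a, b) in pairs:
        if out.raw is not None:
            out.raw[a, b] += bonus
            out.raw[b, a] = out.raw[a, b]
            out.weights[a, b] = out.raw[a, b] / out.normalization
            out.weights[b, a] = out.weights[a, b]
        else:
            if bonus != 0.0:
                inc = weight_increment
                log.info(
                    "no raw energies: disulfide (%d, %d) weight incremented "
                    "by %g", a, b, inc,
                )
                out.weights[a, b] += inc
                out.weights[b, a] = out.weights[a, b]
        if bonus != 0.0 and (a, b) not in out.disulfides:
            out.disulfides.append((a, b))
    return out


def _neighborhood(i, j, n):
    """The five pairs (i, j), (i+-1, j), (i, j+-1) clipped to range."""
    cand = [(i, j), (i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
    return [(a, b) for (a, b) in cand if 1 <= a <= n and 1 <= b <= n]


def zero_disulfide_neighborhood(model: EnergyModel, pairs) -> EnergyModel:
    """Zero the contact weights around each disulfide pair.

    Preparation step for disulfide-intact folding: the covalent linker
    replaces the contact energy, so the five weights (i, j), (i+-1, j),
    (i, j+-1) are removed (raw energies likewise, so the pairs do not
    re-qualify as virtual linkers).
    """
    _check_pairs(pairs, model.n)
    out = model.copy()
    for (i, j) in pairs:
        for (a, b) in _neighborhood(i, j, model.n):
            out.weights[a, b] = out.weights[b, a] = 0.0
            if out.raw is not None:
                out.raw[a, b] = out.raw[b, a] = 0.0
        if (i, j) not in out.disulfides:
            out.disulfides.append((i, j))
    return out


def linker_set(model: EnergyModel, threshold: float = LINKER_THRESHOLD):
    """Linker-eligible pairs: raw energy strictly below ``threshold``.

    Returns sorted (u, v) with u < v and |u - v| > 2.  Without raw
    energies (uniform model), all attractive contact pairs qualify and a
    notice is logged.
    """
    n = model.n
    if model.raw is not None:
        src = model.raw
        cut = threshold
    else:
        log.info("no raw energies: linker set = all attractive contacts")
        src = model.weights
        cut = 0.0
    out = []
    for u in range(1, n):
        for v in range(u + 3, n + 1):
            if src[u, v] < cut:
                out.append((u, v))
    return out


def linker_gain(model: EnergyModel, u: int, v: int):
    """Contact energy gained by forming a linker at (u, v).

    Returns ``(gain_kcal, mask_pairs)`` where the gain is
    ``epsilon * (e[u,v] + e[u+1,v] + e[u-1,v] + e[u,v+1] + e[u,v-1])``
    (out-of-range terms are zero) and ``mask_pairs`` is the set of pairs
    whose weights must be zeroed in the linked Hamiltonian to avoid
    double counting.
    """
    pairs = _neighborhood(u, v, model.n)
    gain = model.epsilon * sum(model.weights[a, b] for (a, b) in pairs)
    return gain, pairs


def mask_region(model: EnergyModel, residues) -> EnergyModel:
    """Zero all contact weights touching the listed residues."""
    residues = sorted(set(int(r) for r in residues))
    for r in residues:
        if not (1 <= r <= model.n):
            raise ValueError(f"residue {r} outside 1..{model.n}")
    out = model.copy()
    for r in residues:
        out.weights[r, :] = 0.0
        out.weights[:, r] = 0.0
        if out.raw is not None:
            out.raw[r, :] = 0.0
            out.raw[:, r] = 0.0
    return out


def masked_model(model: EnergyModel, pairs) -> EnergyModel:
    """Copy of ``model`` with the given weight pairs zeroed (symmetric)."""
    out = model.copy()
    for (a, b) in pairs:
        out.weights[a, b] = out.weights[b, a] = 0.0
    return out


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------

def read_energy_table(text: str) -> dict:
    """Parse a 3-column TSV ``i<TAB>j<TAB>energy_kcal_mol`` (1-based).

    A header line and ``#`` comments are tolerated.
    """
    table = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected 3 columns")
        try:
            i, j, e = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError:
            if lineno == 1:
                continue       # header
            raise ValueError(f"line {lineno}: cannot parse {line!r}")
        table[(i, j)] = e
    return table


def write_contact_map(model: EnergyModel):
    """Render (TSV text, JSON sidecar text) for a contact map."""
    lines = ["i\tj\te_ij"]
    for (i, j) in model.contact_pairs():
        lines.append(f"{i}\t{j}\t{model.weights[i, j]:.10g}")
    sidecar = {
        "n_residues": model.n,
        "epsilon": model.epsilon,
        "normalization": model.normalization,
        "disulfides": [list(p) for p in model.disulfides],
        "n_contacts": len(model.contact_pairs()),
    }
    return "\n".join(lines) + "\n", json.dumps(sidecar, indent=2)
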