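"""Free-energy landscapes, pathways, and theoretical phi-values.

Assembles the model-variant ensembles (plain, linker, oxidative-
disulfide, disulfide-intact) into restricted partition tables, converts
them to free-energy landscapes, finds basins/saddles/dominant pathways
on the discrete order-parameter grid, and computes theoretical
phi-values by pseudo-mutation perturbations of the contact energies.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KCAL
from .contact_model import EnergyModel, linker_gain, masked_model
from .entropy_model import EntropyModel
from .enumeration import enumerate_partition, wsme_l_ensemble
from .partition import OrderParameterSpec, PartitionTable, linked_ensemble
from .transfer_matrix import partition_tm

__all__ = [
    "Landscape",
    "PhiPerturbation",
    "ensemble_partition",
    "free_energy",
    "find_basins_and_saddles",
    "dominant_pathway",
    "phi_theory",
    "phi_ss",
    "domain_phi_average",
    "LYSOZYME_ALPHA_RESIDUES",
    "LYSOZYME_BETA_RESIDUES",
]

#: Residues used to average domain-specific structure formation in hen
#: lysozyme (alpha-domain probe set from pulsed-HX experiments).
LYSOZYME_ALPHA_RESIDUES = (
    8, 10, 11, 12, 13, 17, 23, 27, 28, 29, 31, 34, 36, 37, 38, 39,
    92, 93, 94, 95, 96, 97, 99, 108, 111, 112, 115, 123, 124, 125,
)

#: Beta-domain probe residues of hen lysozyme.
LYSOZYME_BETA_RESIDUES = (
    40, 42, 44, 50, 52, 53, 56, 58, 61, 63, 64, 65, 75, 76, 78, 82, 83, 84,
)


# ---------------------------------------------------------------------------
# ensemble assembly
# ---------------------------------------------------------------------------

def _solve(method):
    if method == "enum":
        return enumerate_partition
    return partition_tm


def ensemble_partition(model: EnergyModel, entropy: EntropyModel,
                       temperature: float, spec: OrderParameterSpec,
                       variant: str = "linker", linkers=None,
                       eta: np.ndarray | None = None,
                       method: str = "tm") -> PartitionTable:
    """Restricted partition table of a model variant.

    ``variant`` is one of ``original1``/``original2`` (no linkers),
    ``linker`` / ``linker_ss`` (ensemble over virtual linkers; for the
    oxidative-disulfide variant the caller applies the disulfide bonus
    to the model first), or ``linker_ss_intact`` (mandatory covalent
    linkers at ``model.disulfides``, weights pre-zeroed around them).
    ``eta`` optionally adds a pseudo-mutation perturbation to every
    contact-energy route.
    """
    energy = model.energy_matrix()
    n = model.n
    if eta is None:
        eta = np.zeros_like(energy)
    pert = energy + eta
    s = entropy.s_residue
    solver = _solve(method)
    linkers = [] if linkers is None else [tuple(l) for l in linkers]

    if variant in ("original1", "original2"):
        return solver(pert, s, temperature, spec)

    def linked_term(base_linkers, uv):
        # eta is added to the masked matrix and therefore acts through
        # the OR-connectivity of each pair (state-gated), including for
        # the five masked pairs whose base energy lives in the constant
        # linker gain.  No unconditional eta gain is added: this keeps
        # the contact-occupancy equivalence of the disulfide-formation
        # estimator exact to first order.
        gain, mask = linker_gain(model, *uv)
        masked = masked_model(model, mask).energy_matrix() + eta
        table = solver(masked, s, temperature, spec,
                       linkers=base_linkers + [uv], gain=gain)
        return table, entropy.log_penalty_factors(*uv)

    if variant in ("linker", "linker_ss"):
        base = solver(pert, s, temperature, spec)
        linked = [linked_term([], uv) for uv in linkers]
        return wsme_l_ensemble(base, linked)

    if variant == "linker_ss_intact":
        ss_pairs = [tuple(p) for p in model.disulfides]
        if not ss_pairs:
            raise ValueError("disulfide-intact variant needs disulfide pairs")
        virtual = [uv for uv in linkers if uv not in ss_pairs]
        out = None
        for ss in ss_pairs:
            z_ss = solver(pert, s, temperature, spec, linkers=[ss])
            inner = [linked_term([ss], uv) for uv in virtual]
            term = linked_ensemble(z_ss, inner)
            out = term if out is None else out.add(term)
        return out.require_positive()

    raise ValueError(f"unknown model variant {variant!r}")


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------

@dataclass
class Landscape:
    """Free energies (kcal/mol) over an order-parameter grid."""

    spec: OrderParameterSpec
    temperature: float
    F: np.ndarray
    annotations: dict = field(default_factory=dict)

    @property
    def ndim(self):
        return self.F.ndim

    def n_grid(self, axis=0):
        return np.arange(self.spec.shape[axis]) / self.spec.sizes[axis]

    def to_tsv(self) -> str:
        lines = []
        if self.ndim == 1:
            lines.append("k\tn\tF_kcal_mol")
            for k, f in enumerate(self.F):
                lines.append(f"{k}\t{k / self.spec.sizes[0]:.6f}\t{f:.8g}")
        else:
            lines.append("k1\tk2\tn1\tn2\tF_kcal_mol")
            n1, n2 = self.spec.sizes
            for k1 in range(self.F.shape[0]):
                for k2 in range(self.F.shape[1]):
                    lines.append(
                        f"{k1}\t{k2}\t{k1 / n1:.6f}\t{k2 / n2:.6f}"
                        f"\t{self.F[k1, k2]:.8g}"
                    )
        return "\n".join(lines) + "\n"


def free_energy(table: PartitionTable) -> Landscape:
    """F = -k_B T ln Z per bin, gauged so the all-unfolded bin is 0.

    Zero bins are reported as +inf.
    """
    table.require_positive()
    kbt = KB_KCAL * table.temperature
    with np.errstate(divide="ignore"):
        f = -kbt * table.logz
    origin = (0,) * table.logz.ndim
    if not np.isfinite(f[origin]):
        raise ValueError("all-unfolded bin has zero partition weight")
    f = f - f[origin]
    f[table.sign == 0] = np.inf
    return Landscape(spec=table.spec, temperature=table.temperature, F=f)


def _local_minima_1d(F):
    out = []
    n = len(F)
    for i in range(n):
        left = F[i - 1] if i > 0 else np.inf
        right = F[i + 1] if i < n - 1 else np.inf
        if np.isfinite(F[i]) and F[i] < left and F[i] < right:
            out.append((i,))
    return out


def _neighbors(idx, shape):
    for ax in range(len(shape)):
        for d in (-1, 1):
            j = list(idx)
            j[ax] += d
            if 0 <= j[ax] < shape[ax]:
                yield tuple(j)


def _local_minima(F):
    if F.ndim == 1:
        return _local_minima_1d(F)
    out = []
    for idx in np.ndindex(F.shape):
        if not np.isfinite(F[idx]):
            continue
        vals = [F[j] for j in _neighbors(idx, F.shape)]
        if all(F[idx] < v for v in vals):
            out.append(idx)
    return out


def _bottleneck_path(F, src, dst):
    """Minimax path between two bins over 4-connected moves.

    Returns (bottleneck value, path, saddle bin) or None when dst is
    unreachable through finite-F bins.
    """
    best = {src: F[src]}
    prev = {src: None}
    heap = [(F[src], src)]
    while heap:
        b, idx = heapq.heappop(heap)
        if idx == dst:
            break
        if b > best.get(idx, np.inf):
            continue
        for nb in _neighbors(idx, F.shape):
            if not np.isfinite(F[nb]):
                continue
            cand = max(b, F[nb])
            if cand < best.get(nb, np.inf):
                best[nb] = cand
                prev[nb] = idx
                heapq.heappush(heap, (cand, nb))
    if dst not in prev and dst != src:
        return None
    path = [dst]
    while path[-1] != src:
        path.append(prev[path[-1]])
    path.reverse()
    saddle = max(path, key=lambda p: F[p])
    return best[dst], path, saddle


def find_basins_and_saddles(ls: Landscape) -> dict:
    """Locate basins (local minima) and saddles between them.

    1D: saddle between adjacent basins is the maximum bin between them.
    2D: saddle between each basin pair is the minimax bin over all
    4-connected paths.  A monotone landscape yields a single basin and
    no saddle (downhill case).
    """
    F = ls.F
    basins = _local_minima(F)
    if not basins:
        # monotone landscape: the lowest finite bin is the only basin
        finite = np.where(np.isfinite(F))
        idx = np.argmin(F[finite])
        basins = [tuple(int(c[idx]) for c in finite)]
    saddles = {}
    if ls.ndim == 1:
        order = sorted(basins)
        for b1, b2 in zip(order[:-1], order[1:]):
            seg = F[b1[0]:b2[0] + 1]
            k = int(np.argmax(seg)) + b1[0]
            saddles[(b1, b2)] = {"bin": (k,), "F": float(F[k])}
    else:
        for i, b1 in enumerate(basins):
            for b2 in basins[i + 1:]:
                res = _bottleneck_path(F, b1, b2)
                if res is None:
                    continue
                _, path, saddle = res
                saddles[(b1, b2)] = {
                    "bin": saddle, "F": float(F[saddle]), "path": path,
                }
    ann = {
        "basins": basins,
        "basin_F": {b: float(F[b]) for b in basins},
        "saddles": saddles,
    }
    ls.annotations.update(ann)
    return ann


def dominant_pathway(ls: Landscape) -> dict:
    """Monotone U -> N grid path minimising the maximum free energy.

    Candidate paths increase one native count per step (so the blended
    order parameter never decreases).  Ties are broken by the lower
    path integral of F, then lexicographically.
    """
    if ls.ndim != 2:
        raise ValueError("dominant pathway requires a 2D landscape")
    F = ls.F
    n1, n2 = F.shape
    # minimax cost-to-go
    G = np.full(F.shape, np.inf)
    G[-1, -1] = F[-1, -1]
    for i in range(n1 - 1, -1, -1):
        for j in range(n2 - 1, -1, -1):
            if (i, j) == (n1 - 1, n2 - 1):
                continue
            succ = min(
                G[i + 1, j] if i + 1 < n1 else np.inf,
                G[i, j + 1] if j + 1 < n2 else np.inf,
            )
            G[i, j] = max(F[i, j], succ)
    mstar = G[0, 0]
    if not np.isfinite(mstar):
        raise ValueError("no connected finite-F monotone path from U to N")
    allowed = F <= mstar + 1e-12
    S = np.full(F.shape, np.inf)
    if allowed[-1, -1]:
        S[-1, -1] = F[-1, -1]
    for i in range(n1 - 1, -1, -1):
        for j in range(n2 - 1, -1, -1):
            if (i, j) == (n1 - 1, n2 - 1) or not allowed[i, j]:
                continue
            succ = min(
                S[i + 1, j] if i + 1 < n1 else np.inf,
                S[i, j + 1] if j + 1 < n2 else np.inf,
            )
            S[i, j] = F[i, j] + succ
    path = [(0, 0)]
    while path[-1] != (n1 - 1, n2 - 1):
        i, j = path[-1]
        cands = []
        if j + 1 < n2 and np.isfinite(S[i, j + 1]):
            cands.append((S[i, j + 1], (i, j + 1)))
        if i + 1 < n1 and np.isfinite(S[i + 1, j]):
            cands.append((S[i + 1, j], (i + 1, j)))
        if not cands:
            raise ValueError("pathway reconstruction failed")
        path.append(min(cands)[1])
    npath = ls.spec.n_pathway()
    result = {
        "path": path,
        "n_pathway": [float(npath[p]) for p in path],
        "F": [float(F[p]) for p in path],
        "max_F": float(mstar),
    }
    ls.annotations["pathway"] = result
    return result


# ---------------------------------------------------------------------------
# theoretical phi-values
# ---------------------------------------------------------------------------

@dataclass
class PhiPerturbation:
    """Pseudo-mutation: contact-energy increments eta (kcal/mol).

    ``eta[i, j] = scale * |E[i, j]|`` for attractive contacts of the
    target residue (or of the single target pair), 0 otherwise.
    """

    n: int
    eta: np.ndarray
    target: object

    @classmethod
    def for_residue(cls, model: EnergyModel, residue: int,
                    scale: float = 0.1) -> "PhiPerturbation":
        energy = model.energy_matrix()
        eta = np.zeros_like(energy)
        l = int(residue)
        if not (1 <= l <= model.n):
            raise ValueError(f"residue {l} outside 1..{model.n}")
        for i in range(1, model.n + 1):
            if energy[i, l] < 0:
                eta[i, l] = eta[l, i] = scale * abs(energy[i, l])
        return cls(n=model.n, eta=eta, target=l)

    @classmethod
    def for_pair(cls, model: EnergyModel, pair, scale: float = 0.1
                 ) -> "PhiPerturbation":
        (i, j) = pair
        energy = model.energy_matrix()
        if energy[i, j] >= 0:
            raise ValueError(
                f"contact ({i}, {j}) is not attractive; eta undefined"
            )
        eta = np.zeros_like(energy)
        eta[i, j] = eta[j, i] = scale * abs(energy[i, j])
        return cls(n=model.n, eta=eta, target=(i, j))


def _log_ratio(table: PartitionTable, bins, origin):
    return np.array([table.logz[b] - table.logz[origin] for b in bins])


def phi_theory(model: EnergyModel, entropy: EntropyModel, temperature: float,
               spec: OrderParameterSpec, residues=None, path=None,
               variant: str = "linker", linkers=None, method: str = "tm",
               base_table: PartitionTable | None = None,
               denom_floor: float = 1e-8):
    """Theoretical phi-values along a set of bins.

    For each residue, all its attractive contacts are weakened
    simultaneously by 10% and the free-energy response along the path is
    normalised by the total (unfolded -> native) response.  Negative
    values are clamped to zero; residues whose total response magnitude
    falls below ``denom_floor`` kcal/mol are reported as NaN (missing).

    Returns ``(residues, bins, phi_matrix)``.
    """
    if residues is None:
        residues = range(1, model.n + 1)
    residues = [int(r) for r in residues]
    if base_table is None:
        base_table = ensemble_partition(model, entropy, temperature, spec,
                                        variant=variant, linkers=linkers,
                                        method=method)
    origin = (0,) * base_table.logz.ndim
    native = tuple(s - 1 for s in base_table.logz.shape)
    if path is None:
        if base_table.logz.ndim != 1:
            raise ValueError("a path is required for 2D tables")
        path = [(k,) for k in range(base_table.logz.shape[0])]
    bins = [tuple(b) if not np.isscalar(b) else (b,) for b in path]
    kbt = KB_KCAL * temperature

    base_r = _log_ratio(base_table, bins, origin)
    base_nat = base_table.logz[native] - base_table.logz[origin]

    phi = np.full((len(residues), len(bins)), np.nan)
    for row, l in enumerate(residues):
        pert = PhiPerturbation.for_residue(model, l)
        if not np.any(pert.eta):
            continue
        mu = ensemble_partition(model, entropy, temperature, spec,
                                variant=variant, linkers=linkers,
                                eta=pert.eta, method=method)
        mu_r = _log_ratio(mu, bins, origin)
        mu_nat = mu.logz[native] - mu.logz[origin]
        denom = -kbt * (mu_nat - base_nat)
        if abs(denom) < denom_floor:
            continue
        vals = -kbt * (mu_r - base_r) / denom
        phi[row] = np.maximum(vals, 0.0)
    return residues, bins, phi


def phi_ss(model: EnergyModel, entropy: EntropyModel, temperature: float,
           spec: OrderParameterSpec, pair, variant: str = "linker_ss",
           linkers=None, method: str = "tm", scale: float = 0.1,
           base_table: PartitionTable | None = None) -> np.ndarray:
    """Degree of formation of one (disulfide) contact per bin.

    Finite-difference estimate: the contact is weakened by
    ``eta = scale * |E|`` and the free-energy response is divided by
    eta, approximating the thermal contact-formation probability to
    first order.
    """
    pert = PhiPerturbation.for_pair(model, pair, scale=scale)
    if base_table is None:
        base_table = ensemble_partition(model, entropy, temperature, spec,
                                        variant=variant, linkers=linkers,
                                        method=method)
    mu = ensemble_partition(model, entropy, temperature, spec,
                            variant=variant, linkers=linkers,
                            eta=pert.eta, method=method)
    (i, j) = pert.target
    eta_ij = pert.eta[i, j]
    kbt = KB_KCAL * temperature
    return (-kbt * (mu.logz - base_table.logz)) / eta_ij


def domain_phi_average(residues, phi_row_by_residue: dict, residue_set
                       ) -> float:
    """Arithmetic mean of phi over a residue set (NaNs excluded)."""
    residue_set = list(residue_set)
    if not residue_set:
        raise ValueError("residue set must be non-empty")
    vals = [phi_row_by_residue[r] for r in residue_set
            if r in phi_row_by_residue and np.isfinite(phi_row_by_residue[r])]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def phi_profile_tsv(residues, bins, phi) -> str:
    header = "residue\t" + "\t".join(
        "bin_" + "_".join(str(x) for x in b) for b in bins
    )
    lines = [header]
    for r, row in zip(residues, phi):
        cells = "\t".join("" if not np.isfinite(x) else f"{x:.6g}"
                          for x in row)
        lines.append(f"{r}\t{cells}")
    return "\n".join(lines) + "\n"


def annotations_json(ls: Landscape) -> str:
    def _key(k):
        return ",".join(str(x) for x in k) if isinstance(k, tuple) else str(k)

    ann = {}
    for name, value in ls.annotations.items():
        if name == "saddles":
            ann[name] = {
                f"{_key(a)}|{_key(b)}": {
                    "bin": list(v["bin"]), "F": v["F"],
                }
                for (a, b), v in value.items()
            }
        elif name == "basin_F":
            ann[name] = {_key(k): v for k, v in value.items()}
        elif name == "basins":
            ann[name] = [list(b) for b in value]
        elif name == "pathway":
            ann[name] = {
                "path": [list(p) for p in value["path"]],
                "n_pathway": value["n_pathway"],
                "F": value["F"],
                "max_F": value["max_F"],
            }
        else:
            ann[name] = value
    return json.dumps(ann, indent=2)
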