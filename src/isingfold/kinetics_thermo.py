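"""Folding kinetics and thermodynamic scans.

1D master-equation folding rates (macroscopic rate = slowest nonzero
relaxation eigenvalue), two-state stability, grid fitting of the energy
scale and linker-entropy scale, the multi-state kinetic scheme driven
by 2D-landscape barriers, domain-formation time courses, and heat
capacity / temperature-dependent contact-energy scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .constants import KB_KCAL, PREFACTOR_A
from .landscape_phi import Landscape, find_basins_and_saddles, _bottleneck_path

__all__ = [
    "RateModel1D",
    "SchemeModel",
    "ThermoScan",
    "folding_rate_1d",
    "stability",
    "fit_parameters",
    "scheme_prefactor",
    "scheme_rates",
    "scheme_matrix",
    "irreversible_scheme_matrix",
    "solve_scheme",
    "terminal_populations",
    "simulate_terminal_split",
    "domain_time_evolution",
    "epsilon_of_T",
    "heat_capacity",
]


# ---------------------------------------------------------------------------
# 1D master equation
# ---------------------------------------------------------------------------

@dataclass
class RateModel1D:
    """Microscopic rates between adjacent native-count bins."""

    up: np.ndarray          # k_{i -> i+1}
    down: np.ndarray        # k_{i+1 -> i}
    matrix: np.ndarray      # dC/dt = matrix @ C
    prefactor: float
    k_f: float


def folding_rate_1d(ls: Landscape, prefactor: float = PREFACTOR_A
                    ) -> RateModel1D:
    """Macroscopic folding rate from a 1D free-energy landscape.

    Nearest-neighbour rates ``k = A exp(-(F_next - F_cur) / 2 k_B T)``
    form a tridiagonal generator; the folding rate is the eigenvalue of
    smallest nonzero magnitude (computed on the detailed-balance
    symmetrised matrix).
    """
    if ls.ndim != 1:
        raise ValueError("folding_rate_1d needs a 1D landscape")
    F = ls.F
    if not np.all(np.isfinite(F)):
        raise ValueError("landscape has infinite free-energy bins")
    kbt = KB_KCAL * ls.temperature
    nb = len(F)
    up = prefactor * np.exp(-(F[1:] - F[:-1]) / (2 * kbt))
    down = prefactor * np.exp(-(F[:-1] - F[1:]) / (2 * kbt))
    W = np.zeros((nb, nb))
    for i in range(nb - 1):
        W[i + 1, i] += up[i]
        W[i, i] -= up[i]
        W[i, i + 1] += down[i]
        W[i + 1, i + 1] -= down[i]
    # similarity transform to a symmetric matrix (same spectrum)
    half = np.exp(-F / (2 * kbt))
    B = (1.0 / half)[:, None] * W * half[None, :]
    eig = scipy.linalg.eigvalsh(0.5 * (B + B.T))
    nonzero = np.abs(eig)[np.abs(eig) > 1e-9 * np.max(np.abs(eig))]
    k_f = float(np.min(nonzero))
    return RateModel1D(up=up, down=down, matrix=W, prefactor=prefactor,
                       k_f=k_f)


def stability(ls: Landscape) -> float:
    """Two-state stability: F(native basin) - F(unfolded basin), kcal/mol."""
    ann = find_basins_and_saddles(ls)
    basins = sorted(ann["basins"])
    if len(basins) < 2:
        raise ValueError("fewer than two basins: two-state stability "
                         "undefined")
    unfolded, native = basins[0], basins[-1]
    return float(ls.F[native] - ls.F[unfolded])


def fit_parameters(builder, dg_target: float, kf_target: float | None = None,
                   h_grid=None, eps_bounds=(0.05, 6.0), temperature=298.0,
                   eps_tol: float = 1e-4):
    """Grid search over the linker-entropy scale with per-point 1D fits.

    ``builder(eps, h)`` must return ``(dG, k_f)`` (``k_f`` may be None
    when fitting stability only).  For each h on the grid the energy
    scale eps minimising the loss is found by bounded scalar search.
    Returns ``(records, best)`` where records hold (h, eps, loss) per
    grid point; selection among near-minimal pairs is left to the
    caller.
    """
    if h_grid is None:
        h_grid = np.round(np.arange(0.5, 2.0 + 1e-9, 0.1), 10)
    kbt = KB_KCAL * temperature

    def loss_at(eps, h):
        dg, kf = builder(eps, h)
        big = 1e12              # finite penalty keeps the scalar search sane
        if dg is None or not np.isfinite(dg):
            return big          # e.g. landscape not two-state at this eps
        loss = ((dg - dg_target) / kbt) ** 2
        if kf_target is not None:
            if kf is None or kf <= 0:
                return big
            loss += np.log(kf / kf_target) ** 2
        return loss

    records = []
    for h in h_grid:
        res = scipy.optimize.minimize_scalar(
            loss_at, bounds=eps_bounds, args=(h,), method="bounded",
            options={"xatol": eps_tol},
        )
        if not res.success:
            raise RuntimeError(
                f"eps search failed at h={h}: {res.message}; "
                f"scanned bounds {eps_bounds}"
            )
        records.append({"h": float(h), "eps": float(res.x),
                        "loss": float(res.fun)})
    best = min(records, key=lambda r: r["loss"])
    return records, best


# ---------------------------------------------------------------------------
# multi-state kinetic scheme
# ---------------------------------------------------------------------------

@dataclass
class SchemeModel:
    """Named kinetic states with barrier-derived microscopic rates."""

    states: list
    rates: dict                      # (X, Y) -> k_XY (1/s)
    barriers: dict = field(default_factory=dict)
    prefactors: dict = field(default_factory=dict)
    matrix: np.ndarray | None = None  # dC/dt = matrix @ C


def scheme_prefactor(n_saddle: float, a0: float = PREFACTOR_A) -> float:
    """Internal-friction prefactor A(n) = A0 / (1 + 5 n^2)."""
    return a0 / (1.0 + 5.0 * n_saddle ** 2)


def scheme_rates(ls: Landscape, state_bins: dict, transitions,
                 a0: float = PREFACTOR_A) -> SchemeModel:
    """Microscopic rates between named basins of a 2D landscape.

    ``state_bins`` maps state name -> basin bin; ``transitions`` lists
    (X, Y) name pairs (both directions are generated).  The barrier for
    X -> Y is F(saddle) - F(X basin) with the saddle from the minimax
    path between the two basins; the prefactor is evaluated at the
    saddle's blended order parameter.
    """
    kbt = KB_KCAL * ls.temperature
    npath = ls.spec.n_pathway()
    rates, barriers, prefs = {}, {}, {}
    for (x, y) in transitions:
        bx, by = tuple(state_bins[x]), tuple(state_bins[y])
        res = _bottleneck_path(ls.F, bx, by)
        if res is None:
            raise ValueError(f"no finite-F path between states {x} and {y}")
        _, _, saddle = res
        n_dag = float(npath[saddle])
        a = scheme_prefactor(n_dag, a0)
        for (src, dst, bsrc) in ((x, y, bx), (y, x, by)):
            dfd = float(ls.F[saddle] - ls.F[bsrc])
            if dfd < 0:
                raise ValueError(
                    f"saddle below basin for {src}->{dst}; "
                    "basin assignment inconsistent"
                )
            rates[(src, dst)] = a * np.exp(-dfd / kbt)
            barriers[(src, dst)] = dfd
            prefs[(src, dst)] = a
    states = list(state_bins)
    model = SchemeModel(states=states, rates=rates, barriers=barriers,
                        prefactors=prefs)
    model.matrix = scheme_matrix(states, rates)
    return model


def scheme_matrix(states, rates) -> np.ndarray:
    """Conservative generator: dC/dt = A C with columns of A summing to 0."""
    idx = {s: i for i, s in enumerate(states)}
    A = np.zeros((len(states), len(states)))
    for (x, y), k in rates.items():
        A[idx[y], idx[x]] += k
        A[idx[x], idx[x]] -= k
    return A


def irreversible_scheme_matrix(rates: dict) -> np.ndarray:
    """Five-state generator with unfolding from the native state dropped.

    States (U, I1, I2, Np1, Np2); requires rates for U<->I1, I1<->I2,
    I2->Np1 and I1->Np2 (native-state unfolding neglected, valid when
    folding barriers out of N are large).  Np1/Np2 tag the pathway
    taken; their total is the native population.
    """
    need = [("U", "I1"), ("I1", "U"), ("I1", "I2"), ("I2", "I1"),
            ("I2", "Np1"), ("I1", "Np2")]
    k = {}
    for pair in need:
        alt = {("I2", "Np1"): ("I2", "N"), ("I1", "Np2"): ("I1", "N")}
        if pair in rates:
            k[pair] = rates[pair]
        elif pair in alt and alt[pair] in rates:
            k[pair] = rates[alt[pair]]
        else:
            raise ValueError(f"missing rate for transition {pair}")
    A = np.zeros((5, 5))
    iU, i1, i2, p1, p2 = range(5)
    A[i1, iU] += k[("U", "I1")]
    A[iU, iU] -= k[("U", "I1")]
    A[iU, i1] += k[("I1", "U")]
    A[i2, i1] += k[("I1", "I2")]
    A[p2, i1] += k[("I1", "Np2")]
    A[i1, i1] -= k[("I1", "U")] + k[("I1", "I2")] + k[("I1", "Np2")]
    A[i1, i2] += k[("I2", "I1")]
    A[p1, i2] += k[("I2", "Np1")]
    A[i2, i2] -= k[("I2", "I1")] + k[("I2", "Np1")]
    return A


def solve_scheme(A: np.ndarray, t_grid, c0=None):
    """Populations C(t) for dC/dt = A C via eigendecomposition.

    Falls back to numerical integration when A is defective (logged via
    a warning from scipy would be silent; we check conditioning).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if c0 is None:
        c0 = np.zeros(n)
        c0[0] = 1.0
    t_grid = np.asarray(t_grid, dtype=float)
    w, V = scipy.linalg.eig(A)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e10:
        from scipy.integrate import solve_ivp

        sol = solve_ivp(lambda t, c: A @ c, (0.0, float(t_grid[-1])),
                        c0, t_eval=t_grid, rtol=1e-10, atol=1e-12,
                        method="LSODA")
        return sol.y.T
    alpha = np.linalg.solve(V, c0.astype(complex))
    out = np.real(V @ (alpha[:, None] * np.exp(w[:, None] * t_grid[None, :])))
    return out.T


def terminal_populations(A: np.ndarray, c0=None) -> np.ndarray:
    """t -> infinity limit of solve_scheme (zero-eigenvalue projection)."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if c0 is None:
        c0 = np.zeros(n)
        c0[0] = 1.0
    w, V = scipy.linalg.eig(A)
    alpha = np.linalg.solve(V, c0.astype(complex))
    keep = np.abs(w) < 1e-9 * max(1.0, np.max(np.abs(w)))
    return np.real(V @ (alpha * keep))


def simulate_terminal_split(rates_from: dict, n_states: int, n_traj: int,
                            rng, absorbing) -> np.ndarray:
    """Stochastic oracle: terminal-state counts from the embedded chain.

    ``rates_from[x]`` is a list of (target, rate); the jump chain is
    simulated until every trajectory reaches an absorbing state.
    """
    probs = {}
    for x, outs in rates_from.items():
        total = sum(r for _, r in outs)
        probs[x] = ([t for t, _ in outs],
                    np.array([r / total for _, r in outs]))
    state = np.zeros(n_traj, dtype=int)
    absorbing = set(absorbing)
    for _ in range(100000):
        active = ~np.isin(state, list(absorbing))
        if not np.any(active):
            break
        for x, (targets, p) in probs.items():
            sel = active & (state == x)
            cnt = int(np.count_nonzero(sel))
            if cnt:
                state[sel] = rng.choice(targets, size=cnt, p=p)
    else:
        raise RuntimeError("trajectories failed to absorb")
    return np.bincount(state, minlength=n_states)


def domain_time_evolution(populations: np.ndarray, phi_by_state) -> np.ndarray:
    """Domain formation p(t) = sum_X phi_X * C_X(t).

    ``populations`` has shape (n_times, n_states); ``phi_by_state`` is
    the per-state domain-average phi (length n_states).
    """
    phi = np.asarray(phi_by_state, dtype=float)
    return populations @ phi


# ---------------------------------------------------------------------------
# thermodynamic scans
# ---------------------------------------------------------------------------

@dataclass
class ThermoScan:
    """Heat-capacity scan over a uniform temperature grid."""

    T: np.ndarray               # full grid (K)
    T_interior: np.ndarray      # where C is defined
    C: np.ndarray               # kcal/(mol.K), baseline included
    log_z: np.ndarray
    baseline: float = 0.0


def epsilon_of_T(T, eps_f: float, p: float, q: float, T_f: float):
    """Temperature-dependent contact-energy scale.

    ``eps(T) = eps_f + p (1 - T/T_f) - q [(1 - T/T_f) + (T/T_f) ln(T/T_f)]``
    so that ``eps(T_f) = eps_f`` exactly.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    x = T / T_f
    out = eps_f + p * (1.0 - x) - q * ((1.0 - x) + x * np.log(x))
    if out.ndim == 0:
        return float(out)
    return out


def heat_capacity(log_z_of_T, T_grid, baseline: float = 0.0) -> ThermoScan:
    """C(T) = d/dT (k_B T^2 d ln Z / dT) by nested central differences.

    ``log_z_of_T(T)`` returns the total log partition function at T
    (rebuilding the model there, including eps(T) if configured).  The
    inner derivative is evaluated at half-steps so C is defined on all
    interior grid points; the optional baseline (kcal/(mol.K)) is added
    uniformly.
    """
    T = np.asarray(T_grid, dtype=float)
    if len(T) < 5:
        raise ValueError("temperature grid needs >= 5 points")
    h = np.diff(T)
    if not np.allclose(h, h[0], rtol=1e-8, atol=1e-10):
        raise ValueError("temperature grid must be uniform")
    h = float(h[0])
    lnz = np.array([log_z_of_T(t) for t in T])
    t_half = 0.5 * (T[:-1] + T[1:])
    g_half = KB_KCAL * t_half ** 2 * np.diff(lnz) / h
    c = np.diff(g_half) / h
    return ThermoScan(T=T, T_interior=T[1:-1], C=c + baseline,
                      log_z=lnz, baseline=baseline)
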