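import numpy as np
import pytest
from scipy.integrate import solve_ivp

from conftest import random_energy, random_s
from isingfold.constants import KB_CAL, KB_KCAL, PREFACTOR_A
from isingfold.enumeration import enumerate_partition
from isingfold.kinetics_thermo import (
    domain_time_evolution,
    epsilon_of_T,
    fit_parameters,
    folding_rate_1d,
    heat_capacity,
    irreversible_scheme_matrix,
    scheme_matrix,
    scheme_prefactor,
    scheme_rates,
    simulate_terminal_split,
    solve_scheme,
    stability,
    terminal_populations,
)
from isingfold.landscape_phi import (
    Landscape,
    ensemble_partition,
    find_basins_and_saddles,
    free_energy,
)
from isingfold.partition import OrderParameterSpec

T = 300.0


def _ls(F, temperature=T):
    F = np.asarray(F, dtype=float)
    spec = OrderParameterSpec.single(len(F) - 1)
    return Landscape(spec=spec, temperature=temperature, F=F)


class TestFoldingRate1D:
    def test_two_bin_analytic(self):
        ls = _ls([0.0, -2.0])
        rm = folding_rate_1d(ls, prefactor=1.0)
        kbt = KB_KCAL * T
        k01 = np.exp(2.0 / (2 * kbt))
        k10 = np.exp(-2.0 / (2 * kbt))
        assert rm.k_f == pytest.approx(k01 + k10, rel=1e-10)

    def test_flat_landscape_uniform_stationary(self):
        ls = _ls([0.0] * 6)
        rm = folding_rate_1d(ls, prefactor=1.0)
        w, v = np.linalg.eig(rm.matrix)
        stat = np.real(v[:, np.argmin(np.abs(w))])
        stat /= stat.sum()
        assert np.allclose(stat, 1.0 / 6.0, atol=1e-10)

    def test_detailed_balance_stationary_distribution(self, rng):
        F = np.concatenate([[0.0], rng.uniform(-2, 3, 10)])
        ls = _ls(F)
        rm = folding_rate_1d(ls)
        pi = np.exp(-F / (KB_KCAL * T))
        pi /= pi.sum()
        assert np.max(np.abs(rm.matrix @ pi)) < 1e-8 * np.max(
            np.abs(rm.matrix))

    def test_rate_matches_ode_relaxation_oracle(self):
        rng = np.random.default_rng(42)
        F = np.concatenate([[0.0], rng.uniform(-2, 3, 11)])
        ls = _ls(F)
        rm = folding_rate_1d(ls, prefactor=1.0)
        pi = np.exp(-F / (KB_KCAL * T))
        pi /= pi.sum()
        c0 = np.eye(len(F))[0]
        t_end = 40.0 / rm.k_f
        sol = solve_ivp(lambda t, c: rm.matrix @ c, (0, t_end), c0,
                        t_eval=np.linspace(0.3 * t_end, 0.6 * t_end, 50),
                        rtol=1e-11, atol=1e-13)
        dist = np.linalg.norm(sol.y.T - pi, axis=1)
        slope = np.polyfit(sol.t, np.log(dist), 1)[0]
        assert -slope == pytest.approx(rm.k_f, rel=1e-3)

    def test_infinite_bins_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            folding_rate_1d(_ls([0.0, np.inf, -1.0]))

    def test_columns_sum_to_zero(self, rng):
        F = np.concatenate([[0.0], rng.uniform(-1, 1, 8)])
        rm = folding_rate_1d(_ls(F))
        assert np.allclose(rm.matrix.sum(axis=0), 0.0, atol=1e-4)


class TestStability:
    def test_definition(self):
        assert stability(_ls([0.0, 4.0, -5.0])) == pytest.approx(-5.0)

    def test_symmetric_double_well(self):
        assert stability(_ls([-1.0, 4.0, -1.0])) == pytest.approx(0.0)

    def test_single_basin_rejected(self):
        with pytest.raises(ValueError, match="two-state"):
            stability(_ls([0.0, -1.0, -2.0, -3.0]))

    def test_matches_oracle_partition(self):
        from isingfold.synthetic_fixtures import ToySpec, make_toy_model

        n = 12
        chain, model, entropy = make_toy_model(
            ToySpec(n=n, topology="compact", seed=8, epsilon=2.8))
        e = model.energy_matrix()
        s = entropy.s_residue
        z = enumerate_partition(e, s, 298.0, OrderParameterSpec.single(n))
        ls = free_energy(z)
        dg = stability(ls)
        ann = ls.annotations
        basins = sorted(ann["basins"])
        assert dg == pytest.approx(ls.F[basins[-1]] - ls.F[basins[0]])


class TestFitParameters:
    def _builder(self, model, entropy, linkers, spec):
        from isingfold.contact_model import linker_set

        def build(eps, h):
            m = model.copy()
            m.epsilon = eps
            ent = entropy
            ent = type(entropy)(n=entropy.n, s_residue=entropy.s_residue[1:],
                                h_scale=h, ca=entropy.ca)
            z = ensemble_partition(m, ent, T, spec, variant="linker",
                                   linkers=linkers)
            ls = free_energy(z)
            try:
                dg = stability(ls)
            except ValueError:
                return np.nan, None
            rate = folding_rate_1d(ls)
            return dg, rate.k_f

        return build

    def test_self_target_recovery(self):
        from isingfold.contact_model import linker_set
        from isingfold.synthetic_fixtures import ToySpec, make_toy_model

        chain, model, entropy = make_toy_model(
            ToySpec(n=12, topology="compact", seed=3, h_scale=1.0))
        spec = OrderParameterSpec.single(12)
        linkers = linker_set(model)
        build = self._builder(model, entropy, linkers, spec)
        eps0, h0 = 2.8, 1.0
        dg0, kf0 = build(eps0, h0)
        records, best = fit_parameters(build, dg0, kf0,
                                       h_grid=[0.8, 0.9, 1.0, 1.1, 1.2],
                                       temperature=T)
        assert best["h"] == pytest.approx(h0)
        assert best["eps"] == pytest.approx(eps0, abs=1e-3)
        assert best["loss"] < 1e-8

    def test_stability_only_loss(self):
        def build(eps, h):
            return -2.0 * eps, None

        records, best = fit_parameters(build, -3.0, None,
                                       h_grid=[1.0], temperature=T)
        assert best["eps"] == pytest.approx(1.5, abs=1e-3)
        assert best["loss"] < 1e-10


class TestScheme:
    def test_prefactor_limits(self):
        assert scheme_prefactor(0.0, a0=PREFACTOR_A) == PREFACTOR_A
        assert scheme_prefactor(1.0, a0=PREFACTOR_A) == PREFACTOR_A / 6.0

    def test_rate_formula_with_unique_saddle(self):
        F = np.array([
            [0.0, 9.0],
            [2.0, -1.0],
        ])
        spec = OrderParameterSpec.split(2, [1])
        ls = Landscape(spec=spec, temperature=T, F=F)
        model = scheme_rates(ls, {"U": (0, 0), "N": (1, 1)}, [("U", "N")],
                             a0=1000.0)
        a = scheme_prefactor(0.5, 1000.0)   # saddle (1, 0): n = 1/2
        kbt = KB_KCAL * T
        assert model.rates[("U", "N")] == pytest.approx(
            a * np.exp(-2.0 / kbt), rel=1e-9)
        assert model.rates[("N", "U")] == pytest.approx(
            a * np.exp(-3.0 / kbt), rel=1e-9)

    def test_barrierless_rate_equals_prefactor(self):
        F = np.array([
            [0.0, 9.0],
            [1e-9, -1.0],
        ])
        spec = OrderParameterSpec.split(2, [1])
        ls = Landscape(spec=spec, temperature=T, F=F)
        model = scheme_rates(ls, {"U": (0, 0), "N": (1, 1)}, [("U", "N")],
                             a0=1000.0)
        assert model.rates[("U", "N")] == pytest.approx(
            scheme_prefactor(0.5, 1000.0), rel=1e-6)

    def test_conservative_matrix_columns(self):
        rates = {("U", "I"): 2.0, ("I", "U"): 1.0, ("I", "N"): 5.0,
                 ("N", "I"): 0.1}
        A = scheme_matrix(["U", "I", "N"], rates)
        assert np.allclose(A.sum(axis=0), 0.0)

    def test_population_conservation(self):
        rates = {("U", "I"): 2.0, ("I", "U"): 1.0, ("I", "N"): 5.0,
                 ("N", "I"): 0.1}
        A = scheme_matrix(["U", "I", "N"], rates)
        t = np.geomspace(1e-4, 100, 60)
        pops = solve_scheme(A, t)
        assert np.max(np.abs(pops.sum(axis=1) - 1.0)) < 1e-9

    def test_frozen_system(self):
        A = np.zeros((3, 3))
        pops = solve_scheme(A, [0.0, 1.0, 10.0])
        assert np.allclose(pops, [[1, 0, 0]] * 3)

    def test_matches_ode_oracle(self, rng):
        k = rng.uniform(0.1, 5.0, size=6)
        rates = {("U", "I1"): k[0], ("I1", "U"): k[1], ("I1", "I2"): k[2],
                 ("I2", "I1"): k[3], ("I2", "Np1"): k[4],
                 ("I1", "Np2"): k[5]}
        A = irreversible_scheme_matrix(rates)
        t = np.geomspace(1e-3, 50, 40)
        got = solve_scheme(A, t)
        c0 = np.eye(5)[0]
        sol = solve_ivp(lambda tt, c: A @ c, (0, t[-1]), c0, t_eval=t,
                        rtol=1e-11, atol=1e-13)
        assert np.max(np.abs(got - sol.y.T)) < 1e-7
        assert np.max(np.abs(got.sum(axis=1) - 1.0)) < 1e-9

    def test_terminal_split_matches_stochastic_oracle(self, rng):
        k = {"UI1": 3.0, "I1U": 1.0, "I1I2": 2.0, "I2I1": 0.7,
             "I2Np1": 1.5, "I1Np2": 0.4}
        rates = {("U", "I1"): k["UI1"], ("I1", "U"): k["I1U"],
                 ("I1", "I2"): k["I1I2"], ("I2", "I1"): k["I2I1"],
                 ("I2", "Np1"): k["I2Np1"], ("I1", "Np2"): k["I1Np2"]}
        A = irreversible_scheme_matrix(rates)
        final = terminal_populations(A)
        split = final[3] / (final[3] + final[4])

        rates_from = {
            0: [(1, k["UI1"])],
            1: [(0, k["I1U"]), (2, k["I1I2"]), (4, k["I1Np2"])],
            2: [(1, k["I2I1"]), (3, k["I2Np1"])],
        }
        n_traj = 1_000_000
        counts = simulate_terminal_split(rates_from, 5, n_traj, rng,
                                         absorbing=[3, 4])
        p_hat = counts[3] / n_traj
        sigma = np.sqrt(p_hat * (1 - p_hat) / n_traj)
        assert abs(split - p_hat) < 3 * sigma

    def test_missing_rate_rejected(self):
        with pytest.raises(ValueError, match="missing rate"):
            irreversible_scheme_matrix({("U", "I1"): 1.0})


class TestDomainEvolution:
    def test_initial_value_is_unfolded_phi(self):
        pops = np.array([[1.0, 0.0, 0.0]])
        assert domain_time_evolution(pops, [0.1, 0.5, 1.0])[0] \
            == pytest.approx(0.1)

    def test_terminal_value_is_native_phi(self):
        pops = np.array([[0.0, 0.0, 1.0]])
        assert domain_time_evolution(pops, [0.1, 0.5, 0.9])[0] \
            == pytest.approx(0.9)

    def test_midcourse_weighted_sum(self, rng):
        pops = rng.dirichlet(np.ones(4), size=5)
        phi = rng.random(4)
        got = domain_time_evolution(pops, phi)
        expected = np.array([np.dot(row, phi) for row in pops])
        assert np.allclose(got, expected)


class TestEpsilonOfT:
    def test_identity_at_reference(self):
        assert epsilon_of_T(293.0, 1.783, -0.307, 11.3, 293.0) \
            == pytest.approx(1.783)

    def test_constant_when_p_q_zero(self):
        for t in (250.0, 300.0, 380.0):
            assert epsilon_of_T(t, 2.0, 0.0, 0.0, 293.0) == 2.0

    def test_direct_evaluation_at_350K(self):
        # independent arithmetic with the documented constants
        x = 350.0 / 293.0
        expected = 1.783 + (-0.307) * (1 - x) - 11.3 * ((1 - x)
                                                        + x * np.log(x))
        assert epsilon_of_T(350.0, 1.783, -0.307, 11.3, 293.0) \
            == pytest.approx(expected, rel=1e-12)

    def test_positive_temperature_required(self):
        with pytest.raises(ValueError):
            epsilon_of_T(-5.0, 1.0, 0.0, 0.0, 293.0)


class TestHeatCapacity:
    def test_single_residue_no_contacts_zero(self):
        # ln Z linear in the entropy-only exponent: C must vanish
        def log_z(t):
            return np.logaddexp(0.0, -2.0 / KB_CAL)

        scan = heat_capacity(log_z, np.arange(290.0, 296.0, 1.0))
        assert np.allclose(scan.C, 0.0, atol=1e-12)

    def test_baseline_shift(self, rng):
        n = 8
        e = random_energy(rng, n)
        s = random_s(rng, n)
        spec = OrderParameterSpec.single(n)

        def log_z(t):
            return enumerate_partition(e, s, t, spec).total_log()

        grid = np.arange(290.0, 311.0, 2.0)
        a = heat_capacity(log_z, grid)
        b = heat_capacity(log_z, grid, baseline=8.0)
        assert np.allclose(b.C - a.C, 8.0)

    def test_matches_mean_energy_derivative_oracle(self, rng):
        n = 10
        e = random_energy(rng, n, density=0.7, scale=2.0)
        s = random_s(rng, n)
        spec = OrderParameterSpec.single(n)

        def log_z(t):
            return enumerate_partition(e, s, t, spec).total_log()

        def mean_energy(t):
            # oracle: direct thermal average of the contact Hamiltonian
            beta = 1.0 / (KB_KCAL * t)
            num = 0.0
            den = 0.0
            from isingfold.enumeration import hamiltonian

            for packed in range(1 << n):
                state = [(packed >> k) & 1 for k in range(n)]
                h = hamiltonian(state, e)
                w = np.exp(-beta * h + np.dot(state, s[1:]) / KB_CAL)
                num += h * w
                den += w
            return num / den

        h = 0.2
        grid = np.arange(298.0, 299.3, h)
        scan = heat_capacity(log_z, grid)
        for ti, ci in zip(scan.T_interior, scan.C):
            oracle = (mean_energy(ti + h / 2) - mean_energy(ti - h / 2)) / h
            assert ci == pytest.approx(oracle, rel=1e-3)

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="uniform"):
            heat_capacity(lambda t: 0.0, [1.0, 2.0, 4.0, 5.0, 6.0])
        with pytest.raises(ValueError, match=">= 5"):
            heat_capacity(lambda t: 0.0, [1.0, 2.0, 3.0])
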