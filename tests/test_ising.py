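"""Glauber dynamics: energies, flip rule, equilibrium and sweep observables."""

import numpy as np
import pytest

from connsyn import (
    ConnectivityMatrix,
    SimulationProtocol,
    SpinTimeSeries,
    critical_beta,
    delta_energy,
    derive_seed,
    desk_protocol,
    flip_probability,
    flip_rate,
    generate_heterogeneous_connectome,
    glauber_sweep,
    interpolated_critical_beta,
    paper_protocol,
    simulate_at_beta,
    susceptibility,
    temperature_sweep,
    total_energy,
)
from connsyn.ising import SweepResult, random_spins


def _pair():
    w = np.zeros((2, 2))
    w[0, 1] = w[1, 0] = 1.0
    return ConnectivityMatrix(weights=w)


class TestFlipProbability:
    @pytest.mark.parametrize("de", [-10.0, -1.0, 0.0, 2.5, 1e6])
    def test_beta_zero_is_exactly_half(self, de):
        assert flip_probability(de, 0.0) == 0.5

    def test_zero_energy_change_is_half(self):
        assert flip_probability(0.0, 3.0) == 0.5

    def test_closed_form(self):
        assert flip_probability(4.0, 1.0) == pytest.approx(1 / (1 + np.e**4))

    def test_monotone_decreasing_in_delta_e(self):
        de = np.linspace(-5, 5, 21)
        p = flip_probability(de, 0.7)
        assert np.all(np.diff(p) < 0)
        assert np.all((p >= 0) & (p <= 1))

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            flip_probability(1.0, -0.1)
        with pytest.raises(ValueError):
            flip_probability(np.inf, 1.0)


class TestEnergies:
    def test_pair_energies(self):
        c = _pair()
        assert total_energy(np.array([1, 1]), c) == -1.0
        assert total_energy(np.array([1, -1]), c) == 1.0
        assert total_energy(np.array([1, 1]), ConnectivityMatrix(np.zeros((2, 2)))) == 0

    def test_single_edge_delta(self, single_edge_3):
        # all-up state, J01 = 2: flipping node 0 costs 2 * 1 * (2 * 1) = 4
        s = np.ones(3, dtype=np.int8)
        assert delta_energy(s, single_edge_3, 0) == 4.0
        assert delta_energy(s, single_edge_3, 2) == 0.0  # isolated node
        s[1] = -1
        assert delta_energy(s, single_edge_3, 0) == -4.0

    def test_delta_consistent_with_total_energy(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(2, 7))
            w = rng.uniform(0, 3, (n, n))
            w = np.triu(w, 1) + np.triu(w, 1).T
            c = ConnectivityMatrix(weights=w)
            s = (2 * rng.integers(0, 2, n) - 1).astype(np.int8)
            i = int(rng.integers(n))
            flipped = s.copy()
            flipped[i] = -flipped[i]
            assert delta_energy(s, c, i) == pytest.approx(
                total_energy(flipped, c) - total_energy(s, c), abs=1e-12
            )

    def test_index_out_of_range(self, single_edge_3):
        with pytest.raises(IndexError):
            delta_energy(np.ones(3, dtype=np.int8), single_edge_3, 7)


class TestGlauberSweep:
    def test_deterministic_given_seed(self, single_edge_3):
        s = random_spins(3, 0)
        a = glauber_sweep(s, single_edge_3, 0.5, seed=9)
        b = glauber_sweep(s, single_edge_3, 0.5, seed=9)
        assert np.array_equal(a, b)

    def test_frozen_limit(self, complete_unit_4):
        s = np.ones(4, dtype=np.int8)
        out = glauber_sweep(s, complete_unit_4, 50.0, seed=1)
        assert np.array_equal(out, s)

    def test_beta_zero_flip_rate_half_any_network(self, complete_unit_4):
        ts = simulate_at_beta(complete_unit_4, 0.0, discard=10, collect=4000, seed=2)
        rates = flip_rate(ts)
        se = 0.5 / np.sqrt(ts.n_sweeps - 1)
        assert np.all(np.abs(rates - 0.5) < 4 * se)


class TestSimulateAtBeta:
    def test_collect_one_row(self, single_edge_3):
        ts = simulate_at_beta(single_edge_3, 0.3, discard=5, collect=1, seed=0)
        assert ts.samples.shape == (1, 3)

    def test_beta_zero_means_vanish(self, single_edge_3):
        ts = simulate_at_beta(single_edge_3, 0.0, discard=10, collect=10_000, seed=3)
        se = 1.0 / np.sqrt(ts.n_sweeps)
        assert np.all(np.abs(ts.samples.mean(axis=0)) < 4 * se)

    def test_zero_network_iid_coins(self):
        c = ConnectivityMatrix(weights=np.zeros((5, 5)))
        ts = simulate_at_beta(c, 2.0, discard=10, collect=8000, seed=4)
        rates = flip_rate(ts)
        se = 0.5 / np.sqrt(ts.n_sweeps - 1)
        assert np.all(np.abs(rates - 0.5) < 4 * se)

    def test_boltzmann_two_spin_equilibrium(self):
        # 2-spin closed form: p(s) = exp(beta * s0 * s1) / Z
        beta = 0.5
        ts = simulate_at_beta(_pair(), beta, discard=500, collect=60_000, seed=7)
        b = (ts.samples > 0).astype(int)
        code = b[:, 0] * 2 + b[:, 1]
        states = [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        w = np.exp([beta * s0 * s1 for s0, s1 in states])
        gibbs = w / w.sum()
        # batch-means standard error handles sweep-to-sweep autocorrelation
        n_batch = 100
        per_batch = code.size // n_batch
        batches = code[: n_batch * per_batch].reshape(n_batch, per_batch)
        for k in range(4):
            freqs = (batches == k).mean(axis=1)
            se = freqs.std(ddof=1) / np.sqrt(n_batch)
            assert abs(freqs.mean() - gibbs[k]) < 3 * se


class TestSusceptibility:
    def test_constant_series_zero(self):
        ts = SpinTimeSeries(beta=1.0, samples=np.ones((50, 4), dtype=np.int8))
        assert susceptibility(ts) == 0.0

    def test_beta_zero_prefactor(self):
        rng = np.random.default_rng(0)
        s = (2 * rng.integers(0, 2, (100, 4)) - 1).astype(np.int8)
        assert susceptibility(SpinTimeSeries(beta=0.0, samples=s)) == 0.0

    def test_iid_fair_spins_closed_form(self):
        # <m^2> = 1/N and <|m|> -> sqrt(2/(pi N)), so chi ~ beta (1 - 2/pi)
        rng = np.random.default_rng(1)
        n, t, beta = 64, 200_000, 1.3
        s = (2 * rng.integers(0, 2, (t, n)) - 1).astype(np.int8)
        chi = susceptibility(SpinTimeSeries(beta=beta, samples=s))
        assert chi == pytest.approx(beta * (1 - 2 / np.pi), rel=0.05)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            susceptibility(SpinTimeSeries(beta=1.0, samples=np.ones((1, 3), dtype=np.int8)))


class TestSweep:
    def test_protocol_defaults_match_full_scale(self):
        p = paper_protocol()
        assert p.relaxation_sweeps == 10**5
        assert p.discard_sweeps == 10**4
        assert p.collect_sweeps == 10**6
        assert p.n_runs == 20
        assert p.betas.size == 80

    def test_invalid_protocols(self):
        with pytest.raises(ValueError):
            SimulationProtocol(betas=np.array([]))
        with pytest.raises(ValueError):
            SimulationProtocol(betas=np.array([0.3, 0.2]))
        with pytest.raises(ValueError):
            SimulationProtocol(n_runs=0)

    def test_critical_beta_argmax_and_endpoint_warning(self):
        sw = SweepResult(
            betas=np.array([0.1, 0.2, 0.3]),
            chi=np.array([[0.1], [0.9], [0.2]]),
            abs_magnetization=np.zeros((3, 1)),
            flip_rates=np.zeros((3, 1, 2)),
            normalization="none",
            seed=0,
        )
        assert critical_beta(sw) == 0.2
        sw_mono = SweepResult(
            betas=np.array([0.1, 0.2, 0.3]),
            chi=np.array([[0.1], [0.2], [0.9]]),
            abs_magnetization=np.zeros((3, 1)),
            flip_rates=np.zeros((3, 1, 2)),
            normalization="none",
            seed=0,
        )
        with pytest.warns(RuntimeWarning, match="endpoint"):
            assert critical_beta(sw_mono) == 0.3
        with pytest.raises(ValueError):
            critical_beta(
                SweepResult(
                    betas=np.array([0.1, 0.2]),
                    chi=np.zeros((2, 1)),
                    abs_magnetization=np.zeros((2, 1)),
                    flip_rates=np.zeros((2, 1, 2)),
                    normalization="none",
                    seed=0,
                )
            )

    def test_interpolated_peak_refines_grid(self):
        # parabola with vertex at 0.24 sampled on a coarse grid
        betas = np.linspace(0.1, 0.4, 7)
        chi = -((betas - 0.24) ** 2)
        sw = SweepResult(
            betas=betas,
            chi=chi[:, None],
            abs_magnetization=np.zeros((7, 1)),
            flip_rates=np.zeros((7, 1, 2)),
            normalization="none",
            seed=0,
        )
        assert interpolated_critical_beta(sw) == pytest.approx(0.24, abs=1e-9)

    def test_single_beta_reduces_to_simulate(self, single_edge_3):
        proto = SimulationProtocol(
            relaxation_sweeps=50,
            discard_sweeps=20,
            collect_sweeps=100,
            n_runs=1,
            betas=np.array([0.4]),
            seed=5,
            normalization="none",
        )
        sw = temperature_sweep(single_edge_3, proto)
        assert sw.chi.shape == (1, 1)
        assert sw.series is not None and sw.series[0][0].n_sweeps == 100

    def test_sweep_deterministic(self):
        c = generate_heterogeneous_connectome(12, seed=0)
        proto = desk_protocol(
            betas=np.linspace(0.3, 1.5, 4),
            relaxation_sweeps=100,
            discard_sweeps=50,
            collect_sweeps=300,
            n_runs=2,
            seed=3,
        )
        a = temperature_sweep(c, proto, keep_series=False)
        b = temperature_sweep(c, proto, keep_series=False)
        assert np.array_equal(a.chi, b.chi)

    def test_freezing_order_follows_strength(self):
        # stronger nodes freeze (flip rate < 0.25) at lower beta
        from scipy import stats

        c = generate_heterogeneous_connectome(30, seed=4)
        proto = desk_protocol(
            betas=np.linspace(0.2, 2.5, 10),
            relaxation_sweeps=500,
            discard_sweeps=300,
            collect_sweeps=2000,
            n_runs=2,
            seed=6,
        )
        sw = temperature_sweep(c, proto, keep_series=False)
        fr = sw.flip_rates.mean(axis=1)
        freeze_beta = np.array(
            [
                sw.betas[np.argmax(fr[:, i] < 0.25)]
                if np.any(fr[:, i] < 0.25)
                else sw.betas[-1]
                for i in range(c.n_nodes)
            ]
        )
        rho = stats.spearmanr(freeze_beta, c.strength())[0]
        assert rho < -0.5


class TestSeriesPersistence:
    def test_round_trip(self, tmp_path, single_edge_3):
        from connsyn import load_series, save_series

        ts = simulate_at_beta(single_edge_3, 0.4, discard=10, collect=200, seed=8)
        save_series(ts, tmp_path / "run0")
        back = load_series(tmp_path / "run0")
        assert back.beta == ts.beta
        assert np.array_equal(back.samples, ts.samples)


class TestSeedDerivation:
    def test_pure_function_of_tokens(self):
        assert derive_seed(3, "a", 1) == derive_seed(3, "a", 1)
        assert derive_seed(3, "a", 1) != derive_seed(3, "a", 2)
        assert derive_seed(3, "a") != derive_seed(4, "a")
        assert 0 <= derive_seed(12345, "x") < 2**31
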