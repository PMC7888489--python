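"""Transfer entropy, PID closures, and the exact Markov-chain oracle."""

import itertools

import numpy as np
import pytest

from connsyn import (
    ConnectivityMatrix,
    LaggedJointDistribution,
    SpinTimeSeries,
    conditional_mutual_information,
    estimate_lagged_joint,
    pid_bertschinger,
    pid_from_distribution,
    pid_mmi,
    simulate_at_beta,
    transfer_entropy,
)
from connsyn.pid import te_from_table


def _series(arr):
    return SpinTimeSeries(beta=0.5, samples=np.asarray(arr, dtype=np.int8))


class TestLaggedJoint:
    def test_constant_series_all_mass_on_one_cell(self):
        ts = _series(np.ones((100, 3)))
        d = estimate_lagged_joint(ts, 0, [1])
        assert d.table[1, 1, 1] == 1.0
        assert d.table.sum() == pytest.approx(1.0)

    def test_alternating_series_two_cells(self):
        arr = np.tile([[1, 1, 1], [-1, -1, -1]], (50, 1))
        arr = np.vstack([arr, arr[:1]])  # 101 rows -> 50 + 50 transitions
        d = estimate_lagged_joint(_series(arr), 0, [1])
        # up -> down and down -> up transitions, half mass each
        assert d.table[0, 1, 1] == pytest.approx(0.5)
        assert d.table[1, 0, 0] == pytest.approx(0.5)

    def test_pooling_weights_runs_by_length(self):
        rng = np.random.default_rng(0)
        a = _series(2 * rng.integers(0, 2, (200, 3)) - 1)
        b = _series(2 * rng.integers(0, 2, (200, 3)) - 1)
        pooled = estimate_lagged_joint([a, b], 0, [1, 2])
        ca = estimate_lagged_joint(a, 0, [1, 2])
        cb = estimate_lagged_joint(b, 0, [1, 2])
        assert np.allclose(pooled.table, 0.5 * (ca.table + cb.table))

    def test_errors(self):
        ts = _series(np.ones((5, 3)))
        with pytest.raises(ValueError, match="target"):
            estimate_lagged_joint(ts, 0, [0, 1])
        with pytest.raises(ValueError, match="lag"):
            estimate_lagged_joint(_series(np.ones((1, 3))), 0, [1])

    def test_future_marginal_matches_next_step(self):
        rng = np.random.default_rng(3)
        ts = _series(2 * rng.integers(0, 2, (500, 3)) - 1)
        d = estimate_lagged_joint(ts, 0, [1, 2])
        fut = d.table.sum(axis=(1, 2, 3))
        b = (ts.samples[1:, 0] > 0).astype(int)
        assert fut[1] == pytest.approx(b.mean())


class TestSerialization:
    def test_json_round_trip(self):
        rng = np.random.default_rng(1)
        t = rng.random((2, 2, 2, 2))
        d = LaggedJointDistribution(table=t / t.sum(), sample_count=321)
        back = LaggedJointDistribution.from_json(d.to_json())
        assert np.allclose(back.table, d.table, atol=1e-15)
        assert back.sample_count == 321


class TestConditionalMI:
    def test_product_distribution_zero(self):
        t = np.full((2, 2, 2), 1 / 8)
        assert conditional_mutual_information(t, [0], [2], [1]) == pytest.approx(0.0)

    def test_perfect_copy_one_bit(self):
        # future equals the source; target's own past independent
        t = np.zeros((2, 2, 2))
        for p in (0, 1):
            for j in (0, 1):
                t[j, p, j] = 0.25
        assert conditional_mutual_information(t, [0], [2], [1]) == pytest.approx(1.0)

    def test_binary_symmetric_channel_closed_form(self):
        eps = 0.1
        t = np.zeros((2, 2, 2))
        for p in (0, 1):
            for j in (0, 1):
                t[j, p, j] += 0.25 * (1 - eps)
                t[1 - j, p, j] += 0.25 * eps
        hb = -(eps * np.log2(eps) + (1 - eps) * np.log2(1 - eps))
        assert conditional_mutual_information(t, [0], [2], [1]) == pytest.approx(
            1 - hb, abs=1e-12
        )

    def test_disjoint_axes_required(self):
        t = np.full((2, 2, 2), 1 / 8)
        with pytest.raises(ValueError):
            conditional_mutual_information(t, [0], [0], [1])


class TestTransferEntropy:
    def test_independent_coins_near_zero(self):
        rng = np.random.default_rng(5)
        ts = _series(2 * rng.integers(0, 2, (100_000, 2)) - 1)
        te = transfer_entropy(ts, 0, [1])
        bias = 7 / (2 * ts.n_sweeps * np.log(2))
        assert te < bias + 0.001

    def test_deterministic_copy_one_bit(self):
        rng = np.random.default_rng(6)
        src = 2 * rng.integers(0, 2, 50_001) - 1
        tgt = np.empty_like(src)
        tgt[0] = 1
        tgt[1:] = src[:-1]  # target copies the source with lag 1
        ts = _series(np.column_stack([tgt, src]))
        assert transfer_entropy(ts, 0, [1]) == pytest.approx(1.0, abs=0.01)

    def test_constant_second_source_adds_nothing(self):
        rng = np.random.default_rng(7)
        arr = 2 * rng.integers(0, 2, (20_000, 3)) - 1
        arr[:, 2] = 1
        ts = _series(arr)
        assert transfer_entropy(ts, 0, [1, 2]) == pytest.approx(
            transfer_entropy(ts, 0, [1]), abs=1e-12
        )

    def test_joint_dominates_single_sources_on_pooled_table(self):
        rng = np.random.default_rng(8)
        c = ConnectivityMatrix(
            weights=np.array([[0, 1, 0.5], [1, 0, 0.3], [0.5, 0.3, 0]])
        )
        ts = simulate_at_beta(c, 0.7, discard=200, collect=5000, seed=1)
        d = estimate_lagged_joint(ts, 0, [1, 2])
        t_joint = te_from_table(d)
        t_j = te_from_table(d.table.sum(axis=3))
        t_k = te_from_table(d.table.sum(axis=2))
        assert t_joint >= max(t_j, t_k) - 1e-12


def _xor_distribution():
    t = np.zeros((2, 2, 2, 2))
    for p, j, k in itertools.product((0, 1), repeat=3):
        t[j ^ k, p, j, k] = 1 / 8
    return LaggedJointDistribution(table=t, sample_count=8)


class TestMMI:
    def test_hand_worked_example(self):
        r = pid_mmi(0.9, 0.3, 0.5)
        assert (r.R, r.U_j, r.U_k, r.S) == pytest.approx((0.3, 0.0, 0.2, 0.4))

    def test_xor_is_pure_synergy(self):
        r = pid_from_distribution(_xor_distribution(), "MMI")
        assert r.S == pytest.approx(1.0, abs=1e-12)
        assert (r.R, r.U_j, r.U_k) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_duplicated_source_is_pure_redundancy(self):
        t = np.zeros((2, 2, 2, 2))
        for p, j in itertools.product((0, 1), repeat=2):
            t[j, p, j, j] = 0.25  # s_k == s_j, future copies both
        r = pid_from_distribution(
            LaggedJointDistribution(table=t, sample_count=4), "MMI"
        )
        assert r.R == pytest.approx(r.T_j)
        assert (r.U_j, r.U_k, r.S) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            pid_mmi(0.1, 0.5, 0.3)

    def test_closure_identities_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            t = rng.random((2, 2, 2, 2))
            d = LaggedJointDistribution(table=t / t.sum(), sample_count=100)
            r = pid_from_distribution(d, "MMI")
            assert abs(r.T_joint - (r.U_j + r.U_k + r.R + r.S)) < 1e-10
            assert abs(r.T_j - (r.U_j + r.R)) < 1e-10
            assert abs(r.T_k - (r.U_k + r.R)) < 1e-10
            assert min(r.R, r.U_j, r.U_k, r.S) >= -1e-10

    def test_source_exchange_swaps_uniques(self):
        rng = np.random.default_rng(10)
        t = rng.random((2, 2, 2, 2))
        t /= t.sum()
        d = LaggedJointDistribution(table=t, sample_count=100)
        d_swap = LaggedJointDistribution(
            table=np.swapaxes(t, 2, 3).copy(), sample_count=100
        )
        a = pid_from_distribution(d, "MMI")
        b = pid_from_distribution(d_swap, "MMI")
        assert (a.U_j, a.U_k) == pytest.approx((b.U_k, b.U_j))
        assert (a.R, a.S) == pytest.approx((b.R, b.S))


class TestBertschinger:
    def test_product_distribution_zero_synergy(self):
        t = np.full((2, 2, 2, 2), 1 / 16)
        r = pid_bertschinger(LaggedJointDistribution(table=t, sample_count=16))
        assert r.S == pytest.approx(0.0, abs=1e-8)

    def test_xor_synergy_is_one_bit(self):
        r = pid_bertschinger(_xor_distribution())
        assert r.S == pytest.approx(1.0, abs=1e-6)

    def test_source_exchange_invariance(self):
        rng = np.random.default_rng(11)
        t = rng.random((2, 2, 2, 2))
        t /= t.sum()
        a = pid_bertschinger(LaggedJointDistribution(table=t, sample_count=100))
        b = pid_bertschinger(
            LaggedJointDistribution(table=np.swapaxes(t, 2, 3).copy(), sample_count=100)
        )
        assert a.S == pytest.approx(b.S, abs=1e-6)
        assert a.R == pytest.approx(b.R, abs=1e-6)

    def test_synergy_never_exceeds_joint_te(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            t = rng.random((2, 2, 2, 2))
            t /= t.sum()
            r = pid_bertschinger(LaggedJointDistribution(table=t, sample_count=100))
            assert -1e-9 <= r.S <= r.T_joint + 1e-9


# ---------------------------------------------------------------------------
# Exact oracle: 3-spin Glauber chain solved by enumeration

def _single_site_kernel(w, beta, i):
    """8x8 transition matrix of a single Glauber update of spin i."""
    k = np.zeros((8, 8))
    for code in range(8):
        s = np.array([1 if code & (1 << (2 - a)) else -1 for a in range(3)])
        de = 2.0 * s[i] * (w[i] @ s)
        p = 1.0 / (1.0 + np.exp(beta * de))
        flipped = code ^ (1 << (2 - i))
        k[code, flipped] = p
        k[code, code] = 1.0 - p
    return k


def exact_sweep_te(w, beta, target, source):
    """Analytic pairwise transfer entropy of the per-sweep 3-spin chain.

    The per-sweep kernel is the average over the 6 update orders of the
    composition of single-site Glauber kernels; the lagged joint follows
    from its stationary distribution.
    """
    kernels = [_single_site_kernel(w, beta, i) for i in range(3)]
    P = np.zeros((8, 8))
    for order in itertools.permutations(range(3)):
        m = np.eye(8)
        for i in order:
            m = m @ kernels[i]
        P += m / 6.0
    evals, evecs = np.linalg.eig(P.T)
    stat = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    stat = stat / stat.sum()
    joint_full = stat[:, None] * P  # (state_t, state_t+1)
    table = np.zeros((2, 2, 2))
    for c0 in range(8):
        bits0 = [(c0 >> (2 - a)) & 1 for a in range(3)]
        for c1 in range(8):
            f = (c1 >> (2 - target)) & 1
            table[f, bits0[target], bits0[source]] += joint_full[c0, c1]
    return conditional_mutual_information(table, [0], [2], [1])


class TestMarkovChainOracle:
    def test_plugin_te_matches_exact_chain(self):
        w = np.array([[0, 1.0, 0.5], [1.0, 0, 0.25], [0.5, 0.25, 0]])
        c = ConnectivityMatrix(weights=w)
        beta = 0.6
        exact = exact_sweep_te(w, beta, target=0, source=1)
        estimates = [
            transfer_entropy(
                simulate_at_beta(c, beta, discard=500, collect=100_000, seed=s),
                0,
                [1],
            )
            for s in range(20)
        ]
        mean = np.mean(estimates)
        sem = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - exact) < 3 * sem + 1e-4

    def test_exact_te_positive_for_coupled_spins(self):
        w = np.array([[0, 1.0, 0.5], [1.0, 0, 0.25], [0.5, 0.25, 0]])
        assert exact_sweep_te(w, 0.6, 0, 1) > 0.001
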