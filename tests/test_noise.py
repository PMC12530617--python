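"""Forward-corruption algebra: transition matrices, cumulative products,
sampling statistics and the closed-form posterior, all checked against
brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from moldiff import (
    corrupt_graph,
    cumulative_matrix,
    make_schedule,
    posterior,
    transition_matrix,
)
from moldiff.noise import (
    corrupt_indices,
    corrupt_step_indices,
    posterior_tensor,
    schedule_from_steps,
)
from conftest import random_schedule


def explicit_product(schedule, channel, t):
    K = schedule.K[channel]
    P = np.eye(K + 1)
    for s in range(1, t + 1):
        P = transition_matrix(s, channel, schedule) @ P
    return P


class TestSchedule:
    def test_single_step_full_mask(self):
        sched = make_schedule(T=1, Ks={"A": 3}, mask_fraction_final=1.0, uniform_weight=0.0)
        assert sched.gamma["A"][1] == pytest.approx(1.0)
        assert sched.alpha["A"][1] == pytest.approx(0.0)
        assert sched.beta["A"][1] == pytest.approx(0.0)

    def test_default_reaches_full_mask(self):
        sched = make_schedule(T=10, Ks={"A": 4})
        survival = np.prod(1.0 - sched.gamma["A"][1:])
        assert 1.0 - survival == pytest.approx(1.0, abs=1e-9)
        assert sched.gbar["A"][10] == pytest.approx(1.0, abs=1e-9)

    def test_per_step_masses_are_feasible(self):
        for T in (1, 5, 50, 500):
            sched = make_schedule(T=T, Ks={"A": 3, "E": 5})
            for ch, K in (("A", 3), ("E", 5)):
                total = sched.alpha[ch] + K * sched.beta[ch] + sched.gamma[ch]
                assert np.abs(total[1:] - 1.0).max() < 1e-12
                assert (sched.alpha[ch] >= 0).all()
                assert (sched.beta[ch] >= 0).all()
                assert (sched.gamma[ch] >= 0).all()

    def test_partial_mask_fraction(self):
        sched = make_schedule(T=8, Ks={"A": 3}, mask_fraction_final=0.5)
        assert sched.gbar["A"][8] == pytest.approx(0.5, abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(T=0, Ks={"A": 3})
        with pytest.raises(ValueError):
            make_schedule(T=5, Ks={"A": 3}, mask_fraction_final=1.5)
        with pytest.raises(ValueError):
            make_schedule(T=5, Ks={"A": 3}, kind="quadratic")

    def test_config_round_trip(self, schedule):
        from moldiff.noise import NoiseSchedule

        clone = NoiseSchedule.from_config(schedule.to_config())
        np.testing.assert_allclose(clone.gbar["A"], schedule.gbar["A"])


class TestTransitionMatrices:
    def test_identity_and_absorbing_limits(self):
        eye = schedule_from_steps({"A": 3}, np.array([1.0, 1.0]), np.zeros(2), np.zeros(2))
        np.testing.assert_allclose(transition_matrix(1, "A", eye), np.eye(4))
        absorbing = schedule_from_steps(
            {"A": 3}, np.zeros(2), np.zeros(2), np.array([0.0, 1.0])
        )
        Q = transition_matrix(1, "A", absorbing)
        assert (Q[3, :3] == 1.0).all()

    def test_hand_computed_column(self):
        # K=2, alpha=0.8, beta=0.05, gamma=0.1 -> column [0.85, 0.05, 0.1]
        sched = schedule_from_steps(
            {"A": 2}, np.array([0.0, 0.8]), np.array([0.0, 0.1]), np.array([0.0, 0.1])
        )
        Q = transition_matrix(1, "A", sched)
        np.testing.assert_allclose(Q[:, 0], [0.85, 0.05, 0.1])
        np.testing.assert_allclose(Q.sum(axis=0), 1.0)

    def test_columns_stochastic_and_mask_absorbing(self, rng):
        for _ in range(10):
            K = int(rng.integers(2, 7))
            T = int(rng.integers(1, 9))
            sched = random_schedule(rng, K, T)
            for t in range(1, T + 1):
                Q = transition_matrix(t, "A", sched)
                assert np.abs(Q.sum(axis=0) - 1.0).max() <= 1e-12
                np.testing.assert_array_equal(Q[:, K], np.eye(K + 1)[K])

    def test_cumulative_matches_explicit_product(self, rng):
        for _ in range(10):
            K = int(rng.integers(2, 7))
            T = int(rng.integers(1, 9))
            sched = random_schedule(rng, K, T)
            for t in range(T + 1):
                np.testing.assert_allclose(
                    cumulative_matrix(t, "A", sched),
                    explicit_product(sched, "A", t),
                    atol=1e-10,
                )

    def test_out_of_range_t(self, schedule):
        with pytest.raises(ValueError):
            transition_matrix(0, "A", schedule)
        with pytest.raises(ValueError):
            cumulative_matrix(schedule.T + 1, "A", schedule)


class TestCorruption:
    def test_t0_returns_clean_graph(self, ethanol, schedule, rng):
        g = corrupt_graph(ethanol, 0, schedule, rng)
        np.testing.assert_array_equal(g.A, ethanol.A)

    def test_terminal_step_masks_everything(self, vocab, ethanol, schedule, rng):
        g = corrupt_graph(ethanol, schedule.T, schedule, rng)
        assert (g.atom_indices == vocab.d_A - 1).all()
        assert (g.charge_indices == vocab.d_C - 1).all()
        low = g.bond_indices[np.tril_indices(5, -1)]
        assert (low == vocab.d_E - 1).all()
        assert (g.bond_indices.diagonal() == 0).all()  # diagonal untouched

    def test_corrupted_graph_stays_symmetric(self, ethanol, schedule, rng):
        g = corrupt_graph(ethanol, schedule.T // 2, schedule, rng)
        np.testing.assert_array_equal(g.E, g.E.swapaxes(0, 1))

    def test_empirical_frequencies_match_cumulative_column(self, schedule, rng):
        t = schedule.T // 2
        N = 100_000
        draws = corrupt_indices(np.zeros(N, dtype=int), t, "A", schedule, rng)
        col = cumulative_matrix(t, "A", schedule)[:, 0]
        freq = np.bincount(draws, minlength=len(col)) / N
        se = np.sqrt(col * (1 - col) / N)
        assert (np.abs(freq - col) <= 4 * se + 1e-12).all()

    def test_mask_is_absorbing_stepwise(self, schedule, rng):
        # follow one entry through every step; once masked it stays masked
        K = schedule.K["A"]
        for _ in range(200):
            x = 0
            masked_at = None
            for t in range(1, schedule.T + 1):
                x = int(corrupt_step_indices(np.array([x]), t, "A", schedule, rng)[0])
                if x == K:
                    masked_at = t
                    break
            if masked_at is not None:
                for t in range(masked_at + 1, schedule.T + 1):
                    x = int(corrupt_step_indices(np.array([x]), t, "A", schedule, rng)[0])
                    assert x == K

    def test_stepwise_and_jump_marginals_agree(self, schedule, rng):
        t = schedule.T // 2
        N = 100_000
        jump = corrupt_indices(np.zeros(N, dtype=int), t, "A", schedule, rng)
        step = np.zeros(N, dtype=int)
        for s in range(1, t + 1):
            step = corrupt_step_indices(step, s, "A", schedule, rng)
        K = schedule.K["A"]
        expected = cumulative_matrix(t, "A", schedule)[:, 0] * N
        observed = np.bincount(step, minlength=K + 1)
        keep = expected > 5
        _, p = stats.chisquare(observed[keep], expected[keep] * observed[keep].sum() / expected[keep].sum())
        assert p > 0.01


class TestScheduleProperties:
    """Hypothesis sweeps over the schedule parameter space."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        T=st.integers(1, 64),
        mff=st.floats(0.05, 1.0),
        uw=st.floats(0.0, 0.5),
        K=st.integers(2, 8),
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_feasibility_and_terminal_mass(self, T, mff, uw, K):
        sched = make_schedule(T=T, Ks={"A": K}, mask_fraction_final=mff, uniform_weight=uw)
        total = sched.alpha["A"] + K * sched.beta["A"] + sched.gamma["A"]
        assert np.abs(total[1:] - 1.0).max() < 1e-9
        for arr in (sched.alpha["A"], sched.beta["A"], sched.gamma["A"]):
            assert (arr >= -1e-15).all()
        assert sched.gbar["A"][T] == pytest.approx(mff, abs=1e-9)

    @given(T=st.integers(1, 10), K=st.integers(2, 6), t_seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_posterior_rows_normalize_or_flag(self, T, K, t_seed):
        rng = np.random.default_rng(t_seed)
        sched = random_schedule(rng, K, T)
        t = int(rng.integers(1, T + 1))
        x0 = int(rng.integers(0, K))
        x_t = int(rng.integers(0, K + 1))
        res = posterior(x_t, x0, t, "A", sched)
        if res.reachable:
            assert res.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert (res.probs >= 0).all()
        else:
            assert (res.probs == 0).all()


def brute_force_posterior(x_t, x0, t, channel, sched):
    K = sched.K[channel]
    Qt = transition_matrix(t, channel, sched)
    Qprev = cumulative_matrix(t - 1, channel, sched)
    probs = np.array([Qt[x_t, j] * Qprev[j, x0] for j in range(K + 1)])
    Z = probs.sum()
    return (probs / Z, True) if Z > 0 else (probs, False)


class TestPosterior:
    def test_t1_is_point_mass_on_x0(self, rng):
        sched = random_schedule(rng, 3, 5)
        for x0 in range(3):
            for x_t in range(4):
                res = posterior(x_t, x0, 1, "A", sched)
                if res.reachable:
                    expected = np.zeros(4)
                    expected[x0] = 1.0
                    np.testing.assert_allclose(res.probs, expected, atol=1e-12)

    def test_matches_enumeration_oracle_everywhere(self, rng):
        sched = random_schedule(rng, 3, 5)
        for t in range(1, 6):
            for x0 in range(3):
                for x_t in range(4):
                    res = posterior(x_t, x0, t, "A", sched)
                    oracle, reachable = brute_force_posterior(x_t, x0, t, "A", sched)
                    assert res.reachable == reachable
                    np.testing.assert_allclose(res.probs, oracle, atol=1e-10)
                    if reachable:
                        assert res.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unreachable_returns_flagged_zeros(self):
        # no uniform noise: an ordinary x_t different from x0 is unreachable
        sched = schedule_from_steps(
            {"A": 3}, np.array([0.0, 0.7, 0.7]), np.zeros(3), np.array([0.0, 0.3, 0.3])
        )
        res = posterior(1, 0, 2, "A", sched)
        assert not res.reachable
        assert (res.probs == 0).all()

    def test_masked_x0_rejected(self, schedule):
        with pytest.raises(ValueError):
            posterior(0, schedule.K["A"], 3, "A", schedule)

    def test_posterior_tensor_agrees_with_scalar_api(self, rng):
        sched = random_schedule(rng, 4, 6)
        for t in (1, 3, 6):
            R = posterior_tensor(t, "A", sched)
            for x_t in range(5):
                for x0 in range(4):
                    res = posterior(x_t, x0, t, "A", sched)
                    np.testing.assert_allclose(R[x_t, :, x0], res.probs, atol=1e-12)
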