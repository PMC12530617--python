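"""Loss terms against brute-force oracles: KL of the reverse mixture versus
the true posterior, cross-entropy identities, weighted combination."""

import numpy as np
import pytest

from moldiff import (
    ChannelTerms,
    LossWeights,
    ce_terms,
    corrupt_graph,
    permute_graph,
    prior_terms,
    total_loss,
    vlb_terms,
)
from moldiff.denoiser import DenoiserOutput
from moldiff.noise import posterior_tensor, tril_indices


def point_mass_output(g, vocab):
    return DenoiserOutput(
        atom_probs=g.A[:, : vocab.K_A].copy(),
        charge_probs=g.C[:, : vocab.K_C].copy(),
        edge_probs=g.E[:, :, : vocab.K_E].copy(),
    )


def random_output(vocab, n, rng):
    def norm(x):
        return x / x.sum(axis=-1, keepdims=True)

    e = rng.random((n, n, vocab.K_E))
    e = (e + e.swapaxes(0, 1)) / 2
    return DenoiserOutput(
        atom_probs=norm(rng.random((n, vocab.K_A))),
        charge_probs=norm(rng.random((n, vocab.K_C))),
        edge_probs=norm(e),
    )


def kl_enumeration_oracle(g0, g_t, t, out, schedule, vocab):
    """Independent loop-based recomputation of the three VLB terms."""
    R = {ch: posterior_tensor(t, ch, schedule) for ch in ("A", "C", "E")}

    def entry_kl(ch, x0, xt, p0):
        q = R[ch][xt, :, x0]
        rev = R[ch][xt] @ p0
        rev = rev / rev.sum()
        total = 0.0
        for j in range(len(q)):
            if q[j] > 0:
                total += q[j] * (np.log(q[j]) - np.log(max(rev[j], 1e-30)))
        return total

    la = sum(
        entry_kl("A", g0.atom_indices[i], g_t.atom_indices[i], out.atom_probs[i])
        for i in range(g0.n)
    )
    lc = sum(
        entry_kl("C", g0.charge_indices[i], g_t.charge_indices[i], out.charge_probs[i])
        for i in range(g0.n)
    )
    rows, cols = tril_indices(g0.n)
    le = sum(
        entry_kl(
            "E", g0.bond_indices[i, j], g_t.bond_indices[i, j], out.edge_probs[i, j]
        )
        for i, j in zip(rows, cols)
    )
    return la, lc, le


class TestVLB:
    def test_point_mass_prediction_gives_zero_kl(self, vocab, ethanol, schedule, rng):
        out = point_mass_output(ethanol, vocab)
        for t in range(2, schedule.T + 1):
            g_t = corrupt_graph(ethanol, t, schedule, rng)
            terms = vlb_terms(ethanol, g_t, t, out, schedule)
            for term in terms:
                assert abs(term) <= 1e-8

    def test_reconstruction_term_at_t1(self, vocab, ethanol, schedule, rng):
        g1 = corrupt_graph(ethanol, 1, schedule, rng)
        out = point_mass_output(ethanol, vocab)
        terms = vlb_terms(ethanol, g1, 1, out, schedule)
        for term in terms:
            assert abs(term) <= 1e-8  # -log 1 = 0 under a perfect prediction

    def test_matches_enumeration_oracle(self, vocab, ethanol, rng):
        # random valid schedule over the vocab's own channel sizes
        from moldiff.noise import schedule_from_steps

        gamma = np.concatenate([[0.0], rng.uniform(0.1, 0.5, size=4)])
        uniform = np.concatenate([[0.0], rng.uniform(0.0, 0.2, size=4)]) * (1 - gamma)
        alpha = 1.0 - gamma - uniform
        sched = schedule_from_steps(
            {"A": vocab.K_A, "C": vocab.K_C, "E": vocab.K_E}, alpha, uniform, gamma
        )
        for t in (1, 2, 4):
            g_t = corrupt_graph(ethanol, t, sched, rng)
            out = random_output(vocab, ethanol.n, rng)
            got = vlb_terms(ethanol, g_t, t, out, sched)
            expected = kl_enumeration_oracle(ethanol, g_t, t, out, sched, vocab)
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_kl_terms_nonnegative(self, vocab, ethanol, schedule, rng):
        for t in (2, 5, 10):
            g_t = corrupt_graph(ethanol, t, schedule, rng)
            out = random_output(vocab, ethanol.n, rng)
            for term in vlb_terms(ethanol, g_t, t, out, schedule):
                assert term >= -1e-12

    def test_t0_rejected(self, vocab, ethanol, schedule, rng):
        out = point_mass_output(ethanol, vocab)
        with pytest.raises(ValueError):
            vlb_terms(ethanol, ethanol, 0, out, schedule)

    def test_prior_term_zero_under_full_masking(self, ethanol, schedule):
        for term in prior_terms(ethanol, schedule):
            assert abs(term) <= 1e-9


class TestCE:
    def test_perfect_prediction_gives_zero(self, vocab, ethanol):
        terms = ce_terms(ethanol, point_mass_output(ethanol, vocab))
        np.testing.assert_allclose(terms, 0.0, atol=1e-12)

    def test_uniform_prediction_gives_log_k(self, vocab, ethanol):
        n = ethanol.n
        out = DenoiserOutput(
            atom_probs=np.full((n, vocab.K_A), 1 / vocab.K_A),
            charge_probs=np.full((n, vocab.K_C), 1 / vocab.K_C),
            edge_probs=np.full((n, n, vocab.K_E), 1 / vocab.K_E),
        )
        terms = ce_terms(ethanol, out)
        assert terms.atom == pytest.approx(np.log(vocab.K_A), abs=1e-12)
        assert terms.charge == pytest.approx(np.log(vocab.K_C), abs=1e-12)
        assert terms.edge == pytest.approx(np.log(vocab.K_E), abs=1e-12)

    def test_matches_direct_summation(self, vocab, ethanol, rng):
        out = random_output(vocab, ethanol.n, rng)
        terms = ce_terms(ethanol, out)
        a0 = ethanol.atom_indices
        expected_a = -np.mean(
            [np.log(out.atom_probs[i, a0[i]]) for i in range(ethanol.n)]
        )
        rows, cols = tril_indices(ethanol.n)
        expected_e = -np.mean(
            [np.log(out.edge_probs[i, j, ethanol.bond_indices[i, j]]) for i, j in zip(rows, cols)]
        )
        assert terms.atom == pytest.approx(expected_a, abs=1e-12)
        assert terms.edge == pytest.approx(expected_e, abs=1e-12)


class TestTotalLoss:
    def test_single_weight_selects_single_term(self):
        w = LossWeights(1, 0, 0, 0, 0, 0)
        vlb = ChannelTerms(3.5, 1.0, 2.0)
        ce = ChannelTerms(0.1, 0.2, 0.3)
        assert total_loss(vlb, ce, w) == pytest.approx(3.5)

    def test_weighted_sum_arithmetic(self):
        w = LossWeights(1, 1, 5, 0.5, 0.5, 2.5)
        ones = ChannelTerms(1.0, 1.0, 1.0)
        assert total_loss(ones, ones, w) == pytest.approx(10.5)
        zeros = ChannelTerms(0.0, 0.0, 0.0)
        assert total_loss(zeros, zeros, w) == 0.0

    def test_nonfinite_term_names_channel(self):
        w = LossWeights()
        bad = ChannelTerms(1.0, np.inf, 1.0)
        with pytest.raises(ValueError, match="VLB_C"):
            total_loss(bad, ChannelTerms(0, 0, 0), w)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-1, 1, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0, 0, 0, 0)


class TestPermutationInvariance:
    def test_all_terms_invariant_under_joint_permutation(self, vocab, ethanol, schedule, rng):
        t = 4
        g_t = corrupt_graph(ethanol, t, schedule, rng)
        out = random_output(vocab, ethanol.n, rng)
        base_vlb = vlb_terms(ethanol, g_t, t, out, schedule)
        base_ce = ce_terms(ethanol, out)
        perm = rng.permutation(ethanol.n)
        out_p = DenoiserOutput(
            atom_probs=out.atom_probs[perm],
            charge_probs=out.charge_probs[perm],
            edge_probs=out.edge_probs[np.ix_(perm, perm)],
        )
        perm_vlb = vlb_terms(
            permute_graph(ethanol, perm), permute_graph(g_t, perm), t, out_p, schedule
        )
        perm_ce = ce_terms(permute_graph(ethanol, perm), out_p)
        np.testing.assert_allclose(perm_vlb, base_vlb, atol=1e-8)
        np.testing.assert_allclose(perm_ce, base_ce, atol=1e-8)
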