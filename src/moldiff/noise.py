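"""Mask-and-replace forward corruption process.

Each categorical entry (atom type, formal charge, bond type) evolves under a
Markov chain whose one-step transition matrix keeps the current category
with probability ``alpha_t``, replaces it uniformly by any of the K ordinary
categories with probability ``beta_t`` each, and sends it to the absorbing
``<MASK>`` state with probability ``gamma_t``:

    Q_t[:, j] = alpha_t e_j + beta_t 1_K + gamma_t e_mask   (j ordinary)
    Q_t[:, mask] = e_mask

Matrices are column-stochastic: ``Q_t[i, j] = q(x_t = i | x_{t-1} = j)``.
The product structure is closed under composition, so cumulative matrices
``Qbar_t = Q_t ... Q_1`` are tracked by three scalars per step
(keep, uniform, mask mass) instead of explicit matrix products.

The default schedule drives the cumulative mask mass linearly to 1 at t = T,
with a small uniform-replacement admixture so the reverse model can also
repair wrongly placed (unmasked) categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .mol_graph import MoleculeGraph, Vocabulary, _one_hot

CHANNELS = ("A", "C", "E")


class PosteriorResult(NamedTuple):
    probs: np.ndarray  # length K+1, distribution over x_{t-1}
    reachable: bool  # False iff q(x_t | x_0) = 0: probs are all-zero


@dataclass
class NoiseSchedule:
    """Per-step (alpha, beta, gamma) and cumulative (keep, uniform, mask)
    masses for t = 0..T, per channel.

    Arrays are indexed by t directly; index 0 holds the trivial step
    (alpha=1) / identity cumulative state.  ``beta`` is per ordinary
    category, so feasibility reads ``alpha + K*beta + gamma = 1``.
    """

    T: int
    K: dict  # channel -> number of ordinary categories
    alpha: dict = field(repr=False)  # channel -> (T+1,)
    beta: dict = field(repr=False)
    gamma: dict = field(repr=False)
    abar: dict = field(repr=False)  # cumulative keep mass
    bbar: dict = field(repr=False)  # cumulative uniform mass (per category)
    gbar: dict = field(repr=False)  # cumulative mask mass
    kind: str = "linear-mask"
    mask_fraction_final: float = 1.0
    uniform_weight: float = 0.05

    def to_config(self) -> dict:
        return {
            "T": self.T,
            "kind": self.kind,
            "mask_fraction_final": self.mask_fraction_final,
            "uniform_weight": self.uniform_weight,
            "K": dict(self.K),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "NoiseSchedule":
        return make_schedule(
            T=cfg["T"],
            Ks=cfg["K"],
            kind=cfg.get("kind", "linear-mask"),
            mask_fraction_final=cfg.get("mask_fraction_final", 1.0),
            uniform_weight=cfg.get("uniform_weight", 0.05),
        )


def make_schedule(
    T: int,
    Ks: dict,
    kind: str = "linear-mask",
    mask_fraction_final: float = 1.0,
    uniform_weight: float = 0.05,
) -> NoiseSchedule:
    """Build the noise schedule shared by all three channels.

    ``linear-mask``: the cumulative mask mass grows as
    ``m_t = mask_fraction_final * t / T``; per-step
    ``gamma_t = (m_t - m_{t-1}) / (1 - m_{t-1})``.  The uniform-replacement
    mass per step is ``K * beta_t = min(uniform_weight * gamma_t,
    1 - gamma_t)`` — a small fraction of the corrupted mass, vanishing at
    the fully-masking terminal step.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 < mask_fraction_final <= 1.0):
        raise ValueError("mask_fraction_final must be in (0, 1]")
    if uniform_weight < 0:
        raise ValueError("uniform_weight must be >= 0")
    if kind != "linear-mask":
        raise ValueError(f"unknown schedule kind {kind!r}")

    t = np.arange(T + 1, dtype=np.float64)
    m = mask_fraction_final * t / T
    gamma_steps = np.zeros(T + 1)
    gamma_steps[1:] = (m[1:] - m[:-1]) / (1.0 - m[:-1])
    total_uniform = np.minimum(uniform_weight * gamma_steps, 1.0 - gamma_steps)
    alpha_steps = 1.0 - gamma_steps - total_uniform
    if (alpha_steps < -1e-12).any():
        raise ValueError("infeasible schedule: corrupted mass exceeds 1")
    alpha_steps = np.clip(alpha_steps, 0.0, 1.0)
    alpha_steps[0], gamma_steps[0] = 1.0, 0.0
    total_uniform[0] = 0.0

    sched = schedule_from_steps(Ks, alpha_steps, total_uniform, gamma_steps)
    sched.kind = kind
    sched.mask_fraction_final = mask_fraction_final
    sched.uniform_weight = uniform_weight
    return sched


def schedule_from_steps(
    Ks: dict,
    alpha_steps: np.ndarray,
    total_uniform_steps: np.ndarray,
    gamma_steps: np.ndarray,
) -> NoiseSchedule:
    """Assemble a schedule from explicit per-step masses (index 0 unused;
    ``total_uniform_steps`` is K*beta).  Cumulative masses follow the
    closed-form composition of the keep/uniform/mask matrix family."""
    T = len(alpha_steps) - 1
    checks = alpha_steps[1:] + total_uniform_steps[1:] + gamma_steps[1:]
    if np.abs(checks - 1.0).max() > 1e-9:
        raise ValueError("per-step masses must satisfy alpha + K*beta + gamma = 1")
    alpha, beta, gamma, abar, bbar, gbar = {}, {}, {}, {}, {}, {}
    for ch, K in Ks.items():
        a = alpha_steps.copy()
        b = total_uniform_steps / K
        g = gamma_steps.copy()
        ab = np.empty(T + 1)
        bb = np.empty(T + 1)
        gb = np.empty(T + 1)
        ab[0], bb[0], gb[0] = 1.0, 0.0, 0.0
        for s in range(1, T + 1):
            # composition Qbar_s = Q_s @ Qbar_{s-1} in (keep, uniform, mask) form
            ab[s] = a[s] * ab[s - 1]
            bb[s] = a[s] * bb[s - 1] + b[s] * ab[s - 1] + K * b[s] * bb[s - 1]
            gb[s] = gb[s - 1] + (ab[s - 1] + K * bb[s - 1]) * g[s]
        alpha[ch], beta[ch], gamma[ch] = a, b, g
        abar[ch], bbar[ch], gbar[ch] = ab, bb, gb

    return NoiseSchedule(
        T=T,
        K=dict(Ks),
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        abar=abar,
        bbar=bbar,
        gbar=gbar,
    )


def schedule_for_vocab(vocab: Vocabulary, T: int, **kwargs) -> NoiseSchedule:
    return make_schedule(T=T, Ks=vocab.Ks(), **kwargs)


def _family_matrix(K: int, keep: float, uniform: float, mask: float) -> np.ndarray:
    """(K+1)x(K+1) column-stochastic matrix of the keep/uniform/mask family."""
    Q = np.zeros((K + 1, K + 1))
    Q[:K, :K] = uniform
    Q[np.arange(K), np.arange(K)] += keep
    Q[K, :K] = mask
    Q[K, K] = 1.0
    return Q


def transition_matrix(t: int, channel: str, schedule: NoiseSchedule) -> np.ndarray:
    """One-step matrix Q_t; mask column is exactly absorbing."""
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t={t} outside [1, {schedule.T}]")
    K = schedule.K[channel]
    return _family_matrix(
        K, schedule.alpha[channel][t], schedule.beta[channel][t], schedule.gamma[channel][t]
    )


def cumulative_matrix(t: int, channel: str, schedule: NoiseSchedule) -> np.ndarray:
    """Qbar_t = Q_t ... Q_1 via the closed-form mass recursion (identity at 0)."""
    if not 0 <= t <= schedule.T:
        raise ValueError(f"t={t} outside [0, {schedule.T}]")
    K = schedule.K[channel]
    return _family_matrix(
        K, schedule.abar[channel][t], schedule.bbar[channel][t], schedule.gbar[channel][t]
    )


def _sample_categories(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one category per row of a (N, K) probability matrix."""
    cdf = prob_rows.cumsum(axis=-1)
    cdf[..., -1] = 1.0
    u = rng.random(prob_rows.shape[:-1] + (1,))
    return (cdf < u).sum(axis=-1)


def corrupt_indices(
    idx: np.ndarray, t: int, channel: str, schedule: NoiseSchedule, rng: np.random.Generator
) -> np.ndarray:
    """Jump-sample x_t ~ Qbar_t column of each clean index (vectorized)."""
    K = schedule.K[channel]
    ab = schedule.abar[channel][t]
    bb = schedule.bbar[channel][t]
    gb = schedule.gbar[channel][t]
    probs = np.full(idx.shape + (K + 1,), bb)
    probs[..., K] = gb
    np.put_along_axis(probs, idx[..., None], ab + bb, axis=-1)
    return _sample_categories(probs, rng)


def corrupt_step_indices(
    idx: np.ndarray, t: int, channel: str, schedule: NoiseSchedule, rng: np.random.Generator
) -> np.ndarray:
    """One forward step x_t ~ Q_t column of x_{t-1}; mask stays mask."""
    K = schedule.K[channel]
    a, b, g = (
        schedule.alpha[channel][t],
        schedule.beta[channel][t],
        schedule.gamma[channel][t],
    )
    probs = np.full(idx.shape + (K + 1,), b)
    probs[..., K] = g
    np.put_along_axis(probs, idx[..., None], a + b, axis=-1)
    masked = idx == K
    out = _sample_categories(probs, rng)
    out[masked] = K
    return out


def tril_indices(n: int):
    """Strictly-lower-triangular index pair arrays (the free edge slots)."""
    return np.tril_indices(n, k=-1)


def corrupt_graph(
    g0: MoleculeGraph, t: int, schedule: NoiseSchedule, rng: np.random.Generator
) -> MoleculeGraph:
    """Sample the noisy graph G_t given the clean graph G_0.

    Atom and charge rows are corrupted independently; edges are corrupted on
    the strictly lower triangle and mirrored (the graph is undirected), with
    the diagonal pinned at no-bond.
    """
    if t == 0:
        return g0.copy()
    n = g0.n
    a_t = corrupt_indices(g0.atom_indices, t, "A", schedule, rng)
    c_t = corrupt_indices(g0.charge_indices, t, "C", schedule, rng)
    rows, cols = tril_indices(n)
    e0 = g0.bond_indices
    e_t = e0.copy()
    low = corrupt_indices(e0[rows, cols], t, "E", schedule, rng)
    e_t[rows, cols] = low
    e_t[cols, rows] = low

    return MoleculeGraph(
        A=_one_hot(a_t, schedule.K["A"] + 1),
        C=_one_hot(c_t, schedule.K["C"] + 1),
        E=_one_hot(e_t, schedule.K["E"] + 1),
        n_real=g0.n_real,
    )


def posterior(
    x_t: int, x0: int, t: int, channel: str, schedule: NoiseSchedule
) -> PosteriorResult:
    """Closed-form posterior q(x_{t-1} | x_t, x_0) as a length-(K+1) vector.

    Proportional to ``Q_t[x_t, :] * Qbar_{t-1}[:, x0]`` with normalizer
    ``Qbar_t[x_t, x0]``.  If x_t is unreachable from x0 the normalizer is 0
    and an all-zero vector is returned with ``reachable=False``.
    """
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t={t} outside [1, {schedule.T}]")
    K = schedule.K[channel]
    if x0 >= K:
        raise ValueError("x0 must be an ordinary (non-mask) category")
    Qt = transition_matrix(t, channel, schedule)
    Qbar_prev = cumulative_matrix(t - 1, channel, schedule)
    norm = cumulative_matrix(t, channel, schedule)[x_t, x0]
    if norm <= 0.0:
        return PosteriorResult(np.zeros(K + 1), False)
    probs = Qt[x_t, :] * Qbar_prev[:, x0] / norm
    return PosteriorResult(probs, True)


def posterior_tensor(t: int, channel: str, schedule: NoiseSchedule) -> np.ndarray:
    """R[i, j, k] = q(x_{t-1}=j | x_t=i, x0=k) for ordinary k, all i, j.

    Unreachable (i, k) pairs give all-zero columns.  Used to vectorize both
    the reverse-step mixture and the KL loss.
    """
    K = schedule.K[channel]
    Qt = transition_matrix(t, channel, schedule)
    Qbar_prev = cumulative_matrix(t - 1, channel, schedule)
    Qbar = cumulative_matrix(t, channel, schedule)
    num = Qt[:, :, None] * Qbar_prev[None, :, :K]  # (i, j, k)
    denom = Qbar[:, :K]  # (i, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(denom[:, None, :] > 0.0, num / denom[:, None, :], 0.0)
    return R
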