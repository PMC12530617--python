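"""Training objective: per-channel variational bounds plus auxiliary
cross-entropy, combined with channel weights.

For each corrupted entry the denoiser predicts a clean-category
distribution p(x0 | x_t).  The reverse step is the posterior mixture

    p(x_{t-1} | x_t) = sum_{x0 ordinary} q(x_{t-1} | x_t, x0) p(x0 | x_t)

and the VLB term at step t is KL[q(x_{t-1} | x_t, x0_true) || p(x_{t-1} | x_t)]
summed over atoms, charges and strictly-lower-triangular edges.  At t = 1
the posterior is a point mass on the clean category, so the same KL formula
reduces to the reconstruction term -log p(x0 | x_1).  The auxiliary
cross-entropy directly scores the clean-category prediction and markedly
improves sample quality when mixed in.

All KL/log computations run in double precision with a 1e-30 floor inside
logarithms (absorbing-state posteriors contain exact zeros).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .denoiser import DenoiserOutput
from .mol_graph import MoleculeGraph
from .noise import NoiseSchedule, posterior_tensor, tril_indices
from .nn.autodiff import Tensor

_LOG_FLOOR = 1e-30


@dataclass(frozen=True)
class LossWeights:
    """Relative weights for (VLB_A, VLB_C, VLB_E, CE_A, CE_C, CE_E).

    Edges are up-weighted: they number n^2 but are mostly "no-bond", and
    bond mistakes dominate decode failures.
    """

    vlb_atom: float = 1.0
    vlb_charge: float = 1.0
    vlb_edge: float = 5.0
    ce_atom: float = 0.5
    ce_charge: float = 0.5
    ce_edge: float = 2.5

    def __post_init__(self):
        vals = self.as_tuple()
        if any(w < 0 for w in vals):
            raise ValueError("loss weights must be nonnegative")
        if not any(w > 0 for w in vals):
            raise ValueError("at least one loss weight must be positive")

    def as_tuple(self):
        return (
            self.vlb_atom,
            self.vlb_charge,
            self.vlb_edge,
            self.ce_atom,
            self.ce_charge,
            self.ce_edge,
        )


class ChannelTerms(NamedTuple):
    atom: float
    charge: float
    edge: float


def _posterior_stack(schedule: NoiseSchedule, channel: str) -> np.ndarray:
    """R[t, i, j, k] = q(x_{t-1}=j | x_t=i, x0=k), cached on the schedule."""
    cache = getattr(schedule, "_posterior_stacks", None)
    if cache is None:
        cache = {}
        schedule._posterior_stacks = cache
    if channel not in cache:
        K = schedule.K[channel]
        stack = np.zeros((schedule.T + 1, K + 1, K + 1, K))
        for t in range(1, schedule.T + 1):
            stack[t] = posterior_tensor(t, channel, schedule)
        cache[channel] = stack
    return cache[channel]


def reverse_mixture_np(
    probs0: np.ndarray,
    xt_idx: np.ndarray,
    t,
    channel: str,
    schedule: NoiseSchedule,
    on_zero: str = "raise",
) -> np.ndarray:
    """Reverse-step distributions over x_{t-1} for a batch of entries.

    ``probs0``: (..., K) clean predictions; ``xt_idx``: (...) current states;
    ``t``: scalar or array broadcastable to ``xt_idx``.  Rows are
    renormalized after dropping unreachable mixture components.

    A row with zero total mass means the current state is unreachable under
    the forward process — impossible on-policy, but scaffold clamping writes
    clean categories into late-step states.  ``on_zero="keep"`` turns such
    rows into a point mass on the current state (they are constant anyway);
    the default raises.
    """
    R = _posterior_stack(schedule, channel)
    t_arr = np.broadcast_to(np.asarray(t), xt_idx.shape)
    Rx = R[t_arr, xt_idx]  # (..., K+1, K)
    rev = np.einsum("...jk,...k->...j", Rx, probs0)
    norm = rev.sum(axis=-1, keepdims=True)
    zero = norm <= 0.0
    if zero.any():
        if on_zero != "keep":
            raise FloatingPointError("reverse mixture has zero mass (unreachable state)")
        stay = np.zeros_like(rev)
        np.put_along_axis(stay, xt_idx[..., None], 1.0, axis=-1)
        rev = np.where(zero, stay, rev)
        norm = np.where(zero, 1.0, norm)
    return rev / norm


def _vlb_channel_tensor(
    probs0: Tensor, x0_idx, xt_idx, t_arr, channel: str, schedule: NoiseSchedule
) -> Tensor:
    """Sum over entries of KL[q(x_{t-1}|x_t,x0) || p(x_{t-1}|x_t)].

    ``probs0`` is (N, K); index arrays are (N,).  Differentiable in probs0.
    """
    R = _posterior_stack(schedule, channel)
    Rx = R[t_arr, xt_idx]  # (N, K+1, K) constant
    N, Kp1, K = Rx.shape
    rev_un = (Tensor(Rx) @ probs0.reshape(N, K, 1)).reshape(N, Kp1)
    rev = rev_un / rev_un.sum(axis=-1, keepdims=True).clamp_min(_LOG_FLOOR)
    q = R[t_arr, xt_idx, :, x0_idx]  # (N, K+1) true posterior, constant
    q_log_q = float(np.sum(np.where(q > 0.0, q * np.log(np.maximum(q, _LOG_FLOOR)), 0.0)))
    cross = (Tensor(q) * rev.clamp_min(_LOG_FLOOR).log()).sum()
    return (-cross) + q_log_q


def _ce_channel_tensor(probs0: Tensor, x0_idx) -> Tensor:
    """Mean negative log-probability of the true clean category."""
    N = probs0.shape[0]
    picked = probs0[np.arange(N), x0_idx]
    return -(picked.clamp_min(_LOG_FLOOR).log().mean())


def _flatten_graph(g: MoleculeGraph):
    rows, cols = tril_indices(g.n)
    return g.atom_indices, g.charge_indices, g.bond_indices[rows, cols]


def vlb_terms(
    g0: MoleculeGraph,
    g_t: MoleculeGraph,
    t: int,
    out: DenoiserOutput,
    schedule: NoiseSchedule,
) -> ChannelTerms:
    """Per-channel VLB term at step t (sum over entries); t = 1 gives the
    reconstruction term -log p(x0 | x_1)."""
    if t == 0:
        raise ValueError("vlb_terms is defined for t >= 1")
    rows, cols = tril_indices(g0.n)
    a0, c0, e0 = _flatten_graph(g0)
    at, ct, et = _flatten_graph(g_t)
    t_a = np.full(g0.n, t)
    t_e = np.full(len(e0), t)
    la = _vlb_channel_tensor(Tensor(out.atom_probs), a0, at, t_a, "A", schedule)
    lc = _vlb_channel_tensor(Tensor(out.charge_probs), c0, ct, t_a, "C", schedule)
    le = _vlb_channel_tensor(
        Tensor(out.edge_probs[rows, cols]), e0, et, t_e, "E", schedule
    )
    return ChannelTerms(la.item(), lc.item(), le.item())


def ce_terms(g0: MoleculeGraph, out: DenoiserOutput) -> ChannelTerms:
    """Per-channel mean cross-entropy against the clean categories."""
    rows, cols = tril_indices(g0.n)
    a0, c0, e0 = _flatten_graph(g0)
    ca = _ce_channel_tensor(Tensor(out.atom_probs), a0)
    cc = _ce_channel_tensor(Tensor(out.charge_probs), c0)
    ce = _ce_channel_tensor(Tensor(out.edge_probs[rows, cols]), e0)
    return ChannelTerms(ca.item(), cc.item(), ce.item())


def prior_terms(g0: MoleculeGraph, schedule: NoiseSchedule) -> ChannelTerms:
    """L_T = KL[q(x_T | x0) || p(x_T)] summed over entries, per channel.

    The generative prior p(x_T) puts the terminal cumulative mask mass on
    <MASK> and spreads the remainder uniformly over ordinary categories;
    with the default schedule (full masking) both distributions are point
    masses on <MASK> and L_T = 0.  Constant in the parameters — reported,
    never differentiated.
    """
    T = schedule.T
    out = []
    counts = {
        "A": g0.n,
        "C": g0.n,
        "E": len(tril_indices(g0.n)[0]),
    }
    for ch in ("A", "C", "E"):
        K = schedule.K[ch]
        ab, bb, gb = (
            schedule.abar[ch][T],
            schedule.bbar[ch][T],
            schedule.gbar[ch][T],
        )
        q = np.full(K + 1, bb)
        q[K] = gb
        # q depends on x0 only through where the "keep" mass sits; KL is the
        # same for every ordinary x0, so compute it once and scale by count.
        p = np.full(K + 1, (1.0 - gb) / K if K else 0.0)
        p[K] = gb
        kl_per_entry = 0.0
        for j in range(K + 1):
            qj = q[j] + (ab if j == 0 else 0.0)  # place keep mass at category 0
            if qj > 0.0:
                kl_per_entry += qj * (
                    np.log(max(qj, _LOG_FLOOR)) - np.log(max(p[j], _LOG_FLOOR))
                )
        out.append(kl_per_entry * counts[ch])
    return ChannelTerms(*out)


def total_loss(vlb: ChannelTerms, ce: ChannelTerms, w: LossWeights) -> float:
    """Weighted sum of the six loss components."""
    names = ("VLB_A", "VLB_C", "VLB_E", "CE_A", "CE_C", "CE_E")
    terms = tuple(vlb) + tuple(ce)
    for name, term in zip(names, terms):
        if not np.isfinite(term):
            raise ValueError(f"non-finite loss term {name}: {term}")
    return float(np.dot(w.as_tuple(), terms))


def batch_loss(
    atom_probs: Tensor,
    charge_probs: Tensor,
    edge_probs_tril: Tensor,
    clean_idx: tuple,  # (a0, c0, e0_tril) arrays of shape (B, n) / (B, P)
    noisy_idx: tuple,  # (at, ct, et_tril)
    t_arr: np.ndarray,  # (B,)
    schedule: NoiseSchedule,
    weights: LossWeights,
):
    """Differentiable total loss for a training batch (mean per molecule for
    VLB sums; mean per entry for CE).  Returns (loss Tensor, components)."""
    a0, c0, e0 = clean_idx
    at, ct, et = noisy_idx
    B, n = a0.shape
    P = e0.shape[1]
    K_A = atom_probs.shape[-1]
    K_C = charge_probs.shape[-1]
    K_E = edge_probs_tril.shape[-1]
    t_nodes = np.repeat(t_arr, n)
    t_edges = np.repeat(t_arr, P)

    vlb_a = _vlb_channel_tensor(
        atom_probs.reshape(B * n, K_A), a0.ravel(), at.ravel(), t_nodes, "A", schedule
    ) / B
    vlb_c = _vlb_channel_tensor(
        charge_probs.reshape(B * n, K_C), c0.ravel(), ct.ravel(), t_nodes, "C", schedule
    ) / B
    vlb_e = _vlb_channel_tensor(
        edge_probs_tril.reshape(B * P, K_E), e0.ravel(), et.ravel(), t_edges, "E", schedule
    ) / B
    ce_a = _ce_channel_tensor(atom_probs.reshape(B * n, K_A), a0.ravel())
    ce_c = _ce_channel_tensor(charge_probs.reshape(B * n, K_C), c0.ravel())
    ce_e = _ce_channel_tensor(edge_probs_tril.reshape(B * P, K_E), e0.ravel())

    w = weights
    loss = (
        vlb_a * w.vlb_atom
        + vlb_c * w.vlb_charge
        + vlb_e * w.vlb_edge
        + ce_a * w.ce_atom
        + ce_c * w.ce_charge
        + ce_e * w.ce_edge
    )
    components = {
        "vlb_atom": vlb_a.item(),
        "vlb_charge": vlb_c.item(),
        "vlb_edge": vlb_e.item(),
        "ce_atom": ce_a.item(),
        "ce_charge": ce_c.item(),
        "ce_edge": ce_e.item(),
    }
    return loss, components
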