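"""Graph-transformer denoiser with random node initialization (RNI).

The network maps a noisy graph G_t (one-hot atom types, charges and bond
types, possibly containing ``<MASK>``), the timestep t and an optional
scalar property condition to *clean-category* distributions for every atom,
charge and edge — probability mass is placed on ordinary categories only,
never on ``<MASK>``.

Node input features concatenate one-hot(A_t) | one-hot(C_t) | RNI noise |
sinusoidal time embedding | (condition embedding).  RNI appends fresh
standard-normal features per forward pass, lifting expressiveness past the
1-WL ceiling of plain message passing while keeping the architecture
permutation-equivariant: permuting the nodes together with their RNI rows
permutes the outputs.

Each layer runs full multi-head attention over nodes with an additive edge
bias, followed by a feed-forward block (pre-norm residuals), and updates the
edge stream from the symmetric pair sum h_i + h_j so edge features — and
hence the predicted edge distributions — stay exactly symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .mol_graph import MoleculeGraph, Vocabulary
from .nn.autodiff import Tensor, concat
from .nn.layers import FeedForward, LayerNorm, Linear, Module, dropout


@dataclass(frozen=True)
class DenoiserConfig:
    layers: int = 6
    hidden: int = 256
    heads: int = 8
    dropout: float = 0.1
    rni_dim: int = 8
    time_embed_dim: int = 16
    condition_dim: int = 16
    edge_hidden: int | None = None  # defaults to hidden // 2

    def __post_init__(self):
        if min(self.layers, self.hidden, self.heads) < 1:
            raise ValueError("layers, hidden and heads must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")

    @property
    def d_edge(self) -> int:
        return self.edge_hidden or max(self.hidden // 2, 8)


@dataclass
class DenoiserOutput:
    """Per-entry clean-category distributions (no ``<MASK>`` mass).

    ``atom_probs`` (n x K_A), ``charge_probs`` (n x K_C) and the symmetric
    ``edge_probs`` (n x n x K_E).
    """

    atom_probs: np.ndarray
    charge_probs: np.ndarray
    edge_probs: np.ndarray


def sinusoidal_embedding(t: np.ndarray, T: int, dim: int) -> np.ndarray:
    """Transformer-style sinusoidal features of the integer timestep.

    Frequencies span 1 .. 1/10000, so neighbouring steps stay distinguishable
    (no aliasing) while the lowest frequency covers the whole 1..T range.
    """
    half = dim // 2
    freqs = np.exp(np.arange(half) * (-np.log(10000.0) / max(half - 1, 1)))
    angles = np.asarray(t, dtype=np.float64)[..., None] * freqs
    emb = np.concatenate([np.sin(angles), np.cos(angles)], axis=-1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros(emb.shape[:-1] + (1,))], axis=-1)
    return emb


class _TransformerLayer(Module):
    def __init__(self, rng, hidden: int, heads: int, d_edge: int):
        self.heads = heads
        self.d_head = hidden // heads
        self.ln_attn = LayerNorm(hidden)
        self.wq = Linear(rng, hidden, hidden)
        self.wk = Linear(rng, hidden, hidden)
        self.wv = Linear(rng, hidden, hidden)
        self.wo = Linear(rng, hidden, hidden)
        self.ln_edge_bias = LayerNorm(d_edge)
        self.edge_bias = Linear(rng, d_edge, heads)
        self.edge_value = Linear(rng, d_edge, hidden)
        self.ln_ffn = LayerNorm(hidden)
        self.ffn = FeedForward(rng, hidden, 4 * hidden, hidden)
        self.ln_edge = LayerNorm(d_edge)
        self.edge_ffn = FeedForward(rng, hidden + d_edge, 2 * d_edge, d_edge)

    def __call__(self, h, e, rate, rng, training):
        B, n, H = h.shape
        hn = self.ln_attn(h)

        def split(x):  # (B, n, H) -> (B, heads, n, d_head)
            return x.reshape(B, n, self.heads, self.d_head).swapaxes(1, 2)

        q, k, v = split(self.wq(hn)), split(self.wk(hn)), split(self.wv(hn))
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        en = self.ln_edge_bias(e)
        bias = self.edge_bias(en)  # (B, n, n, heads)
        logits = logits + bias.swapaxes(1, 3).swapaxes(2, 3)
        att = dropout(logits.softmax(axis=-1), rate, rng, training)
        # aggregate node values plus per-pair edge values under one attention
        ev = (
            self.edge_value(en)
            .reshape(B, n, n, self.heads, self.d_head)
            .swapaxes(2, 3)
            .swapaxes(1, 2)
        )  # (B, heads, i, j, d_head)
        mix = att @ v + (att.reshape(B, self.heads, n, n, 1) * ev).sum(axis=3)
        mix = mix.swapaxes(1, 2).reshape(B, n, H)
        h = h + dropout(self.wo(mix), rate, rng, training)
        h = h + dropout(self.ffn(self.ln_ffn(h)), rate, rng, training)

        pair = h.reshape(B, 1, n, H) + h.reshape(B, n, 1, H)  # symmetric in (i, j)
        e_in = concat([pair, self.ln_edge(e)], axis=-1)
        e = e + dropout(self.edge_ffn(e_in), rate, rng, training)
        return h, e


class GraphTransformerDenoiser(Module):
    """p_theta(clean categories | G_t, t, c) for every atom, charge, edge."""

    def __init__(
        self,
        vocab: Vocabulary,
        config: DenoiserConfig,
        T: int,
        conditional: bool = False,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.vocab = vocab
        self.config = config
        self.T = T
        self.conditional = conditional
        d_node = (
            vocab.d_A
            + vocab.d_C
            + config.rni_dim
            + config.time_embed_dim
            + (config.condition_dim if conditional else 0)
        )
        H, dE = config.hidden, config.d_edge
        self.embed_node = Linear(rng, d_node, H)
        self.embed_edge = Linear(rng, vocab.d_E, dE)
        if conditional:
            self.cond_mlp = FeedForward(rng, 1, config.condition_dim, config.condition_dim)
        self.blocks = [
            _TransformerLayer(rng, H, config.heads, dE) for _ in range(config.layers)
        ]
        self.ln_out = LayerNorm(H)
        self.head_atom = Linear(rng, H, vocab.K_A)
        self.head_charge = Linear(rng, H, vocab.K_C)
        self.ln_out_edge = LayerNorm(dE)
        self.head_edge = Linear(rng, dE, vocab.K_E)

    # -- core forward pass (batched, autodiff) -----------------------------
    def forward(
        self,
        A: np.ndarray,  # (B, n, d_A) one-hot, may contain mask category
        C: np.ndarray,  # (B, n, d_C)
        E: np.ndarray,  # (B, n, n, d_E)
        t: np.ndarray,  # (B,) timesteps in [1, T]
        condition: np.ndarray | None = None,  # (B,) standardized values
        rni: np.ndarray | None = None,  # (B, n, rni_dim); fresh normal if None
        rng: np.random.Generator | None = None,
        training: bool = False,
    ):
        t = np.asarray(t)
        if ((t < 1) | (t > self.T)).any():
            raise ValueError(f"timestep outside [1, {self.T}]")
        B, n = A.shape[:2]
        cfg = self.config
        if rni is None:
            if rng is None:
                rng = np.random.default_rng()
            rni = rng.standard_normal((B, n, cfg.rni_dim))
        time_emb = np.broadcast_to(
            sinusoidal_embedding(t, self.T, cfg.time_embed_dim)[:, None, :],
            (B, n, cfg.time_embed_dim),
        )
        feats = [Tensor(A), Tensor(C), Tensor(rni), Tensor(time_emb)]
        if self.conditional:
            if condition is None:
                raise ValueError("conditional model requires a condition value")
            c = Tensor(np.asarray(condition, dtype=np.float64).reshape(B, 1))
            cemb = self.cond_mlp(c).reshape(B, 1, cfg.condition_dim)
            feats.append(cemb.broadcast_to((B, n, cfg.condition_dim)))
        elif condition is not None:
            raise ValueError("unconditional model given a condition value")

        h = self.embed_node(concat(feats, axis=-1))
        e = self.embed_edge(Tensor(E))
        for block in self.blocks:
            h, e = block(h, e, cfg.dropout, rng, training)

        hn = self.ln_out(h)
        atom_probs = self.head_atom(hn).softmax(axis=-1)
        charge_probs = self.head_charge(hn).softmax(axis=-1)
        el = self.head_edge(self.ln_out_edge(e))
        el = (el + el.swapaxes(1, 2)) * 0.5  # exact symmetry of edge logits
        edge_probs = el.softmax(axis=-1)
        return atom_probs, charge_probs, edge_probs

    # -- spec-level convenience (single graph, numpy out) ------------------
    def predict_clean(
        self,
        g_t: MoleculeGraph,
        t: int,
        condition: float | None = None,
        rni_noise: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> DenoiserOutput:
        cond = None if condition is None else np.asarray([condition])
        rni = None if rni_noise is None else rni_noise[None]
        a, c, e = self.forward(
            g_t.A[None],
            g_t.C[None],
            g_t.E[None],
            np.asarray([t]),
            condition=cond,
            rni=rni,
            rng=rng,
            training=False,
        )
        return DenoiserOutput(a.data[0], c.data[0], e.data[0])

    def config_dict(self) -> dict:
        return asdict(self.config)
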