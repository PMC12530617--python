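"""Training loop: corruption -> denoiser -> weighted VLB + CE objective.

Defaults follow standard practice for this model family: AdamW (lr 1e-4,
weight decay 1e-4), batch size 128, 500 epochs, gradient-norm clipping at
1.0, one uniformly drawn timestep per molecule per step, checkpoint selected
by best validation loss.  A ``fixture_scale_config`` preset (small model,
short schedule, larger learning rate) ships alongside for CPU-scale corpora.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .denoiser import DenoiserConfig, GraphTransformerDenoiser
from .mol_graph import Vocabulary, _one_hot, build_vocabulary, parse_smiles, smiles_to_graph
from .model import MolecularDiffusion
from .noise import corrupt_indices, schedule_for_vocab, tril_indices
from .objective import LossWeights, batch_loss
from .nn.autodiff import Tensor


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 128
    epochs: int = 500
    grad_clip_norm: float = 1.0
    lr_decay: str = "none"  # "none" or "cosine" (to zero over the run)
    seed: int = 0
    split_ratio: tuple = (0.8, 0.1, 0.1)
    weights: LossWeights = field(default_factory=LossWeights)
    T: int = 500
    mask_fraction_final: float = 1.0
    uniform_weight: float = 0.05
    denoiser: DenoiserConfig = field(default_factory=DenoiserConfig)
    n_headroom: int = 2  # free rows beyond the largest training molecule
    n: int | None = None  # explicit graph size override
    condition_column: str | None = None
    t_sampling: str = "stratified"  # "stratified" (jittered even coverage) or "uniform"

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be positive")
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def fixture_scale_config(**overrides) -> TrainConfig:
    """Desk-scale preset for the enumerated fixtures: a 2-layer width-64
    transformer, a short 32-step schedule and a learning rate sized for
    corpora of a few hundred tiny molecules."""
    base = dict(
        lr=3e-3,
        lr_decay="cosine",
        batch_size=16,
        epochs=60,
        T=32,
        denoiser=DenoiserConfig(
            layers=2, hidden=64, heads=4, dropout=0.0, rni_dim=8,
            time_embed_dim=16, condition_dim=16, edge_hidden=64,
        ),
    )
    base.update(overrides)
    return TrainConfig(**base)


def split_dataset(smiles_list, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Disjoint random partition with sizes within 1 of the exact fractions
    (largest-remainder rounding), reproducible from ``seed``."""
    if any(r <= 0 for r in ratios):
        raise ValueError("split ratios must all be positive")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    N = len(smiles_list)
    if N < len(ratios):
        raise ValueError(f"need at least {len(ratios)} molecules, got {N}")
    exact = np.asarray(ratios, dtype=float) * N
    sizes = np.floor(exact).astype(int)
    remainder = exact - sizes
    for i in np.argsort(-remainder)[: N - sizes.sum()]:
        sizes[i] += 1
    sizes = np.maximum(sizes, 1)
    while sizes.sum() > N:
        sizes[np.argmax(sizes)] -= 1
    perm = np.random.default_rng(seed).permutation(N)
    bounds = np.cumsum(sizes)[:-1]
    parts = np.split(perm, bounds)
    return tuple([smiles_list[i] for i in part] for part in parts)


class AdamW:
    """Decoupled weight-decay Adam over a named parameter dict."""

    def __init__(self, params: dict, lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def clip_grad_norm(self, max_norm: float) -> float:
        sq = sum(
            float((p.grad**2).sum()) for p in self.params.values() if p.grad is not None
        )
        norm = np.sqrt(sq)
        if norm > max_norm:
            scale = max_norm / (norm + 1e-12)
            for p in self.params.values():
                if p.grad is not None:
                    p.grad = p.grad * scale
        return norm

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            p.data = p.data - self.lr * (update + self.wd * p.data)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


@dataclass
class TrainResult:
    model: MolecularDiffusion
    history: list  # per-step dicts of loss components
    val_history: list  # per-epoch validation losses
    best_epoch: int
    best_val_loss: float
    final_val_loss: float


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data.reset_index(drop=True)
    return pd.DataFrame({"smiles": list(data)})


def _encode_dataset(smiles, vocab: Vocabulary, n: int):
    N = len(smiles)
    rows, cols = tril_indices(n)
    a = np.empty((N, n), dtype=np.int64)
    c = np.empty((N, n), dtype=np.int64)
    e = np.empty((N, len(rows)), dtype=np.int64)
    for i, s in enumerate(smiles):
        g = smiles_to_graph(s, vocab, n)
        a[i], c[i] = g.atom_indices, g.charge_indices
        e[i] = g.bond_indices[rows, cols]
    return a, c, e


def _eval_loss(denoiser, schedule, weights, enc, cond, n, rng):
    a0, c0, e0 = enc
    rows, cols = tril_indices(n)
    t_arr = rng.integers(1, schedule.T + 1, size=a0.shape[0])
    at = _corrupt_batch(a0, t_arr, "A", schedule, rng)
    ct = _corrupt_batch(c0, t_arr, "C", schedule, rng)
    et = _corrupt_batch(e0, t_arr, "E", schedule, rng)
    A, C = _one_hot(at, denoiser.vocab.d_A), _one_hot(ct, denoiser.vocab.d_C)
    E = _edges_to_dense_onehot(et, n, denoiser.vocab.d_E)
    from .nn.autodiff import no_grad

    with no_grad():
        pa, pc, pe = denoiser.forward(
            A, C, E, t_arr, condition=cond, rng=rng, training=False
        )
        loss, _ = batch_loss(
            pa, pc, Tensor(pe.data[:, rows, cols]), (a0, c0, e0), (at, ct, et),
            t_arr, schedule, weights,
        )
    return loss.item()


def _draw_timesteps(rng, T, size, mode):
    """Per-molecule timesteps, marginally uniform on {1..T}.

    "stratified" spreads the batch evenly over the range (with jitter and a
    random assignment to molecules), cutting the variance of the
    Monte-Carlo loss estimate without changing its expectation.
    """
    if mode == "uniform":
        return rng.integers(1, T + 1, size=size)
    offsets = rng.random(size)
    strata = (np.arange(size) + offsets) / size  # one draw per stratum of (0, 1]
    return rng.permutation(np.floor(strata * T).astype(np.int64) + 1)


def _corrupt_batch(idx, t_arr, channel, schedule, rng):
    out = np.empty_like(idx)
    for t in np.unique(t_arr):
        sel = t_arr == t
        out[sel] = corrupt_indices(idx[sel], int(t), channel, schedule, rng)
    return out


def _edges_to_dense_onehot(e_tril, n, d_E):
    B = e_tril.shape[0]
    rows, cols = tril_indices(n)
    e = np.zeros((B, n, n), dtype=np.int64)
    e[:, rows, cols] = e_tril
    e[:, cols, rows] = e_tril
    return _one_hot(e, d_E)


def train(
    data,
    config: TrainConfig,
    val_data=None,
    vocab: Vocabulary | None = None,
    log_path=None,
) -> TrainResult:
    """Fit the denoiser; returns the best-validation checkpoint.

    ``data``/``val_data`` are SMILES lists or DataFrames with a ``smiles``
    column (plus the property column for conditional training).  When
    ``val_data`` is omitted the training set doubles as validation (the
    fixtures are enumerations, not held-out corpora).
    """
    # canonical row order: training depends on the multiset of molecules,
    # not on the order the corpus file happened to list them in
    frame = _as_frame(data)
    frame = frame.sort_values(by=list(frame.columns), kind="stable").reset_index(drop=True)
    val_frame = _as_frame(val_data) if val_data is not None else frame
    smiles = frame["smiles"].tolist()
    if vocab is None:
        vocab = build_vocabulary(sorted(set(smiles) | set(val_frame["smiles"])))
    max_atoms = max(parse_smiles(s).GetNumAtoms() for s in smiles)
    n = config.n if config.n is not None else max_atoms + config.n_headroom
    schedule = schedule_for_vocab(
        vocab,
        config.T,
        mask_fraction_final=config.mask_fraction_final,
        uniform_weight=config.uniform_weight,
    )
    conditional = config.condition_column is not None
    cond_mean, cond_std = 0.0, 1.0
    cond_vals = None
    val_cond = None
    if conditional:
        cond_vals = frame[config.condition_column].to_numpy(dtype=float)
        cond_mean = float(cond_vals.mean())
        cond_std = float(cond_vals.std()) or 1.0
        cond_vals = (cond_vals - cond_mean) / cond_std
        val_cond = (
            val_frame[config.condition_column].to_numpy(dtype=float) - cond_mean
        ) / cond_std

    denoiser = GraphTransformerDenoiser(
        vocab, config.denoiser, T=config.T, conditional=conditional, seed=config.seed
    )
    params = denoiser.named_params()
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    enc = _encode_dataset(smiles, vocab, n)
    val_enc = _encode_dataset(val_frame["smiles"].tolist(), vocab, n)
    rows, cols = tril_indices(n)
    N = len(smiles)

    history, val_history = [], []
    best_val, best_epoch = np.inf, -1
    best_params = {k: p.data.copy() for k, p in params.items()}
    writer = None
    log_file = None
    if log_path is not None:
        log_file = open(log_path, "w", newline="")
        writer = csv.writer(log_file)
        writer.writerow(
            ["epoch", "step", "loss", "vlb_atom", "vlb_charge", "vlb_edge",
             "ce_atom", "ce_charge", "ce_edge", "val_loss"]
        )

    steps_per_epoch = max(1, int(np.ceil(N / config.batch_size)))
    total_steps = max(1, config.epochs * steps_per_epoch)
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(N)
        for lo in range(0, N, config.batch_size):
            if config.lr_decay == "cosine":
                opt.lr = config.lr * 0.5 * (1.0 + np.cos(np.pi * step / total_steps))
            sel = order[lo : lo + config.batch_size]
            a0, c0, e0 = enc[0][sel], enc[1][sel], enc[2][sel]
            t_arr = _draw_timesteps(rng, config.T, len(sel), config.t_sampling)
            at = _corrupt_batch(a0, t_arr, "A", schedule, rng)
            ct = _corrupt_batch(c0, t_arr, "C", schedule, rng)
            et = _corrupt_batch(e0, t_arr, "E", schedule, rng)
            pa, pc, pe = denoiser.forward(
                _one_hot(at, vocab.d_A),
                _one_hot(ct, vocab.d_C),
                _edges_to_dense_onehot(et, n, vocab.d_E),
                t_arr,
                condition=None if cond_vals is None else cond_vals[sel],
                rng=rng,
                training=True,
            )
            loss, comps = batch_loss(
                pa, pc, pe[:, rows, cols], (a0, c0, e0), (at, ct, et),
                t_arr, schedule, config.weights,
            )
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step}: {comps}; "
                    f"batch indices {sel.tolist()}"
                )
            opt.zero_grad()
            loss.backward()
            opt.clip_grad_norm(config.grad_clip_norm)
            opt.step()
            record = {"epoch": epoch, "step": step, "loss": loss.item(), **comps}
            history.append(record)
            if writer:
                writer.writerow(
                    [epoch, step, record["loss"]]
                    + [comps[k] for k in ("vlb_atom", "vlb_charge", "vlb_edge",
                                          "ce_atom", "ce_charge", "ce_edge")]
                    + [""]
                )
            step += 1
        val_rng = np.random.default_rng(config.seed + 90001)  # same draws each epoch
        val_loss = _eval_loss(
            denoiser, schedule, config.weights, val_enc, val_cond, n, val_rng
        )
        val_history.append(val_loss)
        if writer:
            writer.writerow([epoch, step, "", "", "", "", "", "", "", val_loss])
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_params = {k: p.data.copy() for k, p in params.items()}

    if log_file:
        log_file.close()
    final_val = val_history[-1] if val_history else np.inf
    denoiser.load_params(best_params)
    model = MolecularDiffusion(
        vocab=vocab,
        schedule=schedule,
        denoiser=denoiser,
        n=n,
        conditional=conditional,
        condition_name=config.condition_column,
        cond_mean=cond_mean,
        cond_std=cond_std,
    )
    if config.epochs == 0:
        best_val = final_val = np.inf
    return TrainResult(
        model=model,
        history=history,
        val_history=val_history,
        best_epoch=best_epoch,
        best_val_loss=best_val,
        final_val_loss=final_val,
    )
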