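"""Reverse-diffusion generation.

Sampling starts from the terminal graph (every free atom/charge/edge entry
in the ``<MASK>`` state, no-bond diagonal) and walks t = T..1.  At each step
the denoiser predicts clean-category distributions; the reverse transition
is the posterior mixture over those predictions; edges are sampled on the
strictly lower triangle and mirrored.  The final step takes the argmax of
the clean prediction over ordinary categories, so a decoded graph can never
retain ``<MASK>``.

Scaffold-preserving optimization clamps the first ``n_s`` rows (and the
leading n_s x n_s edge block) to a start molecule after every reverse
update, so the start molecule survives verbatim in every intermediate and
final graph while the remaining rows are free to grow new atoms around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .denoiser import DenoiserOutput
from .mol_graph import (
    MoleculeGraph,
    Vocabulary,
    _one_hot,
    canonical_smiles,
    graph_to_smiles,
    smiles_to_graph,
)
from .model import MolecularDiffusion
from .noise import NoiseSchedule, tril_indices
from .nn.autodiff import no_grad
from .objective import reverse_mixture_np

_CHUNK = 512  # forward-pass batch chunk


@dataclass
class ScaffoldConstraint:
    """Start molecule pinned to the first ``n_s`` rows of the graph."""

    S: MoleculeGraph
    n_s: int
    M_A: np.ndarray = field(repr=False, default=None)
    M_C: np.ndarray = field(repr=False, default=None)
    M_E: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_smiles(cls, start: str, vocab: Vocabulary, n: int) -> "ScaffoldConstraint":
        s = canonical_smiles(start)  # canonical atom order for reproducibility
        g = smiles_to_graph(s, vocab, n)
        n_s = g.n_real  # n_s == n is allowed: a fully constrained graph
        M_A = np.zeros((n, g.A.shape[1]))
        M_C = np.zeros((n, g.C.shape[1]))
        M_E = np.zeros((n, n, g.E.shape[2]))
        M_A[:n_s] = 1.0
        M_C[:n_s] = 1.0
        M_E[:n_s, :n_s] = 1.0
        return cls(S=g, n_s=n_s, M_A=M_A, M_C=M_C, M_E=M_E)


@dataclass
class ReverseDistributions:
    atom: np.ndarray  # (n, K_A+1) over x_{t-1}
    charge: np.ndarray
    edge: np.ndarray  # (n, n, K_E+1), symmetric, no-bond point mass on diagonal


@dataclass
class SampleResult:
    smiles: list  # canonical SMILES or None per requested molecule
    graphs: list  # decoded MoleculeGraph per requested molecule


def reverse_distribution(
    g_t: MoleculeGraph, t: int, out: DenoiserOutput, schedule: NoiseSchedule
) -> ReverseDistributions:
    """Posterior mixture p(x_{t-1} | x_t) for every entry of one graph."""
    n = g_t.n
    atom = reverse_mixture_np(out.atom_probs, g_t.atom_indices, t, "A", schedule)
    charge = reverse_mixture_np(out.charge_probs, g_t.charge_indices, t, "C", schedule)
    rows, cols = tril_indices(n)
    e_idx = g_t.bond_indices
    low = reverse_mixture_np(out.edge_probs[rows, cols], e_idx[rows, cols], t, "E", schedule)
    K_Ep1 = low.shape[-1]
    edge = np.zeros((n, n, K_Ep1))
    edge[rows, cols] = low
    edge[cols, rows] = low
    edge[np.arange(n), np.arange(n), 0] = 1.0
    return ReverseDistributions(atom, charge, edge)


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cdf = probs.cumsum(axis=-1)
    cdf[..., -1] = 1.0
    u = rng.random(probs.shape[:-1] + (1,))
    return (cdf < u).sum(axis=-1)


def _apply_scaffold(a, c, e, scaffold: ScaffoldConstraint):
    ns = scaffold.n_s
    a[:, :ns] = scaffold.S.atom_indices[:ns]
    c[:, :ns] = scaffold.S.charge_indices[:ns]
    e[:, :ns, :ns] = scaffold.S.bond_indices[:ns, :ns]


def _reverse_loop(
    model: MolecularDiffusion,
    n_molecules: int,
    rng: np.random.Generator,
    condition: float | None = None,
    scaffold: ScaffoldConstraint | None = None,
    callback=None,
):
    """Run the full reverse chain for a batch; returns final index arrays."""
    vocab, schedule = model.vocab, model.schedule
    n, T = model.n, schedule.T
    B = n_molecules
    mask_a, mask_c, mask_e = vocab.d_A - 1, vocab.d_C - 1, vocab.d_E - 1
    a = np.full((B, n), mask_a, dtype=np.int64)
    c = np.full((B, n), mask_c, dtype=np.int64)
    e = np.full((B, n, n), mask_e, dtype=np.int64)
    e[:, np.arange(n), np.arange(n)] = 0
    if scaffold is not None:
        _apply_scaffold(a, c, e, scaffold)
    if callback is not None:
        callback(T, a, c, e)
    rows, cols = tril_indices(n)
    cond_arr = None
    if model.conditional:
        if condition is None:
            raise ValueError("conditional model requires a condition value")
        cond_arr = np.full(B, model.standardize(condition))

    for t in range(T, 0, -1):
        p0_a = np.empty((B, n, vocab.K_A))
        p0_c = np.empty((B, n, vocab.K_C))
        p0_e = np.empty((B, n, n, vocab.K_E))
        with no_grad():
            for lo in range(0, B, _CHUNK):
                hi = min(lo + _CHUNK, B)
                pa, pc, pe = model.denoiser.forward(
                    _one_hot(a[lo:hi], vocab.d_A),
                    _one_hot(c[lo:hi], vocab.d_C),
                    _one_hot(e[lo:hi], vocab.d_E),
                    np.full(hi - lo, t),
                    condition=None if cond_arr is None else cond_arr[lo:hi],
                    rng=rng,
                    training=False,
                )
                p0_a[lo:hi], p0_c[lo:hi], p0_e[lo:hi] = pa.data, pc.data, pe.data
        on_zero = "keep" if scaffold is not None else "raise"
        if t > 1:
            a = _sample_rows(
                reverse_mixture_np(p0_a, a, t, "A", schedule, on_zero=on_zero), rng
            )
            c = _sample_rows(
                reverse_mixture_np(p0_c, c, t, "C", schedule, on_zero=on_zero), rng
            )
            low = _sample_rows(
                reverse_mixture_np(
                    p0_e[:, rows, cols], e[:, rows, cols], t, "E", schedule,
                    on_zero=on_zero,
                ),
                rng,
            )
        else:
            # last step: argmax of the clean prediction — no residual <MASK>
            a = p0_a.argmax(axis=-1)
            c = p0_c.argmax(axis=-1)
            low = p0_e[:, rows, cols].argmax(axis=-1)
        e = np.zeros((B, n, n), dtype=np.int64)
        e[:, rows, cols] = low
        e[:, cols, rows] = low
        if scaffold is not None:
            _apply_scaffold(a, c, e, scaffold)
        if callback is not None:
            callback(t - 1, a, c, e)
    return a, c, e


def _decode_batch(model, a, c, e, component: str) -> SampleResult:
    vocab = model.vocab
    smiles, graphs = [], []
    for i in range(a.shape[0]):
        n_real = int((a[i] != vocab.padding_index).sum())
        g = MoleculeGraph.from_indices(vocab, a[i], c[i], e[i], n_real)
        graphs.append(g)
        smiles.append(graph_to_smiles(g, vocab, component=component))
    return SampleResult(smiles=smiles, graphs=graphs)


def sample(
    model: MolecularDiffusion,
    n_molecules: int,
    condition: float | None = None,
    seed: int = 0,
    callback=None,
) -> SampleResult:
    """Generate ``n_molecules`` graphs and decode them.

    Returns one entry per request; failed decodes are ``None`` in
    ``smiles`` (they count against validity) with the raw graph kept.
    """
    rng = np.random.default_rng(seed)
    a, c, e = _reverse_loop(
        model, n_molecules, rng, condition=condition, callback=callback
    )
    return _decode_batch(model, a, c, e, component="largest")


def optimize(
    model: MolecularDiffusion,
    start: str,
    condition: float,
    n_samples: int,
    seed: int = 0,
    callback=None,
) -> SampleResult:
    """Property-targeted generation that preserves ``start`` as a subgraph.

    Requires a conditional model.  The start molecule occupies the first
    rows in canonical atom order and is re-imposed after every reverse
    update; decoding keeps the connected component containing it.
    """
    if not model.conditional:
        raise ValueError("optimization requires a conditional checkpoint")
    scaffold = ScaffoldConstraint.from_smiles(start, model.vocab, model.n)
    rng = np.random.default_rng(seed)
    a, c, e = _reverse_loop(
        model,
        n_samples,
        rng,
        condition=condition,
        scaffold=scaffold,
        callback=callback,
    )
    return _decode_batch(model, a, c, e, component="scaffold")
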