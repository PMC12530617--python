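# Methods

## Model

`moldiff` generates 2D molecular graphs with a discrete denoising diffusion
model.  A molecule with up to `n` heavy atoms is a triple `G = <A, C, E>` of
categorical variables: atom types `A` (n × d_A one-hot), formal charges `C`
(n × d_C) and bond types `E` (n × n × d_E, symmetric, "no-bond" on the
diagonal).  Molecules smaller than `n` are completed with `<PADDING>` atoms
that carry no bonds; padding is an ordinary atom category that the model
corrupts and predicts like any element, which is how the size distribution
of molecules is learned rather than sampled from the data.  Hydrogens are
implicit; stereochemistry and isotopes are stripped on encode.

### Forward process: mask-and-replace

Every entry evolves independently under a Markov chain with column-stochastic
transition matrices

    Q_t[:, j] = α_t e_j + β_t 1_K + γ_t e_mask   (j ordinary),
    Q_t[:, mask] = e_mask,

i.e. an entry is kept with probability α_t, replaced by a uniformly chosen
ordinary category with probability K·β_t, and absorbed into `<MASK>` with
probability γ_t.  The matrix family is closed under composition, so the
cumulative products `Q̄_t = Q_t···Q_1` are tracked by three masses
(keep, uniform, mask) per step in O(T) instead of explicit matrix products;
tests verify the closed form against the explicit product to 1e-10.

The default schedule ("linear-mask") makes the *cumulative* mask mass linear
in t, `m_t = mask_fraction_final · t/T` with `mask_fraction_final = 1`, so
the terminal state is all-mask and the per-step rate is
`γ_t = (m_t − m_{t−1})/(1 − m_{t−1})`.  Uniform replacement is a small
admixture, `K·β_t = min(uniform_weight·γ_t, 1−γ_t)` with
`uniform_weight = 0.05`: masking dominates (the denoiser mostly restores
masked entries) while the uniform channel leaves a path for the reverse
process to repair wrongly committed unmasked entries.  One (α, γ) profile is
shared by all three channels; only K differs.  `T` defaults to 500 for
full-scale corpora; the fixture preset uses T = 32 (T = 50 for the
single-molecule study), ample for graphs with ≤ 15 free entries.

Edges are corrupted on the strictly lower triangle and mirrored (the graph
is undirected); the diagonal stays "no-bond".

### Reverse process

The denoiser predicts clean-category distributions `p(x̃_0 | G_t)` (never
`<MASK>`).  The reverse transition mixes exact posteriors:

    p(x_{t−1} | x_t) = Σ_{x̃0} q(x_{t−1} | x_t, x̃0) · p(x̃0 | x_t),
    q(x_{t−1}=j | x_t=i, x0=k) ∝ Q_t[i, j] · Q̄_{t−1}[j, k] / Q̄_t[i, k].

Unreachable mixture components (zero denominator) are dropped and rows
renormalized.  Sampling runs t = T..1 with categorical draws per entry
(lower-triangle edges mirrored); at t = 1 the final value is the argmax of
the clean prediction over ordinary categories, so no `<MASK>` can survive
into the output.  Decoding drops padding rows, keeps the largest connected
component (ties broken by lowest node index) and asks RDKit to sanitize;
failures count as invalid generations.

### Denoiser

A graph transformer with a node stream and an edge stream:

- node inputs: one-hot(A_t) ‖ one-hot(C_t) ‖ RNI ‖ sinusoidal time embedding
  ‖ (condition embedding);
- per layer (pre-norm residuals): multi-head attention whose logits carry an
  additive per-pair edge bias, and whose output aggregates, under the same
  attention weights, both node values and a per-pair *edge value*
  projection — without the edge-value path the node stream only sees edge
  content through scalar biases, which measurably hurts bond coherence in
  generated graphs;
- edge update from the symmetric pair sum `h_i + h_j` concatenated with the
  edge state, so edge features (hence edge predictions) are symmetric by
  construction; output edge logits are additionally symmetrized exactly.

Random node initialization (RNI) appends `rni_dim = 8` fresh standard-normal
features to every node on every forward pass, in training and sampling
alike.  It breaks the permutation symmetry that would otherwise make all
rows of an all-mask graph indistinguishable, while keeping the network
permutation-equivariant: permuting nodes together with their RNI rows
permutes the outputs (tested exhaustively at n = 4).  Holding RNI fixed
across a reverse trajectory, or averaging predictions over several RNI
draws, both degraded recovery in our experiments; fresh draws per step are
the default.

Full-scale defaults are 6 layers, hidden 256, 8 heads, dropout 0.1; the
fixture preset uses 2 layers, hidden 64, 4 heads, edge stream width 64,
no dropout.  Weights are Xavier-uniform; timesteps use transformer-style
sinusoidal features of the integer step (frequencies 1..1/10000, so
neighbouring steps remain distinguishable).  A scalar property condition is
standardized by training-set mean/sd and embedded through a small MLP whose
output is appended to every node.

### Objective

Per channel ch ∈ {atoms, charges, edges} the variational term at a sampled
step t is `Σ_entries KL[q(x_{t−1}|x_t, x0) ‖ p(x_{t−1}|x_t)]`, which at
t = 1 reduces to the reconstruction term `−log p(x0|x_1)`; the constant
prior term L_T is reported but not differentiated (zero under full masking).
An auxiliary cross-entropy `mean(−log p(x̃0 = x0 | x_t))` per channel
sharpens clean predictions.  The total is a weighted sum with defaults
(1, 1, 5) for the VLB terms and 0.5× those for the CE terms: edge terms are
up-weighted because they number O(n²), are mostly "no-bond", and dominate
decode failures.  KL and log computations run in float64 with 1e-30 floors
(absorbing-state posteriors contain exact zeros).

### Training

AdamW (lr 1e-4, weight decay 1e-4), batch 128, 500 epochs, gradient-norm
clip 1.0, best-validation checkpoint selection — these are the full-scale
defaults; the fixture preset raises the learning rate to 3e-3 with cosine
decay and shrinks everything else.  One timestep is drawn per molecule per
step; draws are stratified across the batch (jittered even coverage of
1..T, randomly assigned to molecules), which keeps the per-example marginal
uniform while reducing the variance of the loss estimate.  Training rows
are sorted canonically first, so the result depends on the multiset of
molecules, not file order.  All computation is numpy in float64 on a tape
recorded by the package's own reverse-mode autodiff core (`moldiff.nn`),
which makes runs bit-reproducible from a single seed.

### Conditional generation and optimization

Conditional models receive the target property value as a standardized
scalar at every node.  Scaffold-preserving optimization clamps the first
`n_s` rows (and the leading n_s × n_s edge block) to the start molecule —
encoded in canonical atom order — after every reverse update, beginning
with the initial all-mask state, so every intermediate graph contains the
start molecule verbatim and generation can only *add* atoms around it.
Clamped clean entries can be unreachable under the forward process at large
t; their reverse rows are held in place rather than raising, since the
clamp overwrites them anyway.  Decoding keeps the component containing the
scaffold (the largest-component rule could otherwise discard it).

## Synthetic fixtures

Real benchmark corpora are large downloads, so the test bed is built from
closed-form enumerations with exact reference distributions: all unbranched
C/O chains up to a maximum length (O-O linkages excluded — unstable
peroxide-type bonds), uniformly weighted.  With ≤ 3 heavy atoms this gives
exactly eight molecules (C, O, CC, CO, CCC, CCO, COC, OCO); their RDKit
logP values split into a carbon-only and an oxygen-bearing mode, which the
conditional tests use as targets.  A `ring_mix` variant adds small carbon
rings.  These fixtures probe the machinery — exact corruption algebra,
recovery of a known distribution (total variation against the analytic
reference), directional property steering, scaffold clamping — but not
drug-like chemical diversity: metrics like novelty or internal diversity on
an 8-molecule support say nothing about behaviour on real screening
libraries, and validity on 1–3 heavy-atom graphs is far easier than on
MOSES/ZINC-scale molecules.

Study problem sizes: single-molecule recovery uses a 2-layer/width-64 model,
T = 50, 500 optimizer steps, 200 samples; distribution recovery trains 750
steps on the 8-chain corpus and draws 2,000 samples; conditional runs reuse
that scale with 200 samples per condition over five seeds; scaffold checks
run 100 constrained generations with the constraint asserted at every
reverse step.

## Numerical choices and degenerate inputs

- Posterior rows for unreachable (x_t, x0) pairs are flagged all-zero
  vectors, never an exception (the oracle sweeps need them defined).
- `mask_fraction_final < 1` is allowed but leaves a schedule whose terminal
  state is not pure mask; the prior term then treats the remaining mass as
  uniform over ordinary categories.
- Component ties in decoding break to the lowest minimum node index.
- An empty valid set makes uniqueness/novelty NaN ("undefined"), not zero.
- Internal diversity follows the MOSES convention: mean over ordered
  fingerprint pairs including self-pairs, Morgan radius 2, 2048 bits.
- The charge vocabulary always contains 0 so padding rows have a neutral
  one-hot charge even if no training molecule is neutral.

## Known limitations

- No atom/bond deletion during optimization: the clamp can only extend the
  start molecule (reducing molecular complexity is out of reach).
- No stereochemistry, isotopes, or 3D conformers.
- The numpy autodiff core is single-threaded CPU code sized for fixture
  corpora; full MOSES/ZINC training would require a GPU implementation of
  the same architecture.
- Uniqueness on a tiny enumerated support is intrinsically low (many
  duplicates are the *correct* behaviour when recovering an 8-molecule
  distribution); it is reported for completeness, not as a quality score.
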