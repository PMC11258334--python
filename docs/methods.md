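# Methods

## Problem setting

Screening cascades in drug discovery (and level-of-theory hierarchies in
quantum chemistry) produce data at several fidelities: a *low-fidelity* (LF)
tier that is cheap, noisy and abundant — e.g. single-dose primary-screen
activities for ~10⁶ compounds — and a *high-fidelity* (HF) tier that is
precise, expensive and sparse — e.g. dose–response pXC50 values for
10³–10⁴ selected compounds. The package learns HF predictive models that
exploit the LF tier, in two settings: **transductive** (every HF molecule
also has a measured LF label) and **inductive** (test molecules lack LF
labels entirely — the "no low-fidelity" set).

## Model

### Graph representation

Molecules are parsed from SMILES into heavy-atom graphs: node features `X`
(element one-hot, degree one-hot, formal charge, aromatic flag, H-count;
schema versioned, checkpoints refuse a mismatched version) and a symmetric
binary adjacency `A` with self-loops added at parse time. Hydrogens are
implicit; bond features are not used — the encoder consumes only `(X, A)`.

### Supervised variational graph autoencoder

The encoder stacks two symmetric-normalised graph convolutions
(`Â H W`, `Â = D^{-1/2} A D^{-1/2}`, no biases so zero-padded rows stay
exactly zero) to produce per-node Gaussian parameters:

    q(z_i | X, A) = N(z_i | μ_i, diag(σ_i²)),
    μ = GCN_μ(X, A),    log σ = GCN_σ(X, A).

The decoder reconstructs adjacency entries from latent inner products,
`p(A_ij = 1 | z_i, z_j) = τ(z_iᵀ z_j)` with `τ` the logistic sigmoid. Only
connectivity is reconstructed, never node features. Training minimises

    L = −E_q[log p(A | Z)] + KL[q ∥ N(0, I)] / N_nodes + λ_sup · ℓ(ν(readout(Z)), y)

where `ℓ` is mean squared error for regression and binary cross-entropy for
classification, and `ν` is a two-layer perceptron head. Notes:

* The supervised head operates on the *pooled* latent (readout of `Z`),
  not on per-node latents — a per-node head cannot emit one molecular
  property. This is the single biggest gap the implementation had to close.
* The KL is the exact closed form, summed over nodes; inside the training
  objective it is divided by the node count so molecules of different sizes
  contribute comparably. The reported loss parts always sum to the total.
* Non-edges are sub-sampled at `neg_ratio` (default 1) negatives per
  observed edge, re-drawn each epoch from a seeded stream; a graph with no
  non-edges falls back to positives only.
* Inference is deterministic: `predict`/`embed` use `μ` and never sample.

### Readouts

Standard readouts are column-wise sum / mean / max. The adaptive readout is
a Set Transformer:

    ST(H)    = (1/K) Σ_k [Decoder(Encoder(H))]_k
    Encoder  = MAB^n(H, H)
    Decoder  = FF(MAB^m(PMA(Z), PMA(Z)))
    PMA(Z)   = MAB(s, FF(Z))            (learnable seed s)
    MAB(X,Y) = A + FF(A),  A = X + MultiHead(X, Y, Y)

with no positional encodings and no dropout. Design choices where the
formulation left room:

* **Head slicing.** The per-head average is taken over `K` slices of the
  final linear projection's output (projection width `K · out_dim`, sliced
  and averaged to `out_dim`) — the simplest reading consistent with the
  formula, and it cleanly decouples the graph-embedding width from the node
  width.
* **Padding.** Node matrices are zero-padded to `M` rows and padding rows
  are *not* masked inside attention by default. The test suite measures the
  consequence (one extra pad row perturbs the output by a bounded, small
  amount); an optional `mask_padding` flag restores exact invariance.
* **FF blocks** are two-layer with tanh; width = `hidden_dim`.
* Defaults for fixtures: `K=4, n=1, m=1, hidden_dim=64, out_dim=64`
  (tests and experiments use smaller widths for speed); all overridable.

### Transfer strategies

Six strategies transfer LF knowledge into the HF model. All augmentations
are concatenated to the pooled graph embedding immediately before the
prediction head; scalar label augmentations are standardised with LF-train
statistics first (this prevents the scale pathologies that the label-sweep
diagnostic exposes).

| strategy          | augmentation / regime                                  | inductive? |
|-------------------|--------------------------------------------------------|-----------|
| `none`            | baseline, HF data only                                 | yes |
| `label`           | raw measured LF label                                  | no (raises on no-LF records) |
| `predicted_label` | LF model's prediction                                  | yes |
| `hybrid_label`    | raw label at train time, predicted at evaluation       | yes |
| `embeddings`      | fixed LF embedding ψ_S(x), joined with live ψ_T(x)     | yes |
| `tune_vgae`       | init from LF checkpoint, retrain everything            | yes |
| `tune_readout`    | init from LF checkpoint, freeze GCN stack, retrain readout + head | yes |

`tune_readout` requires an adaptive-readout LF model (a fixed pooling has
nothing to tune) and also leaves the prediction head trainable — the head is
part of the non-frozen remainder. Freezing disables gradient updates;
frozen parameters are bit-identical before and after any training step.
With more than two fidelities, a separate model is trained per lower
fidelity and labels/embeddings are concatenated in fidelity order
(least- to most-accurate).

## Synthetic data generator

The generator emulates the screening-funnel structure: `n_lf` molecules with
LF labels and an `n_hf ≪ n_lf` subset (default ratio 1:100, echoing the
more-than-two-orders-of-magnitude disparity of real cascades) with HF
labels. Molecules are assembled atom-by-atom from a valence-respecting
C/N/O/S/F/Cl vocabulary with occasional ring closures, sanitised by RDKit,
and deduplicated — every SMILES round-trips through the parser. Sizes span
6–22 heavy atoms.

A latent property `g` is a fixed, deterministic function of structure
(heteroatom fractions, degree moments, ring count, size), standardised over
the library. Labels are noisy views: `HF = g + ε_h` (σ_h = 0.1 by default)
and `LF = g + ε_l`, where the LF noise variance is solved in closed form
from `corr(LF, HF) = r_target` (independent Gaussian noises) and re-solved
from empirical moments if the realised correlation misses ±0.05. The
`skewed_hts` noise model instead collapses the bottom 70% of activity onto
a tight baseline spike, mimicking the inactive bias of primary screens — in
this mode the correlation target is deliberately not enforced (the spike is
the point). Splits: an `inductive_frac` of HF molecules becomes the
no-low-fidelity test set (LF label deleted, removed from the LF pool); the
remainder splits 60/20/20 into HF train/val/test; all other molecules are
LF training data.

What a green test on this generator establishes: that the implementation
correctly exploits LF information whose relation to the HF target is a
noisy affine one with controllable correlation, under realistic small-graph
chemistry. What it does not establish: performance on real HTS data, whose
label noise is assay-specific and whose structure–activity landscape is far
less smooth than `g`; absolute metric values here do not transfer.

## Training and numerical choices

* All tensors are float64 on a small in-repo reverse-mode autodiff engine
  (no GPU frameworks are required); gradients are verified against finite
  differences in the test suite.
* Optimiser: Adam, default learning rate 3e-3 (1e-2 destabilises the
  attention readout), full batch unless `batch_size` is set.
* Labels are standardised to zero mean / unit variance during regression
  training; predictions are mapped back.
* Early stopping (optional) monitors validation MAE and restores the best
  weights.
* Every stochastic stage (data generation, initialisation, latent sampling,
  negative-edge draws) derives from a single per-run seed through named
  substreams, so runs are exactly reproducible; reports are byte-identical
  across reruns.
* The 5σ label filter uses the population standard deviation, computed in a
  single pass (not iteratively); with sd = 0 nothing diverges and all
  values are kept.
* Ties in the best-strategy tally break toward the strategy listed earliest
  in the canonical ordering.

## Known limitations

* The Set Transformer is O(M²) in the padding capacity; `M` is sized to the
  dataset's largest molecule, and very heterogeneous size distributions pay
  for their padding (unmasked by default, see above).
* Classification support replaces the supervised term with cross-entropy
  but keeps the edge-reconstruction objective unchanged.
* The checkpoint format stores weights as JSON text — portable and
  diff-able, but not compact; at the default fixture sizes a checkpoint is
  a few hundred kilobytes.
* `tune_vgae` conventionally pairs with a sum readout (its role is the
  classical whole-network fine-tuning baseline); pairing it with an
  adaptive readout works but duplicates `tune_readout`'s niche.
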