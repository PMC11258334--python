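# mfgnn — multi-fidelity transfer learning for molecular property prediction

Drug-discovery screening funnels (and quantum-chemistry level-of-theory
hierarchies) produce *multi-fidelity* data: a huge, cheap, noisy
**low-fidelity** tier — single-dose primary-screen activities for millions
of compounds — and a sparse, expensive, precise **high-fidelity** tier —
dose–response pXC50 values for a few thousand selected compounds. `mfgnn`
is for computational chemists and ML practitioners who need accurate
predictive models on the sparse high-fidelity task by transferring what can
be learnt from the low-fidelity tier, in both the transductive setting
(every HF molecule has a measured LF label) and the inductive setting (test
molecules lack LF labels — the "no low-fidelity" set).

## The model

The backbone is a **supervised variational graph autoencoder** over
heavy-atom molecular graphs `(X, A)`:

    q(z_i | X, A) = N(z_i | μ_i, diag(σ_i²)),   μ = GCN_μ(X, A),  log σ = GCN_σ(X, A)
    p(A_ij = 1 | z_i, z_j) = τ(z_iᵀ z_j)

trained on the evidence lower bound (edge reconstruction with negative
sub-sampling, KL to a standard-normal prior) plus a supervised term
`λ · ‖ν(readout(Z)) − y‖²` so the latent space organises around the
property of interest. The readout is either a standard pooling (sum / mean
/ max) or an adaptive **Set Transformer**

    ST(H) = (1/K) Σ_k [Decoder(Encoder(H))]_k,   MAB(X, Y) = A + FF(A),  A = X + MultiHead(X, Y, Y)

whose learnable parameters are what make fine-tuning on small HF tasks
possible. Six transfer strategies are implemented: feature augmentation
with the raw LF label (Ψ_Label), the LF model's predicted label
(Ψ_Predicted), a train-raw / evaluate-predicted hybrid (Ψ_Hybrid), the LF
latent embedding ψ_S(x) concatenated with the live HF embedding ψ_T(x)
(Ψ_Embeddings); and pre-train/fine-tune regimes Ψ_(Tune VGAE) (retrain
everything) and Ψ_(Tune readout) (freeze the GCN stack, retrain the
adaptive readout). Strategies are ranked by **% MAE decrease** =
`100 · (MAE_baseline − MAE_strategy) / MAE_baseline`. See
[docs/methods.md](docs/methods.md) for assumptions, defaults and
limitations. Everything runs on NumPy with a small in-repo autodiff engine
— no GPU frameworks required.

## Worked example

```python
from mfgnn import (ExperimentConfig, ReadoutConfig, SyntheticConfig,
                   TrainConfig, VGAEConfig, run_experiment)

cfg = ExperimentConfig(
    synthetic=SyntheticConfig(n_lf=1200, n_hf=200, target_r=0.9),
    strategies=("none", "label", "embeddings"),
    seeds=(1, 2, 3),
    model=VGAEConfig(latent_dim=12, gcn_hidden=24, head_hidden=24,
                     readout=ReadoutConfig(kind="set_transformer", K=4,
                                           hidden_dim=32, out_dim=16, M=20)),
    lf_train=TrainConfig(epochs=50, batch_size=256),
    hf_train=TrainConfig(epochs=160, patience=30),
)
report = run_experiment(cfg)
test = report.table[report.table.split == "hf_test"]
print(test.groupby("strategy")[["mae", "r2", "pct_mae_decrease"]].median())
```

This generates a synthetic screening cascade of 1200 molecules with LF
labels, 200 of which also carry HF labels correlated at Pearson r ≈ 0.9,
pre-trains a low-fidelity supervised VGAE with the attention readout, and
trains high-fidelity models under each strategy. Output (median over the
three seeds, hf_test split):

```
  strategy      mae        r2  pct_mae_decrease
embeddings 0.233646  0.863532         51.479906
     label 0.339513  0.767668         40.241770
      none 0.568145 -0.034125          0.000000
```

The non-augmented baseline (`none`) barely beats the dataset mean on 120
training molecules (R² ≈ 0); concatenating the raw LF label cuts the test
MAE by ~40%, and transferring the learnt LF *embedding* — which also works
inductively, for molecules never screened — by ~51%, lifting R² to 0.86.

The same machinery is scriptable from the shell:

```bash
mfgnn generate --out data.csv
mfgnn train-lf --data data.csv --out lf.json
mfgnn train-hf --data data.csv --strategy embeddings --lf-checkpoint lf.json --out hf.json
mfgnn sweep-label --checkpoint hf_label.json --smiles "CCO"   # Fig-style diagnostic
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch:
it generates the synthetic multi-fidelity world, pre-trains the low-fidelity
model, evaluates the transfer strategies against the non-augmented baseline
on three seeds derived from `--seed`, prints the median test-split metrics,
and writes the (empty) numeric-target report as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
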