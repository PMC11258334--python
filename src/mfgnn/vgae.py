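"""Supervised variational graph autoencoder (VGAE).

The probabilistic encoder stacks graph convolutions to produce per-node
Gaussian parameters,

    q(z_i | X, A) = N(z_i | mu_i, diag(sigma_i^2)),
    mu = GCN_mu(X, A),  log sigma = GCN_sigma(X, A),

the decoder reconstructs adjacency entries through the logistic sigmoid of
latent inner products, p(A_ij = 1 | z_i, z_j) = tau(z_i^T z_j), and training
maximises the evidence lower bound (edge reconstruction with negative
sub-sampling, minus a KL penalty to the standard-normal prior) plus a
supervised term: a small feed-forward head nu applied to the pooled latent
representation, with mean squared error for regression and binary
cross-entropy for classification.

Only graph connectivity is reconstructed, never node features.  Inference is
deterministic (uses mu, no sampling).  Graph convolutions here are the
symmetric-normalised operator Â H W without biases, so zero-padded rows stay
exactly zero through the whole stack.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat, glorot
from .molgraph import (FEATURIZATION_VERSION, AtomFeaturizationScheme,
                       ConfigurationError, DEFAULT_SCHEME, MolecularGraph,
                       MultiFidelityDataset, normalized_adjacency,
                       pad_node_matrix, parse_smiles_to_graph)
from .readouts import (ReadoutConfig, SetTransformerParams,
                       init_set_transformer, set_transformer_forward)

COMPONENTS = ("gcn", "readout", "head")


class CheckpointError(ValueError):
    """Checkpoint incompatible with this model/featurization version."""


class LabelledDataError(ValueError):
    """A supervised operation was given a record without the required label."""


# --------------------------------------------------------------------------- #
# Configs
# --------------------------------------------------------------------------- #

@dataclass
class VGAEConfig:
    latent_dim: int = 16
    gcn_hidden: int = 32
    head_hidden: int = 32
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    task_type: str = "regression"
    aug_dim: int = 0          # width of the augmentation concatenated before the head

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("latent_dim", "gcn_hidden", "head_hidden", "task_type", "aug_dim")}
        d["readout"] = self.readout.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VGAEConfig":
        d = dict(d)
        d["readout"] = ReadoutConfig.from_dict(d["readout"])
        return cls(**d)


@dataclass
class TrainConfig:
    epochs: int = 120
    batch_size: int = 0        # 0 = full batch
    learning_rate: float = 3e-3   # Adam; 1e-2 destabilises the attention readout
    seed: int = 0
    lambda_sup: float = 1.0    # weight of the supervised term
    neg_ratio: int = 1         # sampled non-edges per observed edge
    patience: int = 0          # early stopping on validation MAE; 0 = off

    def __post_init__(self):
        if self.lambda_sup < 0:
            raise ConfigurationError("lambda_sup must be >= 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("epochs", "batch_size", "learning_rate", "seed",
                 "lambda_sup", "neg_ratio", "patience")}


@dataclass
class LatentEncoding:
    mu: np.ndarray
    log_sigma: np.ndarray
    Z: np.ndarray | None = None


# --------------------------------------------------------------------------- #
# Model
# --------------------------------------------------------------------------- #

class VGAEModel:
    """Weights + configuration of a supervised VGAE with pluggable readout."""

    def __init__(self, config: VGAEConfig, scheme: AtomFeaturizationScheme = DEFAULT_SCHEME,
                 rng: np.random.Generator | None = None, seed: int = 0):
        rng = rng if rng is not None else np.random.default_rng(seed)
        self.config = config
        self.scheme = scheme
        self.seed = seed
        d, h, L = scheme.d, config.gcn_hidden, config.latent_dim
        self.gcn_mu = [glorot(rng, d, h), glorot(rng, h, L)]
        self.gcn_sigma = [glorot(rng, d, h), glorot(rng, h, L)]
        ro = config.readout
        self.readout_params: SetTransformerParams | None = None
        if ro.kind == "set_transformer":
            self.readout_params = init_set_transformer(rng, L, ro)
            pooled = ro.out_dim
        else:
            pooled = L
        self.pooled_dim = pooled
        hh = config.head_hidden
        self.head = {"w1": glorot(rng, pooled + config.aug_dim, hh),
                     "b1": Tensor(np.zeros(hh), True),
                     "w2": glorot(rng, hh, 1), "b2": Tensor(np.zeros(1), True)}
        self.freeze_flags = {c: False for c in COMPONENTS}
        self.label_mean = 0.0
        self.label_std = 1.0
        # LF-train statistics used to standardise scalar label augmentations
        self.aug_stats: dict = {}
        self.train_log: list = []
        self.parent_hash: str | None = None
        self.regime: str | None = None

    # ------------------------------------------------------------ parameters
    def component_params(self, component: str) -> list:
        if component == "gcn":
            return list(self.gcn_mu) + list(self.gcn_sigma)
        if component == "readout":
            return self.readout_params.parameters() if self.readout_params else []
        if component == "head":
            return [self.head[k] for k in ("w1", "b1", "w2", "b2")]
        raise ConfigurationError(f"unknown component {component!r}")

    def parameters(self) -> list:
        return sum((self.component_params(c) for c in COMPONENTS), [])

    def apply_freeze(self) -> None:
        """Disable gradient computation for frozen components."""
        for c in COMPONENTS:
            for p in self.component_params(c):
                p.requires_grad = not self.freeze_flags[c]

    def copy(self) -> "VGAEModel":
        return copy.deepcopy(self)

    @property
    def task_type(self) -> str:
        return self.config.task_type

    # ----------------------------------------------------------- checkpoints
    def state_dict(self) -> dict:
        return {
            "format": "mfgnn-checkpoint-v1",
            "featurization_version": self.scheme.version,
            "config": self.config.to_dict(),
            "seed": self.seed,
            "freeze_flags": self.freeze_flags,
            "label_mean": self.label_mean,
            "label_std": self.label_std,
            "aug_stats": self.aug_stats,
            "regime": self.regime,
            "parent_hash": self.parent_hash,
            "weights": [p.data.tolist() for p in self.parameters()],
        }

    def weights_hash(self) -> str:
        import hashlib
        m = hashlib.sha256()
        for p in self.parameters():
            m.update(np.ascontiguousarray(p.data).tobytes())
        return m.hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.state_dict(), fh)

    @classmethod
    def from_state_dict(cls, state: dict,
                        scheme: AtomFeaturizationScheme = DEFAULT_SCHEME) -> "VGAEModel":
        if state.get("featurization_version") != scheme.version:
            raise CheckpointError(
                f"checkpoint featurization {state.get('featurization_version')!r} "
                f"!= current {scheme.version!r}")
        model = cls(VGAEConfig.from_dict(state["config"]), scheme=scheme,
                    seed=state.get("seed", 0))
        params = model.parameters()
        if len(params) != len(state["weights"]):
            raise CheckpointError("weight count mismatch")
        for p, w in zip(params, state["weights"]):
            arr = np.asarray(w, dtype=np.float64)
            if arr.shape != p.data.shape:
                raise CheckpointError("weight shape mismatch")
            p.data = arr
        model.freeze_flags = dict(state["freeze_flags"])
        model.label_mean = state["label_mean"]
        model.label_std = state["label_std"]
        model.aug_stats = dict(state.get("aug_stats") or {})
        model.regime = state.get("regime")
        model.parent_hash = state.get("parent_hash")
        model.apply_freeze()
        return model

    @classmethod
    def load(cls, path, scheme: AtomFeaturizationScheme = DEFAULT_SCHEME) -> "VGAEModel":
        with open(path) as fh:
            return cls.from_state_dict(json.load(fh), scheme=scheme)

    # -------------------------------------------------------------- forward
    def _gcn_stack(self, layers, x: Tensor, ahat: Tensor) -> Tensor:
        h = ahat @ (x @ layers[0])
        h = h.tanh()
        return ahat @ (h @ layers[1])

    def encode_batch(self, x: Tensor, ahat: Tensor) -> tuple:
        mu = self._gcn_stack(self.gcn_mu, x, ahat)
        log_sigma = self._gcn_stack(self.gcn_sigma, x, ahat)
        return mu, log_sigma

    def pool(self, z: Tensor, mask: np.ndarray) -> Tensor:
        """Batched readout of (B × M × L) latents -> (B × pooled_dim)."""
        kind = self.config.readout.kind
        if kind == "set_transformer":
            return set_transformer_forward(z, self.readout_params,
                                           self.config.readout, key_mask=mask)
        if kind == "sum":
            return z.sum(axis=1)
        if kind == "mean":
            counts = mask.sum(axis=1, keepdims=True).astype(float)
            return z.sum(axis=1) * Tensor(1.0 / counts)  # (B,L) * (B,1)
        if kind == "max":
            neg = Tensor(np.where(mask, 0.0, -1e9)[:, :, None])
            return (z + neg).max(axis=1)
        raise ConfigurationError(kind)

    def head_forward(self, pooled: Tensor, aug: np.ndarray | None = None) -> Tensor:
        if self.config.aug_dim:
            if aug is None:
                raise ConfigurationError("model expects an augmentation vector")
            pooled = concat([pooled, Tensor(np.atleast_2d(aug))], axis=-1)
        elif aug is not None and np.asarray(aug).size:
            raise ConfigurationError("model was built without an augmentation slot")
        h = (pooled @ self.head["w1"] + self.head["b1"]).tanh()
        return h @ self.head["w2"] + self.head["b2"]


# --------------------------------------------------------------------------- #
# Spec operations (single graph, numpy in / numpy out)
# --------------------------------------------------------------------------- #

def _graph_tensors(model: VGAEModel, graph: MolecularGraph) -> tuple:
    if graph.node_features.shape[1] != model.scheme.d:
        raise ConfigurationError(
            f"graph feature dim {graph.node_features.shape[1]} != model d {model.scheme.d}")
    m = model.config.readout.M
    x = pad_node_matrix(graph.node_features, m)
    ahat = np.zeros((m, m))
    n = graph.num_nodes
    ahat[:n, :n] = normalized_adjacency(graph.adjacency)
    mask = np.zeros(m, bool)
    mask[:n] = True
    return x, ahat, mask


def encode(graph: MolecularGraph, model: VGAEModel) -> LatentEncoding:
    """Per-node Gaussian parameters mu, log sigma of shape (num_nodes, latent_dim)."""
    x, ahat, _ = _graph_tensors(model, graph)
    mu, ls = model.encode_batch(Tensor(x[None]), Tensor(ahat[None]))
    n = graph.num_nodes
    return LatentEncoding(mu.data[0, :n], ls.data[0, :n])


def sample_latent(encoding: LatentEncoding, seed: int) -> np.ndarray:
    """Reparameterised draw Z = mu + sigma * eps, reproducible under `seed`."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(encoding.mu.shape)
    z = encoding.mu + np.exp(encoding.log_sigma) * eps
    encoding.Z = z
    return z


def decode_edge_prob(z_i: np.ndarray, z_j: np.ndarray) -> float:
    """tau(z_i^T z_j): edge probability from the inner-product decoder."""
    z_i, z_j = np.asarray(z_i, float), np.asarray(z_j, float)
    if z_i.shape != z_j.shape:
        raise ConfigurationError("latent vectors must have equal length")
    return float(1.0 / (1.0 + np.exp(-float(z_i @ z_j))))


def kl_term(encoding: LatentEncoding) -> float:
    """Closed-form KL[q || N(0, I)] summed over nodes (always >= 0)."""
    mu, ls = encoding.mu, encoding.log_sigma
    return float(0.5 * np.sum(mu ** 2 + np.exp(2 * ls) - 1.0 - 2 * ls))


def _select_pairs(adjacency: np.ndarray, neg_ratio: int, rng: np.random.Generator):
    """Upper-triangular (incl. diagonal) positives and a seeded non-edge subsample."""
    n = adjacency.shape[0]
    iu, ju = np.triu_indices(n)
    vals = adjacency[iu, ju]
    pos = np.flatnonzero(vals == 1)
    neg = np.flatnonzero(vals == 0)
    if neg_ratio > 0 and len(neg) > 0:
        k = min(len(neg), neg_ratio * len(pos))
        neg = rng.choice(neg, size=k, replace=False)
    elif neg_ratio > 0:
        neg = np.array([], dtype=int)  # no non-edges: fall back to positives only
    sel = np.concatenate([pos, np.asarray(neg, dtype=int)])
    return iu[sel], ju[sel], vals[sel]


def reconstruction_term(graph: MolecularGraph, z: np.ndarray, neg_ratio: int = 1,
                        seed: int = 0) -> float:
    """Mean log-likelihood of observed edges plus sampled non-edges (<= 0)."""
    rng = np.random.default_rng(seed)
    ii, jj, target = _select_pairs(graph.adjacency, neg_ratio, rng)
    logits = np.einsum("ij,ij->i", z[ii], z[jj])
    # stable log tau / log(1 - tau)
    ll = -(np.maximum(logits, 0) - logits * target + np.log1p(np.exp(-np.abs(logits))))
    return float(ll.mean())


def supervised_loss(graph: MolecularGraph, y: float | None, model: VGAEModel,
                    train_cfg: TrainConfig, seed: int = 0) -> tuple:
    """Joint loss of one labelled graph; returns (total, parts).

    parts = {recon, kl, sup}: recon is the negative mean edge log-likelihood,
    kl the node-summed KL divided by the node count, sup the weighted
    supervised term; they sum to the total exactly.
    """
    if y is None:
        raise LabelledDataError("supervised_loss requires a label")
    enc = encode(graph, model)
    z = sample_latent(enc, seed)
    recon = -reconstruction_term(graph, z, train_cfg.neg_ratio, seed)
    kl = kl_term(enc) / graph.num_nodes
    x, ahat, mask = _graph_tensors(model, graph)
    zpad = pad_node_matrix(z, model.config.readout.M)
    pooled = model.pool(Tensor(zpad[None]), mask[None])
    pred = model.head_forward(pooled).data.ravel()[0]
    ystd = (float(y) - model.label_mean) / model.label_std
    if model.task_type == "classification":
        p = np.clip(1 / (1 + np.exp(-pred)), 1e-12, 1 - 1e-12)
        sup = -(ystd * np.log(p) + (1 - ystd) * np.log(1 - p))
    else:
        sup = (pred - ystd) ** 2
    parts = {"recon": recon, "kl": kl, "sup": train_cfg.lambda_sup * sup}
    total = parts["recon"] + parts["kl"] + parts["sup"]
    return total, parts


def filter_outliers(values: np.ndarray, k: float = 5.0) -> np.ndarray:
    """Keep-mask: True where |v - mean| <= k * sd (population sd, single pass).

    With sd = 0 (all values equal) nothing diverges and everything is kept.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("filter_outliers requires a non-empty vector")
    sd = v.std()
    if sd == 0:
        return np.ones(v.shape, dtype=bool)
    return np.abs(v - v.mean()) <= k * sd


# --------------------------------------------------------------------------- #
# Batched training
# --------------------------------------------------------------------------- #

def _batch_arrays(model: VGAEModel, graphs: list) -> dict:
    m = model.config.readout.M
    b, d = len(graphs), model.scheme.d
    x = np.zeros((b, m, d))
    ahat = np.zeros((b, m, m))
    adj = np.zeros((b, m, m))
    mask = np.zeros((b, m), bool)
    for i, g in enumerate(graphs):
        n = g.num_nodes
        x[i, :n] = g.node_features
        ahat[i, :n, :n] = normalized_adjacency(g.adjacency)
        adj[i, :n, :n] = g.adjacency
        mask[i, :n] = True
    return {"x": x, "ahat": ahat, "adj": adj, "mask": mask,
            "counts": mask.sum(axis=1)}


def _recon_masks(batch: dict, neg_ratio: int, rng: np.random.Generator) -> tuple:
    """Per-epoch (B × M × M) selection weights and targets for edge BCE."""
    adj, mask = batch["adj"], batch["mask"]
    b, m, _ = adj.shape
    sel = np.zeros((b, m, m))
    for i in range(b):
        n = int(batch["counts"][i])
        ii, jj, _ = _select_pairs(adj[i, :n, :n], neg_ratio, rng)
        sel[i, ii, jj] = 1.0
    sel /= np.maximum(sel.sum(axis=(1, 2), keepdims=True), 1.0)
    return sel, adj


def _bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    t = Tensor(target)
    absl = logits.relu() * 2.0 - logits
    return logits.relu() - logits * t + ((-absl).exp() + 1.0).log()


def _forward_loss(model: VGAEModel, batch: dict, y_std: np.ndarray,
                  cfg: TrainConfig, rng: np.random.Generator,
                  aug: np.ndarray | None = None, sample: bool = True) -> tuple:
    x, ahat, mask = Tensor(batch["x"]), Tensor(batch["ahat"]), batch["mask"]
    mu, log_sigma = model.encode_batch(x, ahat)
    if sample:
        eps = rng.standard_normal(mu.shape) * mask[:, :, None]
        z = mu + log_sigma.exp() * Tensor(eps)
    else:
        z = mu
    counts = batch["counts"]

    sel, target = _recon_masks(batch, cfg.neg_ratio, rng)
    logits = z @ z.T
    recon = (_bce_with_logits(logits, target) * Tensor(sel)).sum(axis=(1, 2)).mean()

    kl_nodes = ((mu ** 2 + (log_sigma * 2.0).exp() - 1.0 - log_sigma * 2.0)
                * Tensor(mask[:, :, None].astype(float))).sum(axis=(1, 2)) * 0.5
    kl = (kl_nodes * Tensor(1.0 / counts)).mean()

    pooled = model.pool(z, mask)
    pred = model.head_forward(pooled, aug=aug)
    pred = pred.reshape(pred.shape[0])
    if model.task_type == "classification":
        sup = _bce_with_logits(pred, y_std).mean()
    else:
        sup = ((pred - Tensor(y_std)) ** 2).mean()

    total = recon + kl + sup * cfg.lambda_sup
    parts = {"recon": float(recon.data), "kl": float(kl.data),
             "sup": float(cfg.lambda_sup * sup.data)}
    return total, parts


def _predict_batch(model: VGAEModel, batch: dict,
                   aug: np.ndarray | None = None) -> np.ndarray:
    """Deterministic standardized-scale predictions (uses mu, no sampling)."""
    mu, _ = model.encode_batch(Tensor(batch["x"]), Tensor(batch["ahat"]))
    pooled = model.pool(mu, batch["mask"])
    out = model.head_forward(pooled, aug=aug).data.ravel()
    return out


def train_model(model: VGAEModel, graphs: list, y: np.ndarray, cfg: TrainConfig,
                aug: np.ndarray | None = None, val: tuple | None = None) -> VGAEModel:
    """Fit the supervised VGAE on labelled graphs (in place; also returned).

    `aug` is an optional (n × aug_dim) augmentation matrix concatenated to the
    pooled embedding before the prediction head.  `val` is an optional
    (graphs, y, aug) triple used for early stopping on validation MAE.
    Identical seeds give identical epoch-loss trajectories.
    """
    if not graphs:
        raise ValueError("empty training set")
    y = np.asarray(y, dtype=float)
    if model.task_type == "regression":
        model.label_mean = float(y.mean())
        model.label_std = float(y.std()) or 1.0
    y_std = ((y - model.label_mean) / model.label_std
             if model.task_type == "regression" else y)

    rng = np.random.default_rng(cfg.seed)
    model.apply_freeze()
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    batch_all = _batch_arrays(model, graphs)
    if val is not None:
        vg, vy, vaug = val
        vbatch = _batch_arrays(model, vg)
        vy = np.asarray(vy, dtype=float)
    best_val, best_state, since_best = np.inf, None, 0
    model.train_log = []
    n = len(graphs)
    bs = cfg.batch_size or n
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_parts = {"recon": 0.0, "kl": 0.0, "sup": 0.0}
        nb = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            sub = {k: (batch_all[k][idx] if k != "counts" else batch_all["counts"][idx])
                   for k in batch_all}
            total, parts = _forward_loss(model, sub, y_std[idx], cfg, rng,
                                         aug=None if aug is None else aug[idx])
            opt.zero_grad()
            total.backward()
            opt.step()
            for k in ep_parts:
                ep_parts[k] += parts[k]
            nb += 1
        rec = {"epoch": epoch, **{k: v / nb for k, v in ep_parts.items()}}
        rec["total"] = rec["recon"] + rec["kl"] + rec["sup"]
        if val is not None and cfg.patience:
            pred = _predict_batch(model, vbatch, aug=vaug)
            pred = pred * model.label_std + model.label_mean \
                if model.task_type == "regression" else pred
            vmae = float(np.abs(pred - vy).mean())
            rec["val_mae"] = vmae
            if vmae < best_val - 1e-9:
                best_val, since_best = vmae, 0
                best_state = [p.data.copy() for p in model.parameters()]
            else:
                since_best += 1
            if since_best >= cfg.patience:
                model.train_log.append(rec)
                break
        model.train_log.append(rec)
    if val is not None and cfg.patience and best_state is not None:
        for p, w in zip(model.parameters(), best_state):
            p.data = w
    return model


def train_lf_model(dataset: MultiFidelityDataset, model_cfg: VGAEConfig,
                   train_cfg: TrainConfig,
                   scheme: AtomFeaturizationScheme = DEFAULT_SCHEME,
                   graphs: dict | None = None, label_key: str | None = None) -> VGAEModel:
    """Train the low-fidelity model on the lf_train split (supervised VGAE).

    `graphs` optionally maps mol_id -> parsed MolecularGraph to avoid
    re-parsing; `label_key` selects an extra fidelity level instead of the
    primary lf_label (used for >2-fidelity cascades).
    """
    recs = dataset.subset("lf_train")
    if label_key is None:
        recs = [r for r in recs if r.lf_label is not None]
        labels = np.array([r.lf_label for r in recs], dtype=float)
    else:
        recs = [r for r in recs if r.extra_lf_labels.get(label_key) is not None]
        labels = np.array([r.extra_lf_labels[label_key] for r in recs], dtype=float)
    if not recs:
        raise ValueError("no low-fidelity training records")
    gs = [graphs[r.mol_id] if graphs else parse_smiles_to_graph(r.smiles, scheme, r.mol_id)
          for r in recs]
    model = VGAEModel(model_cfg, scheme=scheme, seed=train_cfg.seed)
    train_model(model, gs, labels, train_cfg)
    # LF-train label statistics: used later to standardise scalar augmentations
    model.aug_stats = {"lf_mean": float(labels.mean()),
                       "lf_std": float(labels.std()) or 1.0}
    return model


def predict(model: VGAEModel, graph: MolecularGraph,
            aug: np.ndarray | None = None) -> float:
    """Deterministic property prediction on the original label scale."""
    batch = _batch_arrays(model, [graph])
    out = _predict_batch(model, batch, aug=None if aug is None else np.atleast_2d(aug))
    val = float(out[0])
    if model.task_type == "regression":
        val = val * model.label_std + model.label_mean
    return val


def embed(model: VGAEModel, graph: MolecularGraph) -> np.ndarray:
    """Graph-level latent embedding psi(x): pooled vector before the head."""
    batch = _batch_arrays(model, [graph])
    mu, _ = model.encode_batch(Tensor(batch["x"]), Tensor(batch["ahat"]))
    return model.pool(mu, batch["mask"]).data[0]
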