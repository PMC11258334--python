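"""Transfer-learning strategies between fidelity levels.

Feature-augmentation maps concatenate low-fidelity information to the
high-fidelity model input (at the pooled graph embedding, immediately before
the prediction head):

* ``label``            — the raw measured low-fidelity label (transductive only)
* ``predicted_label``  — the LF model's prediction, for any molecule
* ``hybrid_label``     — raw label at train time when available, predicted
                         label at evaluation time and for unseen molecules
* ``embeddings``       — the fixed LF graph-level embedding psi_S(x),
                         concatenated with the live HF embedding psi_T(x)

Fine-tuning regimes initialise the high-fidelity model from the low-fidelity
checkpoint: ``tune_vgae`` retrains everything, ``tune_readout`` freezes the
graph-convolution stack and retrains only the adaptive readout (and head).
Scalar label augmentations are standardised with LF-train statistics before
concatenation to avoid scale pathologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .molgraph import (ConfigurationError, MolecularGraph, MultiFidelityDataset,
                       MultiFidelityRecord, parse_smiles_to_graph)
from .vgae import (TrainConfig, VGAEConfig, VGAEModel, embed, predict,
                   train_model)

STRATEGIES = ("none", "label", "predicted_label", "hybrid_label",
              "embeddings", "tune_vgae", "tune_readout")

AUGMENTATION_STRATEGIES = ("label", "predicted_label", "hybrid_label", "embeddings")


class TransductiveViolationError(ValueError):
    """The raw-label map was applied to a molecule without a low-fidelity label."""


class StrategyError(ValueError):
    """Strategy/dataset or strategy/model incompatibility."""


@dataclass
class Strategy:
    name: str = "none"
    lf_models: list = field(default_factory=list)

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise StrategyError(f"unknown strategy {self.name!r}")
        if self.name in ("tune_vgae", "tune_readout") and len(self.lf_models) != 1:
            raise StrategyError(f"{self.name} requires exactly one LF checkpoint")
        if self.name in ("predicted_label", "hybrid_label", "embeddings") \
                and not self.lf_models:
            raise StrategyError(f"{self.name} requires at least one LF checkpoint")


@dataclass
class AugmentedInput:
    mol_id: str
    vector: np.ndarray
    provenance: list  # per element: raw_label | predicted_label | embedding

    def __post_init__(self):
        self.vector = np.atleast_1d(np.asarray(self.vector, dtype=float))


def _lf_stats(lf_model: VGAEModel | None, dataset: MultiFidelityDataset | None):
    """LF-train label mean/std used to standardise scalar augmentations."""
    if lf_model is not None and lf_model.aug_stats:
        return lf_model.aug_stats["lf_mean"], lf_model.aug_stats["lf_std"]
    if dataset is not None:
        vals = [r.lf_label for r in dataset.subset("lf_train") if r.lf_label is not None]
        if vals:
            v = np.asarray(vals, float)
            return float(v.mean()), float(v.std()) or 1.0
    return 0.0, 1.0


# --------------------------------------------------------------------------- #
# Feature-augmentation maps
# --------------------------------------------------------------------------- #

def psi_label(x: MultiFidelityRecord, stats: tuple = (0.0, 1.0)) -> AugmentedInput:
    """Raw low-fidelity label augmentation (transductive setting only)."""
    if x.lf_label is None:
        raise TransductiveViolationError(
            f"record {x.mol_id!r} has no low-fidelity label; the raw-label map "
            "is restricted to the transductive setting")
    mean, std = stats
    return AugmentedInput(x.mol_id, [(x.lf_label - mean) / std], ["raw_label"])


def psi_predicted(x: MultiFidelityRecord, lf_model: VGAEModel,
                  graph: MolecularGraph | None = None) -> AugmentedInput:
    """Predicted low-fidelity label augmentation (works for any molecule)."""
    g = graph if graph is not None else parse_smiles_to_graph(x.smiles, lf_model.scheme,
                                                              x.mol_id)
    mean, std = _lf_stats(lf_model, None)
    val = (predict(lf_model, g) - mean) / std
    return AugmentedInput(x.mol_id, [val], ["predicted_label"])


def psi_hybrid(x: MultiFidelityRecord, lf_model: VGAEModel, mode: str = "train",
               graph: MolecularGraph | None = None) -> AugmentedInput:
    """Raw label when available at train time, LF-predicted label otherwise."""
    if mode not in ("train", "eval"):
        raise ConfigurationError(f"unknown hybrid mode {mode!r}")
    if mode == "train" and x.lf_label is not None:
        return psi_label(x, stats=_lf_stats(lf_model, None))
    return psi_predicted(x, lf_model, graph=graph)


def psi_embeddings(x: MultiFidelityRecord, lf_model: VGAEModel,
                   graph: MolecularGraph | None = None) -> AugmentedInput:
    """Fixed LF graph-level embedding psi_S(x) (the HF model later concatenates
    it with its own live embedding psi_T(x) before the prediction head)."""
    g = graph if graph is not None else parse_smiles_to_graph(x.smiles, lf_model.scheme,
                                                              x.mol_id)
    vec = embed(lf_model, g)
    return AugmentedInput(x.mol_id, vec, ["embedding"] * vec.size)


def multi_fidelity_augment(x: MultiFidelityRecord, lf_models: list, mode: str,
                           fidelity_names: list | None = None,
                           dataset: MultiFidelityDataset | None = None,
                           graph: MolecularGraph | None = None) -> AugmentedInput:
    """Concatenate each lower-fidelity model's label or embedding in fidelity order."""
    if mode not in ("labels", "embeddings"):
        raise ConfigurationError(f"unknown multi-fidelity mode {mode!r}")
    if dataset is not None and fidelity_names is not None:
        expected = list(dataset.fidelity_names[:len(lf_models)])
        if list(fidelity_names) != expected:
            raise StrategyError(
                f"fidelity ordering {list(fidelity_names)} does not match the "
                f"dataset's {expected}")
    pieces, prov = [], []
    for m in lf_models:
        part = (psi_predicted(x, m, graph=graph) if mode == "labels"
                else psi_embeddings(x, m, graph=graph))
        pieces.append(part.vector)
        prov.extend(part.provenance)
    return AugmentedInput(x.mol_id, np.concatenate(pieces), prov)


# --------------------------------------------------------------------------- #
# Freezing and fine-tuning
# --------------------------------------------------------------------------- #

def freeze_components(model: VGAEModel, which) -> VGAEModel:
    """Freeze the named components; frozen parameters stay bit-identical
    through any subsequent training step (gradients disabled)."""
    which = set(which)
    unknown = which - set(model.freeze_flags)
    if unknown:
        raise ConfigurationError(f"unknown component(s): {sorted(unknown)}")
    for c in model.freeze_flags:
        model.freeze_flags[c] = c in which
    model.apply_freeze()
    return model


def fine_tune(lf_model: VGAEModel, hf_dataset: MultiFidelityDataset, regime: str,
              train_cfg: TrainConfig, graphs: dict | None = None) -> VGAEModel:
    """Pre-train/fine-tune transfer: initialise from the LF checkpoint.

    ``tune_vgae``: all weights start from the LF model, nothing frozen.
    ``tune_readout``: the GCN stack is frozen; the adaptive readout and the
    prediction head remain trainable (requires an adaptive-readout LF model).
    """
    if regime not in ("tune_vgae", "tune_readout"):
        raise StrategyError(f"unknown fine-tuning regime {regime!r}")
    if regime == "tune_readout" and lf_model.config.readout.kind != "set_transformer":
        raise StrategyError("tune_readout requires an adaptive (Set Transformer) "
                            "readout; a fixed pooling has nothing to tune")
    model = lf_model.copy()
    model.parent_hash = lf_model.weights_hash()
    model.regime = regime
    freeze_components(model, {"gcn"} if regime == "tune_readout" else set())
    recs = [r for r in hf_dataset.subset("hf_train") if r.hf_label is not None]
    if not recs:
        raise ValueError("no high-fidelity training records")
    gs = [graphs[r.mol_id] if graphs else
          parse_smiles_to_graph(r.smiles, model.scheme, r.mol_id) for r in recs]
    y = np.array([r.hf_label for r in recs], dtype=float)
    val = None
    vrecs = [r for r in hf_dataset.subset("hf_val") if r.hf_label is not None]
    if vrecs and train_cfg.patience:
        vgs = [graphs[r.mol_id] if graphs else
               parse_smiles_to_graph(r.smiles, model.scheme, r.mol_id) for r in vrecs]
        val = (vgs, np.array([r.hf_label for r in vrecs], dtype=float), None)
    if train_cfg.epochs > 0:
        train_model(model, gs, y, train_cfg, val=val)
    return model


# --------------------------------------------------------------------------- #
# High-fidelity training across strategies
# --------------------------------------------------------------------------- #

def _records_for(dataset: MultiFidelityDataset, split: str):
    want_label = split != "no_lf_test"
    recs = dataset.subset(split)
    return [r for r in recs if (r.hf_label is not None or not want_label)]


def build_augmentations(dataset: MultiFidelityDataset, strategy: Strategy,
                        splits: list, graphs: dict | None = None) -> dict:
    """Per-split augmentation matrices for an augmentation strategy.

    Returns ``{split: (records, aug_matrix | None)}``.  The hybrid map uses raw
    labels only on the training split; validation/test use predicted labels.
    """
    g_of = (lambda r: graphs[r.mol_id]) if graphs else \
        (lambda r: parse_smiles_to_graph(r.smiles, mol_id=r.mol_id))
    out = {}
    for split in splits:
        recs = _records_for(dataset, split)
        if strategy.name == "none" or not recs:
            out[split] = (recs, None)
            continue
        rows = []
        for r in recs:
            if strategy.name == "label":
                rows.append(psi_label(r, stats=_lf_stats(
                    strategy.lf_models[0] if strategy.lf_models else None,
                    dataset)).vector)
            elif strategy.name == "predicted_label":
                if len(strategy.lf_models) > 1:
                    rows.append(multi_fidelity_augment(
                        r, strategy.lf_models, "labels", graph=g_of(r)).vector)
                else:
                    rows.append(psi_predicted(r, strategy.lf_models[0],
                                              graph=g_of(r)).vector)
            elif strategy.name == "hybrid_label":
                mode = "train" if split == "hf_train" else "eval"
                rows.append(psi_hybrid(r, strategy.lf_models[0], mode=mode,
                                       graph=g_of(r)).vector)
            elif strategy.name == "embeddings":
                if len(strategy.lf_models) > 1:
                    rows.append(multi_fidelity_augment(
                        r, strategy.lf_models, "embeddings", graph=g_of(r)).vector)
                else:
                    rows.append(psi_embeddings(r, strategy.lf_models[0],
                                               graph=g_of(r)).vector)
            else:
                raise StrategyError(strategy.name)
        out[split] = (recs, np.vstack(rows))
    return out


def train_hf_model(hf_dataset: MultiFidelityDataset, strategy: Strategy,
                   model_cfg: VGAEConfig, train_cfg: TrainConfig,
                   graphs: dict | None = None) -> tuple:
    """Train a high-fidelity model under one transfer strategy.

    Returns ``(model, metrics)`` where metrics maps each evaluated split
    (hf_val, hf_test, and no_lf_test when present and reachable) to the
    standard metric set.
    """
    from .pipeline import compute_metrics  # local import avoids a cycle

    eval_splits = ["hf_val", "hf_test"]
    if hf_dataset.subset("no_lf_test"):
        eval_splits.append("no_lf_test")

    if strategy.name in ("tune_vgae", "tune_readout"):
        model = fine_tune(strategy.lf_models[0], hf_dataset, strategy.name,
                          train_cfg, graphs=graphs)
        augs = {s: (_records_for(hf_dataset, s), None) for s in eval_splits}
    else:
        augs = build_augmentations(hf_dataset, strategy,
                                   ["hf_train"] + eval_splits, graphs=graphs)
        recs, aug_train = augs["hf_train"]
        if not recs:
            raise ValueError("no high-fidelity training records")
        cfg = VGAEConfig(**{**model_cfg.to_dict(), "readout": model_cfg.readout})
        cfg.aug_dim = 0 if aug_train is None else aug_train.shape[1]
        model = VGAEModel(cfg, seed=train_cfg.seed)
        if strategy.name in ("label", "predicted_label", "hybrid_label"):
            mean, std = _lf_stats(
                strategy.lf_models[0] if strategy.lf_models else None, hf_dataset)
            model.aug_stats = {"lf_mean": mean, "lf_std": std}
        g_of = (lambda r: graphs[r.mol_id]) if graphs else \
            (lambda r: parse_smiles_to_graph(r.smiles, mol_id=r.mol_id))
        gs = [g_of(r) for r in recs]
        y = np.array([r.hf_label for r in recs], dtype=float)
        val = None
        if train_cfg.patience and augs.get("hf_val", ([], None))[0]:
            vrecs, vaug = augs["hf_val"]
            val = ([g_of(r) for r in vrecs],
                   np.array([r.hf_label for r in vrecs], dtype=float), vaug)
        train_model(model, gs, y, train_cfg, aug=aug_train, val=val)

    metrics = {}
    g_of = (lambda r: graphs[r.mol_id]) if graphs else \
        (lambda r: parse_smiles_to_graph(r.smiles, mol_id=r.mol_id))
    for split in eval_splits:
        recs, aug = augs.get(split, (_records_for(hf_dataset, split), None))
        recs = [r for r in recs if r.hf_label is not None]
        if len(recs) < 2:
            continue
        if aug is not None and aug.shape[0] != len(recs):
            keep = [i for i, r in enumerate(augs[split][0]) if r.hf_label is not None]
            aug = aug[keep]
        preds = np.array([predict(model, g_of(r),
                                  aug=None if aug is None else aug[i])
                          for i, r in enumerate(recs)])
        y = np.array([r.hf_label for r in recs], dtype=float)
        metrics[split] = compute_metrics(y, preds, hf_dataset.task_type)
    return model, metrics


# --------------------------------------------------------------------------- #
# Diagnostics and classical baselines
# --------------------------------------------------------------------------- #

def simulate_label_sweep(hf_model: VGAEModel, graph: MolecularGraph,
                         lo: float = -50.0, hi: float = 50.0,
                         step: float = 0.5) -> pd.DataFrame:
    """Predictions while sweeping the scalar label slot over [lo, hi].

    Requires a model trained with a scalar label augmentation (aug_dim == 1).
    The returned table is ordered by supplied label and carries the Spearman
    monotonicity statistic in ``df.attrs['spearman_rho']``.
    """
    if hf_model.config.aug_dim != 1:
        raise StrategyError("label sweep needs a model with a scalar label slot "
                            f"(aug_dim == 1, got {hf_model.config.aug_dim})")
    mean = hf_model.aug_stats.get("lf_mean", 0.0)
    std = hf_model.aug_stats.get("lf_std", 1.0)
    values = np.arange(lo, hi + step / 2, step)
    preds = [predict(hf_model, graph, aug=np.array([(v - mean) / std]))
             for v in values]
    df = pd.DataFrame({"supplied_label": values, "prediction": preds})
    rho = spearmanr(df["supplied_label"], df["prediction"]).statistic
    df.attrs["spearman_rho"] = float(0.0 if np.isnan(rho) else rho)
    return df


def train_downstream_baseline(features, labels, kind: str = "random_forest",
                              task_type: str = "regression", seed: int = 0,
                              test: tuple | None = None) -> tuple:
    """Fit an off-the-shelf learner on a tabular (fingerprint/augmented)
    representation; returns (model, metrics) with the usual metric set."""
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
    from sklearn.linear_model import LinearRegression, LogisticRegression
    from sklearn.svm import SVC, SVR

    from .pipeline import compute_metrics

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows vs {y.shape[0]} labels")
    reg = task_type == "regression"
    makers = {
        "random_forest": lambda: (RandomForestRegressor if reg else
                                  RandomForestClassifier)(
                                      n_estimators=100, random_state=seed),
        "svm": lambda: SVR() if reg else SVC(probability=True, random_state=seed),
        "linear": lambda: LinearRegression() if reg else
        LogisticRegression(max_iter=1000, random_state=seed),
    }
    if kind not in makers:
        raise ConfigurationError(f"unknown baseline kind {kind!r}")
    est = makers[kind]()
    est.fit(X, y)
    Xe, ye = test if test is not None else (X, y)
    Xe = np.asarray(Xe, dtype=float)
    ye = np.asarray(ye, dtype=float)
    if reg:
        pred = est.predict(Xe)
    else:
        pred = est.predict_proba(Xe)[:, 1]
    return est, compute_metrics(ye, pred, task_type)
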