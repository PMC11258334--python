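"""Experiment orchestration: metrics, strategy comparisons and reports.

Runs low-fidelity pre-training once per readout kind, then every requested
transfer strategy over the requested seeds (and, optionally, nested training
sizes), collecting MAE / R² / Pearson r (AUROC / MCC for classification)
per split, the "% MAE decrease" ranking statistic against the non-augmented
baseline, and the uplift-vs-correlation regression.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .molgraph import MultiFidelityDataset
from .readouts import ReadoutConfig
from .synthetic import SyntheticConfig, generate_dataset, vary_train_size_subsets
from .transfer import STRATEGIES, Strategy, train_hf_model
from .vgae import TrainConfig, VGAEConfig, VGAEModel, train_lf_model

UNDEFINED = float("nan")


# --------------------------------------------------------------------------- #
# Metrics
# --------------------------------------------------------------------------- #

def compute_metrics(y_true, y_pred, task_type: str = "regression") -> dict:
    """Standard metric set; constant-target R² is flagged, never a crash.

    Regression: MAE, R², Pearson r.  Classification (scores in y_pred):
    AUROC and MCC at the 0.5 threshold, plus MAE of the scores.
    """
    from sklearn.metrics import (matthews_corrcoef, mean_absolute_error,
                                 r2_score, roc_auc_score)

    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least two observations")
    out = {"mae": float(mean_absolute_error(y_true, y_pred))}
    if task_type == "regression":
        if np.ptp(y_true) == 0:
            out["r2"] = UNDEFINED
            out["undefined_metrics"] = ["r2"]
        else:
            out["r2"] = float(r2_score(y_true, y_pred))
        if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
            out["pearson_r"] = UNDEFINED
        else:
            out["pearson_r"] = float(np.corrcoef(y_true, y_pred)[0, 1])
    else:
        labels = y_true.astype(int)
        hard = (y_pred >= 0.5).astype(int)
        out["mcc"] = float(matthews_corrcoef(labels, hard))
        if len(np.unique(labels)) < 2:
            out["auroc"] = UNDEFINED
            out["undefined_metrics"] = ["auroc"]
        else:
            out["auroc"] = float(roc_auc_score(labels, y_pred))
    return out


def compute_mae_decrease(mae_baseline: float, mae_strategy: float) -> float:
    """% MAE decrease = 100 · (baseline − strategy) / baseline.

    Negative when the strategy hurts; NaN (undefined) for a zero baseline.
    """
    if mae_baseline == 0:
        return UNDEFINED
    return 100.0 * (mae_baseline - mae_strategy) / mae_baseline


def correlation_uplift_analysis(points) -> dict:
    """OLS of uplift (% MAE decrease) on LF/HF label correlation.

    `points` is an iterable of (r, uplift) pairs (≥ 3 required).  Returns the
    slope, intercept, Pearson r of the relationship and a 95% confidence
    interval on the slope.
    """
    pts = [(float(r), float(u)) for r, u in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 (correlation, uplift) points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    res = sps.linregress(x, y)
    tcrit = sps.t.ppf(0.975, len(pts) - 2)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "pearson_r": float(res.rvalue),
        "slope_ci95": (float(res.slope - tcrit * res.stderr),
                       float(res.slope + tcrit * res.stderr)),
        "n": len(pts),
    }


# --------------------------------------------------------------------------- #
# Experiment configuration and report
# --------------------------------------------------------------------------- #

def _parse_strategy_spec(spec: str) -> tuple:
    """'embeddings@sum' -> ('embeddings', 'sum'); default LF readout is neural."""
    name, _, ro = spec.partition("@")
    if name not in STRATEGIES:
        raise ValueError(f"unknown strategy {name!r}")
    if ro == "":
        ro = "sum" if name == "tune_vgae" else "set_transformer"
    if ro == "neural":
        ro = "set_transformer"
    return name, ro


@dataclass
class ExperimentConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    strategies: tuple = ("none", "label", "embeddings")
    seeds: tuple = (0, 1, 2)
    model: VGAEConfig = field(default_factory=VGAEConfig)
    lf_train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=40, batch_size=256))
    hf_train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=150, patience=30))
    checkpoint_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps({
            "synthetic": asdict(self.synthetic),
            "strategies": list(self.strategies),
            "seeds": list(self.seeds),
            "model": self.model.to_dict(),
            "lf_train": self.lf_train.to_dict(),
            "hf_train": self.hf_train.to_dict(),
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    table: pd.DataFrame
    config_hash: str = ""
    checkpoint_hashes: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "config_hash": self.config_hash,
            "checkpoint_hashes": self.checkpoint_hashes,
            "rows": self.table.sort_values(
                list(self.table.columns[:5])).to_dict(orient="records"),
        }
        text = json.dumps(payload, sort_keys=True, indent=1, default=float)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def median_uplift(self, strategy: str, split: str = "hf_test",
                      lf_readout: str | None = None) -> float:
        t = self.table
        sel = (t["strategy"] == strategy) & (t["split"] == split)
        if lf_readout:
            sel &= t["lf_readout"] == lf_readout
        return float(t[sel]["pct_mae_decrease"].median())

    def best_strategy_tally(self, split: str = "hf_test") -> dict:
        """Per-seed winner by % MAE decrease; exact ties break toward the
        strategy listed earliest in the canonical ordering."""
        order = {s: i for i, s in enumerate(STRATEGIES)}
        t = self.table[(self.table["split"] == split)
                       & (self.table["strategy"] != "none")]
        tally: dict = {}
        for seed, grp in t.groupby("seed"):
            best = grp.loc[grp["pct_mae_decrease"].idxmax()]
            ties = grp[grp["pct_mae_decrease"] == best["pct_mae_decrease"]]
            winner = min(ties["strategy"], key=lambda s: order[s])
            tally[winner] = tally.get(winner, 0) + 1
        return tally


# --------------------------------------------------------------------------- #
# Orchestration
# --------------------------------------------------------------------------- #

def _lf_model_for(cfg: ExperimentConfig, dataset, graphs, readout_kind: str,
                  seed: int, cache: dict) -> VGAEModel:
    key = (readout_kind, seed)
    if key in cache:
        return cache[key]
    path = None
    if cfg.checkpoint_dir:
        os.makedirs(cfg.checkpoint_dir, exist_ok=True)
        path = os.path.join(cfg.checkpoint_dir,
                            f"lf_{readout_kind}_{seed}_{cfg.config_hash()}.json")
        if os.path.exists(path):
            cache[key] = VGAEModel.load(path)
            return cache[key]
    ro = ReadoutConfig(**{**cfg.model.readout.to_dict(), "kind": readout_kind})
    mcfg = VGAEConfig(**{**cfg.model.to_dict(), "readout": ro})
    tcfg = TrainConfig(**{**cfg.lf_train.to_dict(), "seed": seed})
    model = train_lf_model(dataset, mcfg, tcfg, graphs=graphs)
    if path:
        model.save(path)
    cache[key] = model
    return model


def _strategy_rows(cfg: ExperimentConfig, dataset, graphs, seed: int,
                   cache: dict, hf_ids: list | None = None,
                   train_size: int | None = None) -> list:
    """Run every configured strategy once for one seed; returns report rows."""
    if hf_ids is not None:
        keep = set(hf_ids)
        recs = [r if (r.split != "hf_train" or r.mol_id in keep) else
                type(r)(r.mol_id, r.smiles, r.lf_label, r.hf_label, "lf_train",
                        dict(r.extra_lf_labels))
                for r in dataset.records]
        dataset = dataset.replace_records(recs)
    rows = []
    for spec in cfg.strategies:
        name, ro_kind = _parse_strategy_spec(spec)
        lf_models = []
        if name in ("predicted_label", "hybrid_label", "embeddings",
                    "tune_vgae", "tune_readout"):
            lf_models = [_lf_model_for(cfg, dataset, graphs, ro_kind, seed, cache)]
        strategy = Strategy(name, lf_models)
        hf_ro = cfg.model.readout
        if name in ("tune_vgae", "tune_readout"):
            hf_ro = lf_models[0].config.readout
        mcfg = VGAEConfig(**{**cfg.model.to_dict(), "readout": hf_ro})
        tcfg = TrainConfig(**{**cfg.hf_train.to_dict(), "seed": seed})
        model, metrics = train_hf_model(dataset, strategy, mcfg, tcfg, graphs=graphs)
        for split, m in metrics.items():
            rows.append({"strategy": name, "lf_readout": ro_kind, "split": split,
                         "train_size": train_size or len(dataset.subset("hf_train")),
                         "seed": seed, **m,
                         "checkpoint": model.weights_hash()})
    return rows


def _attach_uplift(df: pd.DataFrame) -> pd.DataFrame:
    base = df[df["strategy"] == "none"].set_index(["split", "train_size", "seed"])
    vals = []
    for _, row in df.iterrows():
        key = (row["split"], row["train_size"], row["seed"])
        if row["strategy"] == "none" or key not in base.index:
            vals.append(0.0 if row["strategy"] == "none" else UNDEFINED)
        else:
            vals.append(compute_mae_decrease(base.loc[key, "mae"], row["mae"]))
    df = df.copy()
    df["pct_mae_decrease"] = vals
    return df


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Generate data, pre-train LF models per readout kind, run all strategies
    over all seeds, and assemble the comparative report."""
    rows = []
    checkpoints = {}
    for seed in cfg.seeds:
        scfg = SyntheticConfig(**{**asdict(cfg.synthetic), "seed": seed})
        dataset, _, graphs = generate_dataset(scfg)
        cache: dict = {}
        rows.extend(_strategy_rows(cfg, dataset, graphs, seed, cache))
        checkpoints.update({f"lf_{k[0]}_{k[1]}": m.weights_hash()
                            for k, m in cache.items()})
    df = _attach_uplift(pd.DataFrame(rows))
    return ExperimentReport(df, cfg.config_hash(), checkpoints)


def vary_train_size_experiment(cfg: ExperimentConfig, sizes) -> ExperimentReport:
    """One report row per (size, strategy, seed) with fixed val/test sets."""
    rows = []
    for seed in cfg.seeds:
        scfg = SyntheticConfig(**{**asdict(cfg.synthetic), "seed": seed})
        dataset, _, graphs = generate_dataset(scfg)
        subsets = vary_train_size_subsets(dataset, sizes, seed=seed)
        cache: dict = {}
        for size, ids in zip(sizes, subsets):
            rows.extend(_strategy_rows(cfg, dataset, graphs, seed, cache,
                                       hf_ids=ids, train_size=size))
    df = _attach_uplift(pd.DataFrame(rows))
    return ExperimentReport(df, cfg.config_hash())
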