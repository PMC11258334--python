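"""Shared fixtures: small synthetic worlds and pre-trained tiny models.

Everything is generated programmatically at test time; session-scoped
fixtures cache the expensive trained models so multiple tests can share them.
"""

import numpy as np
import pytest

from mfgnn import (ReadoutConfig, SyntheticConfig, TrainConfig, VGAEConfig,
                   generate_dataset, parse_smiles_to_graph, train_lf_model)

SMILES_FIXTURES = [
    "CCO", "C1CC1", "c1ccccc1", "CC(=O)O", "CCN(CC)CC", "C1CCNCC1",
    "CC(C)Cc1ccc(C)cc1", "OCC(O)CO", "ClCCl", "CSC", "N#Cc1ccccc1",
    "CC(N)C(=O)O", "c1ccncc1", "CC1=CC(=O)CC(C)(C)C1", "FC(F)(F)c1ccccc1",
]


@pytest.fixture(scope="session")
def tiny_readout_config():
    return ReadoutConfig(kind="set_transformer", K=2, n=1, m=1,
                         hidden_dim=16, out_dim=8, M=20)


@pytest.fixture(scope="session")
def tiny_model_config(tiny_readout_config):
    return VGAEConfig(latent_dim=8, gcn_hidden=16, head_hidden=16,
                      readout=tiny_readout_config)


@pytest.fixture(scope="session")
def small_world():
    """A small multi-fidelity world with an inductive slice."""
    cfg = SyntheticConfig(n_lf=200, n_hf=80, target_r=0.9, seed=7,
                          max_atoms=16, inductive_frac=0.15)
    dataset, gt, graphs = generate_dataset(cfg)
    return {"cfg": cfg, "dataset": dataset, "gt": gt, "graphs": graphs}


@pytest.fixture(scope="session")
def trained_lf_model(small_world, tiny_model_config):
    return train_lf_model(small_world["dataset"], tiny_model_config,
                          TrainConfig(epochs=30, batch_size=64, seed=0),
                          graphs=small_world["graphs"])


@pytest.fixture(scope="session")
def trained_lf_sum_model(small_world, tiny_model_config):
    cfg = VGAEConfig(**{**tiny_model_config.to_dict(),
                        "readout": ReadoutConfig(kind="sum", M=20)})
    return train_lf_model(small_world["dataset"], cfg,
                          TrainConfig(epochs=30, batch_size=64, seed=0),
                          graphs=small_world["graphs"])


@pytest.fixture(scope="session")
def fixture_graphs():
    return [parse_smiles_to_graph(s) for s in SMILES_FIXTURES]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
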