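"""Transfer strategies: augmentation maps, freeze contracts, fine-tuning."""

import numpy as np
import pytest

from mfgnn import (MultiFidelityRecord, ReadoutConfig, Strategy, TrainConfig,
                   VGAEConfig, fine_tune, freeze_components,
                   multi_fidelity_augment, parse_smiles_to_graph, predict,
                   psi_embeddings, psi_hybrid, psi_label, psi_predicted,
                   simulate_label_sweep, train_downstream_baseline,
                   train_hf_model, train_model)
from mfgnn.molgraph import ConfigurationError
from mfgnn.transfer import (StrategyError, TransductiveViolationError,
                            _lf_stats)


def _rec(mol_id="r1", smiles="CCO", lf=1.5, hf=2.0, split="hf_train"):
    return MultiFidelityRecord(mol_id, smiles, lf, hf, split)


class TestPsiMaps:
    def test_label_concatenation(self):
        out = psi_label(_rec(lf=3.5))
        np.testing.assert_array_equal(out.vector, [3.5])
        assert out.provenance == ["raw_label"]

    def test_label_standardisation(self):
        out = psi_label(_rec(lf=3.5), stats=(1.5, 2.0))
        np.testing.assert_allclose(out.vector, [1.0])

    def test_label_requires_lf_label(self):
        rec = MultiFidelityRecord("x", "CC", lf_label=None, hf_label=1.0,
                                  split="no_lf_test")
        with pytest.raises(TransductiveViolationError):
            psi_label(rec)

    def test_predicted_works_without_lf_label(self, trained_lf_model):
        rec = MultiFidelityRecord("x", "CCN", lf_label=None, hf_label=1.0,
                                  split="no_lf_test")
        out = psi_predicted(rec, trained_lf_model)
        assert out.vector.shape == (1,)
        assert out.provenance == ["predicted_label"]

    def test_predicted_deterministic(self, trained_lf_model):
        rec = _rec()
        a = psi_predicted(rec, trained_lf_model).vector
        b = psi_predicted(rec, trained_lf_model).vector
        np.testing.assert_array_equal(a, b)

    def test_predicted_close_to_label_on_trained_molecule(self, trained_lf_model,
                                                          small_world):
        """Model-quality probe: |f̃_S(x) − lf_label| is finite on LF data."""
        r = small_world["dataset"].subset("lf_train")[0]
        out = psi_predicted(r, trained_lf_model, graph=small_world["graphs"][r.mol_id])
        assert np.isfinite(out.vector).all()

    def test_hybrid_equals_label_in_domain_at_train(self, trained_lf_model):
        rec = _rec(lf=0.7)
        stats = _lf_stats(trained_lf_model, None)
        np.testing.assert_array_equal(
            psi_hybrid(rec, trained_lf_model, "train").vector,
            psi_label(rec, stats=stats).vector)

    def test_hybrid_equals_predicted_out_of_domain(self, trained_lf_model):
        rec = MultiFidelityRecord("x", "CCN", lf_label=None, hf_label=1.0,
                                  split="no_lf_test")
        for mode in ("train", "eval"):
            np.testing.assert_array_equal(
                psi_hybrid(rec, trained_lf_model, mode).vector,
                psi_predicted(rec, trained_lf_model).vector)

    def test_hybrid_in_domain_at_eval_uses_prediction(self, trained_lf_model):
        rec = _rec(lf=0.7)
        np.testing.assert_array_equal(
            psi_hybrid(rec, trained_lf_model, "eval").vector,
            psi_predicted(rec, trained_lf_model).vector)

    def test_embeddings_shape_and_fixedness(self, trained_lf_model):
        rec = _rec()
        out1 = psi_embeddings(rec, trained_lf_model)
        out2 = psi_embeddings(rec, trained_lf_model)
        assert out1.vector.shape == (trained_lf_model.config.readout.out_dim,)
        assert set(out1.provenance) == {"embedding"}
        np.testing.assert_array_equal(out1.vector, out2.vector)


class TestMultiFidelity:
    def test_two_models_concatenate_in_order(self, trained_lf_model,
                                             trained_lf_sum_model):
        rec = _rec()
        out = multi_fidelity_augment(rec, [trained_lf_model, trained_lf_sum_model],
                                     "embeddings")
        d1 = trained_lf_model.config.readout.out_dim
        d2 = trained_lf_sum_model.config.latent_dim
        assert out.vector.shape == (d1 + d2,)
        np.testing.assert_array_equal(out.vector[:d1],
                                      psi_embeddings(rec, trained_lf_model).vector)

    def test_single_model_degenerates_to_plain_map(self, trained_lf_model):
        rec = _rec()
        np.testing.assert_array_equal(
            multi_fidelity_augment(rec, [trained_lf_model], "embeddings").vector,
            psi_embeddings(rec, trained_lf_model).vector)
        np.testing.assert_array_equal(
            multi_fidelity_augment(rec, [trained_lf_model], "labels").vector,
            psi_predicted(rec, trained_lf_model).vector)

    def test_ordering_mismatch_raises(self, trained_lf_model, small_world):
        with pytest.raises(StrategyError):
            multi_fidelity_augment(_rec(), [trained_lf_model], "labels",
                                   fidelity_names=["hf"],
                                   dataset=small_world["dataset"])


class TestFreeze:
    def test_freeze_gcn_only_gcn_unchanged(self, small_world, tiny_model_config):
        from mfgnn import VGAEModel
        model = VGAEModel(tiny_model_config, seed=3)
        freeze_components(model, {"gcn"})
        before_gcn = [p.data.copy() for p in model.component_params("gcn")]
        before_ro = [p.data.copy() for p in model.component_params("readout")]
        recs = small_world["dataset"].subset("lf_train")[:40]
        gs = [small_world["graphs"][r.mol_id] for r in recs]
        y = np.array([r.lf_label for r in recs])
        train_model(model, gs, y, TrainConfig(epochs=2, seed=0))
        for p, b in zip(model.component_params("gcn"), before_gcn):
            np.testing.assert_array_equal(p.data, b)
        assert any(not np.array_equal(p.data, b)
                   for p, b in zip(model.component_params("readout"), before_ro))

    def test_total_freeze_is_parameter_noop(self, small_world, tiny_model_config):
        from mfgnn import VGAEModel
        model = VGAEModel(tiny_model_config, seed=4)
        freeze_components(model, {"gcn", "readout", "head"})
        before = [p.data.copy() for p in model.parameters()]
        recs = small_world["dataset"].subset("lf_train")[:40]
        gs = [small_world["graphs"][r.mol_id] for r in recs]
        y = np.array([r.lf_label for r in recs])
        lm, ls = model.label_mean, model.label_std
        train_model(model, gs, y, TrainConfig(epochs=2, seed=0))
        for p, b in zip(model.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_unknown_component_rejected(self, tiny_model_config):
        from mfgnn import VGAEModel
        with pytest.raises(ConfigurationError):
            freeze_components(VGAEModel(tiny_model_config), {"decoder"})


class TestFineTune:
    def test_tune_readout_gcn_bit_identical(self, trained_lf_model, small_world):
        before = [p.data.copy() for p in trained_lf_model.component_params("gcn")]
        tuned = fine_tune(trained_lf_model, small_world["dataset"], "tune_readout",
                          TrainConfig(epochs=3, seed=0),
                          graphs=small_world["graphs"])
        for p, b in zip(tuned.component_params("gcn"), before):
            np.testing.assert_array_equal(p.data, b)
        assert tuned.regime == "tune_readout"
        assert tuned.parent_hash == trained_lf_model.weights_hash()

    def test_tune_vgae_zero_epochs_identity(self, trained_lf_model, small_world):
        tuned = fine_tune(trained_lf_model, small_world["dataset"], "tune_vgae",
                          TrainConfig(epochs=0, seed=0),
                          graphs=small_world["graphs"])
        for p, b in zip(tuned.parameters(), trained_lf_model.parameters()):
            np.testing.assert_array_equal(p.data, b.data)

    def test_tune_readout_requires_adaptive(self, trained_lf_sum_model, small_world):
        with pytest.raises(StrategyError):
            fine_tune(trained_lf_sum_model, small_world["dataset"], "tune_readout",
                      TrainConfig(epochs=1))


class TestStrategyContracts:
    def test_strategy_validation(self, trained_lf_model):
        with pytest.raises(StrategyError):
            Strategy("tune_vgae", [])
        with pytest.raises(StrategyError):
            Strategy("embeddings", [])
        with pytest.raises(StrategyError):
            Strategy("not_a_strategy")
        Strategy("label")  # raw labels need no checkpoint

    def test_inductive_reachability(self, small_world, tiny_model_config,
                                    trained_lf_model):
        """Inductive-capable strategies all produce no_lf_test metrics."""
        cfg = TrainConfig(epochs=4, seed=0)
        for name in ("none", "predicted_label", "hybrid_label", "embeddings"):
            strat = Strategy(name, [] if name == "none" else [trained_lf_model])
            _, metrics = train_hf_model(small_world["dataset"], strat,
                                        tiny_model_config, cfg,
                                        graphs=small_world["graphs"])
            assert "no_lf_test" in metrics, name

    def test_label_strategy_rejects_no_lf_records(self, small_world,
                                                  tiny_model_config):
        with pytest.raises(TransductiveViolationError):
            train_hf_model(small_world["dataset"], Strategy("label"),
                           tiny_model_config, TrainConfig(epochs=1),
                           graphs=small_world["graphs"])


@pytest.fixture(scope="module")
def label_model(small_world, tiny_model_config, trained_lf_model):
    ds = small_world["dataset"]
    trans = ds.replace_records([r for r in ds.records if r.split != "no_lf_test"])
    strat = Strategy("predicted_label", [trained_lf_model])
    model, _ = train_hf_model(trans, strat, tiny_model_config,
                              TrainConfig(epochs=10, seed=0),
                              graphs=small_world["graphs"])
    return model


class TestLabelSweep:
    def test_sweep_has_201_rows_and_statistic(self, label_model):
        df = simulate_label_sweep(label_model, parse_smiles_to_graph("CCO"),
                                  -50, 50, 0.5)
        assert len(df) == 201
        assert df["supplied_label"].is_monotonic_increasing
        assert -1.0 <= df.attrs["spearman_rho"] <= 1.0

    def test_model_without_scalar_slot_rejected(self, trained_lf_model):
        with pytest.raises(StrategyError):
            simulate_label_sweep(trained_lf_model, parse_smiles_to_graph("CC"))


class TestDownstreamBaseline:
    def test_linear_on_realizable_target(self, rng):
        X = rng.normal(size=(120, 8))
        w = rng.normal(size=8)
        y = X @ w + 0.2
        _, metrics = train_downstream_baseline(X, y, kind="linear")
        assert metrics["r2"] > 0.99

    def test_label_column_improves_rf(self, rng):
        """Adding a correlated label column lowers random-forest test MAE."""
        n = 200
        fp = rng.integers(0, 2, size=(n, 32)).astype(float)
        g = fp[:, :6] @ rng.normal(size=6)
        y = g + 0.1 * rng.normal(size=n)
        lf = g + 0.15 * rng.normal(size=n)  # r ≈ 0.95 proxy label
        tr, te = slice(0, 150), slice(150, None)
        _, m_plain = train_downstream_baseline(fp[tr], y[tr], "random_forest",
                                               test=(fp[te], y[te]), seed=0)
        Xa = np.column_stack([fp, lf])
        _, m_aug = train_downstream_baseline(Xa[tr], y[tr], "random_forest",
                                             test=(Xa[te], y[te]), seed=0)
        assert m_aug["mae"] < m_plain["mae"]

    def test_row_mismatch(self):
        with pytest.raises(ValueError):
            train_downstream_baseline(np.zeros((3, 2)), np.zeros(4))

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        _, m1 = train_downstream_baseline(X, y, "random_forest", seed=7)
        _, m2 = train_downstream_baseline(X, y, "random_forest", seed=7)
        assert m1 == m2
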