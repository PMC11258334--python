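"""Supervised VGAE: closed-form oracles, equivariance, training behaviour."""

import numpy as np
import pytest

from mfgnn import (ReadoutConfig, TrainConfig, VGAEConfig, VGAEModel,
                   decode_edge_prob, embed, encode, filter_outliers, kl_term,
                   parse_smiles_to_graph, predict, reconstruction_term,
                   sample_latent, supervised_loss, train_lf_model)
from mfgnn.molgraph import ConfigurationError, normalized_adjacency
from mfgnn.vgae import LatentEncoding, CheckpointError


def _tiny_model(kind="sum", seed=0, latent=6):
    ro = ReadoutConfig(kind=kind, K=2, n=1, m=1, hidden_dim=16, out_dim=8, M=20)
    return VGAEModel(VGAEConfig(latent_dim=latent, gcn_hidden=12, head_hidden=8,
                                readout=ro), seed=seed)


class TestEncode:
    def test_shapes(self):
        model = _tiny_model()
        g = parse_smiles_to_graph("CCO")
        enc = encode(g, model)
        assert enc.mu.shape == (3, 6) and enc.log_sigma.shape == (3, 6)

    def test_permutation_equivariance(self, rng):
        model = _tiny_model()
        g = parse_smiles_to_graph("CC(C)Cc1ccc(C)cc1")
        enc = encode(g, model)
        perm = rng.permutation(g.num_nodes)
        enc_p = encode(g.permuted(perm), model)
        np.testing.assert_allclose(enc_p.mu, enc.mu[perm], rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(enc_p.log_sigma, enc.log_sigma[perm],
                                   rtol=1e-8, atol=1e-10)

    def test_two_node_path_manual_matrix_product(self):
        """Hand-computed two-layer GCN on the 2-node path graph."""
        model = _tiny_model()
        g = parse_smiles_to_graph("CC")
        ahat = normalized_adjacency(g.adjacency)
        x = g.node_features
        w1, w2 = model.gcn_mu[0].data, model.gcn_mu[1].data
        manual = ahat @ np.tanh(ahat @ x @ w1) @ w2
        np.testing.assert_allclose(encode(g, model).mu, manual, rtol=1e-10)

    def test_dimension_mismatch(self):
        model = _tiny_model()
        g = parse_smiles_to_graph("CC")
        g.node_features = np.zeros((2, 3))
        with pytest.raises(ConfigurationError):
            encode(g, model)


class TestSampling:
    def test_sigma_zero_limit_returns_mu(self):
        enc = LatentEncoding(mu=np.ones((3, 2)), log_sigma=np.full((3, 2), -700.0))
        np.testing.assert_allclose(sample_latent(enc, 0), enc.mu)

    def test_seeded_determinism(self):
        enc = LatentEncoding(mu=np.zeros((4, 3)), log_sigma=np.zeros((4, 3)))
        np.testing.assert_array_equal(sample_latent(enc, 42), sample_latent(enc, 42))

    def test_monte_carlo_mean(self):
        """Empirical mean of 10k draws within 3 standard errors of mu."""
        mu, sigma = 1.7, np.exp(0.3)
        enc = LatentEncoding(mu=np.full((1, 1), mu), log_sigma=np.full((1, 1), 0.3))
        draws = np.array([sample_latent(enc, s)[0, 0] for s in range(10_000)])
        assert abs(draws.mean() - mu) < 3 * sigma / np.sqrt(10_000)


class TestDecoder:
    def test_closed_forms(self):
        assert decode_edge_prob(np.zeros(3), np.zeros(3)) == pytest.approx(0.5)
        assert decode_edge_prob([1, 0], [1, 0]) == pytest.approx(0.73106, abs=1e-5)
        assert decode_edge_prob([1, 0], [0, 1]) == pytest.approx(0.5)

    def test_symmetry_exact(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert decode_edge_prob(a, b) == decode_edge_prob(b, a)

    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            decode_edge_prob(np.zeros(2), np.zeros(3))


class TestKL:
    def test_prior_gives_zero(self):
        enc = LatentEncoding(np.zeros((5, 3)), np.zeros((5, 3)))
        assert kl_term(enc) == pytest.approx(0.0)

    def test_unit_mean_closed_form(self):
        enc = LatentEncoding(np.ones((1, 1)), np.zeros((1, 1)))
        assert kl_term(enc) == pytest.approx(0.5)

    def test_variance_e_closed_form(self):
        # sigma^2 = e: KL = (sigma^2 - 1 - ln sigma^2)/2 = (e - 2)/2
        enc = LatentEncoding(np.zeros((1, 1)), np.full((1, 1), 0.5))
        assert kl_term(enc) == pytest.approx((np.e - 2) / 2, abs=1e-9)

    def test_nonnegative_random(self, rng):
        for _ in range(20):
            enc = LatentEncoding(rng.normal(size=(4, 3)),
                                 rng.normal(scale=0.7, size=(4, 3)))
            assert kl_term(enc) >= 0


class TestReconstruction:
    def test_two_node_enumeration_oracle(self):
        """2-node single-edge graph: hand-enumerate the three i<=j pairs."""
        g = parse_smiles_to_graph("CC")
        z = np.array([[1.0, 0.5], [0.8, -0.2]])
        seed = 11
        got = reconstruction_term(g, z, neg_ratio=1, seed=seed)
        # all pairs are positives here (self-loops + the bond): no non-edges
        logits = [z[0] @ z[0], z[0] @ z[1], z[1] @ z[1]]
        expect = np.mean([np.log(1 / (1 + np.exp(-l))) for l in logits])
        assert got == pytest.approx(expect, abs=1e-12)

    def test_perfect_latents_approach_zero(self):
        g = parse_smiles_to_graph("CCO")
        # bonded pairs (0-1, 1-2) and self-loops get large positive logits,
        # the non-edge (0, 2) a large negative one
        z = np.array([[10.0, 0.0, 10.0], [10.0, 10.0, 0.0], [0.0, 10.0, -10.0]])
        val = reconstruction_term(g, z, neg_ratio=1, seed=0)
        assert -0.05 < val <= 0

    def test_seeded_subsampling_deterministic(self):
        g = parse_smiles_to_graph("CCCCO")
        z = np.random.default_rng(1).normal(size=(5, 3))
        assert reconstruction_term(g, z, 1, seed=5) == \
            reconstruction_term(g, z, 1, seed=5)


class TestSupervisedLoss:
    def test_parts_sum_exactly(self):
        model = _tiny_model()
        g = parse_smiles_to_graph("CCN")
        total, parts = supervised_loss(g, 0.7, model, TrainConfig(), seed=2)
        assert total == pytest.approx(parts["recon"] + parts["kl"] + parts["sup"],
                                      abs=1e-12)

    def test_lambda_zero_is_unsupervised(self):
        model = _tiny_model()
        g = parse_smiles_to_graph("CCN")
        total, parts = supervised_loss(g, 0.7, model,
                                       TrainConfig(lambda_sup=0.0), seed=2)
        assert parts["sup"] == 0.0
        assert total == pytest.approx(parts["recon"] + parts["kl"])

    def test_parts_match_independent_oracles(self):
        """Recompute each part with the standalone operations."""
        model = _tiny_model()
        g = parse_smiles_to_graph("C1CCNCC1")
        cfg = TrainConfig(lambda_sup=1.0, neg_ratio=1)
        seed = 9
        total, parts = supervised_loss(g, 1.3, model, cfg, seed=seed)
        enc = encode(g, model)
        z = sample_latent(enc, seed)
        assert parts["recon"] == pytest.approx(
            -reconstruction_term(g, z, 1, seed), abs=1e-12)
        assert parts["kl"] == pytest.approx(kl_term(enc) / g.num_nodes, abs=1e-12)

    def test_missing_label_raises(self):
        from mfgnn.vgae import LabelledDataError
        with pytest.raises(LabelledDataError):
            supervised_loss(parse_smiles_to_graph("CC"), None, _tiny_model(),
                            TrainConfig())


class TestPredictEmbed:
    @pytest.mark.parametrize("kind", ["sum", "set_transformer"])
    def test_end_to_end_permutation_invariance(self, kind, rng):
        model = _tiny_model(kind=kind)
        g = parse_smiles_to_graph("CC(C)c1ccccc1O")
        base_p, base_e = predict(model, g), embed(model, g)
        for _ in range(5):
            gp = g.permuted(rng.permutation(g.num_nodes))
            assert predict(model, gp) == pytest.approx(base_p, rel=1e-5, abs=1e-8)
            np.testing.assert_allclose(embed(model, gp), base_e,
                                       rtol=1e-5, atol=1e-8)

    def test_inference_bit_deterministic(self):
        model = _tiny_model(kind="set_transformer")
        g = parse_smiles_to_graph("OCC(O)CO")
        assert predict(model, g) == predict(model, g)

    def test_embed_length_is_out_dim(self):
        model = _tiny_model(kind="set_transformer")
        assert embed(model, parse_smiles_to_graph("CCO")).shape == (8,)

    def test_embeddings_do_not_collapse(self, trained_lf_model, small_world):
        graphs = list(small_world["graphs"].values())[:50]
        embs = np.array([embed(trained_lf_model, g) for g in graphs])
        assert embs.std(axis=0).max() > 1e-3


class TestTraining:
    def test_seeded_trajectories_identical(self, small_world, tiny_model_config):
        kw = dict(graphs=small_world["graphs"])
        cfg = TrainConfig(epochs=3, batch_size=64, seed=5)
        m1 = train_lf_model(small_world["dataset"], tiny_model_config, cfg, **kw)
        m2 = train_lf_model(small_world["dataset"], tiny_model_config, cfg, **kw)
        assert m1.train_log == m2.train_log

    def test_loss_decreases(self, trained_lf_model):
        log = trained_lf_model.train_log
        assert log[-1]["total"] < log[0]["total"]

    def test_constant_labels_recovered(self, small_world, tiny_model_config):
        """Degenerate fit: y ≡ c gives predictions near c."""
        ds = small_world["dataset"]
        const = ds.replace_records([
            type(r)(r.mol_id, r.smiles, 2.5 if r.lf_label is not None else None,
                    r.hf_label, r.split, dict(r.extra_lf_labels))
            for r in ds.records])
        model = train_lf_model(const, tiny_model_config,
                               TrainConfig(epochs=15, batch_size=64, seed=1),
                               graphs=small_world["graphs"])
        preds = [predict(model, small_world["graphs"][r.mol_id])
                 for r in const.subset("lf_train")[:30]]
        np.testing.assert_allclose(preds, 2.5, atol=0.3)

    def test_empty_training_split_raises(self, tiny_model_config):
        from mfgnn import MultiFidelityDataset, MultiFidelityRecord
        ds = MultiFidelityDataset([MultiFidelityRecord("a", "CC", hf_label=1.0,
                                                       split="hf_train")])
        with pytest.raises(ValueError):
            train_lf_model(ds, tiny_model_config, TrainConfig(epochs=1))


class TestCheckpoint:
    def test_round_trip(self, tmp_path, trained_lf_model, small_world):
        p = tmp_path / "model.json"
        trained_lf_model.save(p)
        back = VGAEModel.load(p)
        g = next(iter(small_world["graphs"].values()))
        assert predict(back, g) == pytest.approx(predict(trained_lf_model, g),
                                                 abs=1e-12)

    def test_featurization_version_mismatch_refused(self, tmp_path, trained_lf_model):
        from mfgnn import AtomFeaturizationScheme
        p = tmp_path / "model.json"
        trained_lf_model.save(p)
        wrong = AtomFeaturizationScheme(version="someone-elses-v9")
        with pytest.raises(CheckpointError):
            VGAEModel.load(p, scheme=wrong)


class TestFilterOutliers:
    def test_all_equal_all_kept(self):
        assert filter_outliers(np.full(10, 3.3), 5).all()

    def test_single_huge_outlier_removed(self):
        """999 zeros + one 1000: only the 1000 diverges by > 5 sd."""
        vals = np.concatenate([np.zeros(999), [1000.0]])
        mask = filter_outliers(vals, 5)
        assert mask.sum() == 999 and not mask[-1]

    def test_standard_normal_keeps_999_per_mille(self):
        vals = np.random.default_rng(0).standard_normal(10_000)
        assert filter_outliers(vals, 5).mean() >= 0.999
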