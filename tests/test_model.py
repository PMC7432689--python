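import numpy as np
import pytest

from lncfusion.model import (MODALITIES, FeatureEncoder, ModelConfig,
                             Prediction, build_submodel, decision_fusion_vote,
                             fast_config, fuse_and_finetune,
                             pretrain_submodels, train_model, TrainedModel)
from lncfusion.sequence_io import LabeledDataset, Transcript
from lncfusion.synthetic import GeneratorConfig, generate_benchmark


@pytest.fixture(scope="module")
def trained(small_benchmark, tiny_config):
    return train_model(small_benchmark, tiny_config)


@pytest.fixture(scope="module")
def pretrained(small_benchmark, tiny_config):
    return pretrain_submodels(small_benchmark, tiny_config)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            ModelConfig(ofh_hidden=(0,))
        with pytest.raises(ValueError):
            ModelConfig(modalities=("ofh", "bogus"))
        with pytest.raises(ValueError):
            ModelConfig(learning_rate=-1)

    def test_json_round_trip(self):
        cfg = fast_config(seed=5, modalities=("kmer",))
        assert ModelConfig.from_json(cfg.to_json()) == cfg


class TestBuildSubmodel:
    def test_ofh_widths(self):
        cfg = ModelConfig(ofh_hidden=(64, 32))
        sub = build_submodel("ofh", cfg)
        assert sub.features.layers[0].params["W"].shape[0] == 4
        assert sub.descriptor_width == 32
        x = np.zeros((3, 4))
        assert sub.descriptor(x).shape == (3, 32)

    def test_kmer_input_width_4096(self):
        sub = build_submodel("kmer", ModelConfig(k=6))
        assert sub.features.layers[0].params["W"].shape[0] == 4096

    def test_onehot_shapes(self):
        cfg = fast_config(maxlen=250)
        sub = build_submodel("onehot", cfg)
        x = np.zeros((2, 4, cfg.maxlen), dtype=np.float32)
        assert sub.descriptor(x).shape == (2, cfg.cnn_dense[-1])
        assert sub.logits(x).shape == (2, 1)

    def test_seeded_init_identical(self):
        cfg = fast_config(seed=21)
        for modality in MODALITIES:
            a = build_submodel(modality, cfg, np.random.default_rng(7))
            b = build_submodel(modality, cfg, np.random.default_rng(7))
            for (_, la, ka), (_, lb, kb) in zip(a.full.named_params(),
                                                b.full.named_params()):
                np.testing.assert_array_equal(la.params[ka], lb.params[kb])

    def test_unknown_modality(self):
        with pytest.raises(ValueError, match="unknown modality"):
            build_submodel("protein", ModelConfig())


class TestPretrain:
    def test_loss_decreases(self, pretrained):
        submodels, _ = pretrained
        for sub in submodels.values():
            assert sub.history[-1] < sub.history[0]

    def test_single_class_rejected(self, tiny_config):
        ts = [Transcript(f"t{i}", "ATGAAATAA" * 30) for i in range(8)]
        data = LabeledDataset(ts, np.zeros(8, dtype=int))
        with pytest.raises(ValueError, match="both classes"):
            pretrain_submodels(data, tiny_config)

    def test_deterministic_given_seed(self, small_benchmark):
        cfg = fast_config(maxlen=250, pretrain_epochs=2, modalities=("ofh",),
                          seed=17)
        p1, _ = pretrain_submodels(small_benchmark, cfg)
        p2, _ = pretrain_submodels(small_benchmark, cfg)
        np.testing.assert_array_equal(p1["ofh"].head.params["W"],
                                      p2["ofh"].head.params["W"])
        assert p1["ofh"].history == p2["ofh"].history

    def test_ofh_alone_separates_synthetic(self, small_benchmark, tiny_config):
        submodels, enc = pretrain_submodels(
            small_benchmark, fast_config(maxlen=250, modalities=("ofh",), seed=3))
        holdout, _ = generate_benchmark(
            GeneratorConfig(n_per_class=50, length_range=(200, 700), seed=123))
        X = enc.encode(holdout.transcripts, ("ofh",))
        acc = ((submodels["ofh"].predict_proba(X["ofh"]) >= 0.5).astype(int)
               == holdout.labels).mean()
        assert acc > 0.9


class TestFuseAndFinetune:
    def test_descriptor_width_mismatch(self, small_benchmark, tiny_config):
        submodels, enc = pretrain_submodels(small_benchmark, tiny_config)
        bad = fast_config(maxlen=250, ofh_hidden=(8, 8), seed=3)
        with pytest.raises(ValueError, match="descriptor width"):
            fuse_and_finetune(submodels, small_benchmark, bad, enc)

    def test_missing_submodel(self, small_benchmark, tiny_config, pretrained):
        submodels, enc = pretrained
        partial = {"ofh": submodels["ofh"]}
        with pytest.raises(ValueError, match="missing pretrained"):
            fuse_and_finetune(partial, small_benchmark, tiny_config, enc)

    def test_modality_subset_same_code_path(self, small_benchmark):
        cfg = fast_config(maxlen=250, modalities=("kmer",), pretrain_epochs=4,
                          fusion_epochs=2, finetune_epochs=1, seed=3)
        model = train_model(small_benchmark, cfg)
        assert model.architecture == "kmer"
        p = model.predict_proba(small_benchmark.transcripts[:10])
        assert ((p >= 0) & (p <= 1)).all()

    def test_freeze_contract(self, small_benchmark):
        cfg = fast_config(maxlen=250, pretrain_epochs=3, fusion_epochs=2,
                          finetune_epochs=0, batch_size=32, seed=5)
        submodels, enc = pretrain_submodels(small_benchmark, cfg)
        before = {m: {k: v.copy() for k, v in s.full.state_arrays().items()}
                  for m, s in submodels.items()}
        fuse_and_finetune(submodels, small_benchmark, cfg, enc)
        for m, s in submodels.items():
            for k, v in s.full.state_arrays().items():
                np.testing.assert_array_equal(v, before[m][k])


class TestPredict:
    def test_inference_deterministic(self, trained, small_benchmark):
        ts = small_benchmark.transcripts[:20]
        np.testing.assert_array_equal(trained.predict_proba(ts),
                                      trained.predict_proba(ts))

    def test_probability_range(self, trained, small_benchmark):
        p = trained.predict_proba(small_benchmark.transcripts)
        assert ((p >= 0) & (p <= 1)).all()

    def test_order_equivariance(self, trained, small_benchmark):
        ts = small_benchmark.transcripts[:30]
        by_id = {pr.id: pr.p_lnc for pr in trained.predict(ts)}
        rev = {pr.id: pr.p_lnc for pr in trained.predict(ts[::-1])}
        assert by_id == pytest.approx(rev, abs=1e-9)

    def test_direction_on_holdout(self, trained):
        holdout, _ = generate_benchmark(
            GeneratorConfig(n_per_class=40, length_range=(200, 700), seed=321))
        p = trained.predict_proba(holdout.transcripts)
        assert p[holdout.labels == 1].mean() > p[holdout.labels == 0].mean()

    def test_too_short_flagged(self, trained):
        preds = trained.predict([Transcript("ok", "ATGAAATAA" * 30),
                                 Transcript("tiny", "ACGTA")])
        assert preds[0].status == "ok"
        assert preds[1].status == "too_short" and preds[1].label == -1

    def test_prediction_invariant(self):
        with pytest.raises(ValueError):
            Prediction("x", 1.5, 1)


class TestDecisionFusion:
    def test_tally_oracle(self, pretrained, small_benchmark):
        submodels, enc = pretrained
        ts = small_benchmark.transcripts[:50]
        preds = decision_fusion_vote(submodels, enc, ts)
        X = enc.encode(ts, MODALITIES)
        probas = {m: submodels[m].predict_proba(X[m]) for m in MODALITIES}
        for i, pr in enumerate(preds):
            votes = sum(int(probas[m][i] >= 0.5) for m in MODALITIES)
            assert pr.label == int(votes >= 2)
            assert pr.p_lnc == pytest.approx(
                np.mean([probas[m][i] for m in MODALITIES]))

    def test_requires_three_submodels(self, pretrained, small_benchmark):
        submodels, enc = pretrained
        with pytest.raises(ValueError, match="three submodels"):
            decision_fusion_vote({"ofh": submodels["ofh"]}, enc,
                                 small_benchmark.transcripts[:2])


class TestPersistence:
    def test_save_load_round_trip(self, trained, small_benchmark, tmp_path):
        path = tmp_path / "model.npz"
        trained.save(path)
        loaded = TrainedModel.load(path)
        ts = small_benchmark.transcripts[:25]
        np.testing.assert_allclose(loaded.predict_proba(ts),
                                   trained.predict_proba(ts), atol=1e-12)
        assert loaded.config == trained.config
        np.testing.assert_allclose(loaded.encoder.hexamer_table.f_coding,
                                   trained.encoder.hexamer_table.f_coding)
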