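import math

import numpy as np
import pytest

from mfpinc.deep_features import (ExtractorConfig, GruExtractor, _GruCell,
                                  build_extractor, extract_deep_features,
                                  extract_deep_features_batch,
                                  train_extractor)

from .conftest import make_motif_data


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


class TestConfig:
    def test_defaults_give_1200_features(self):
        assert ExtractorConfig().feature_dim == 1200

    def test_invalid_sizes_error(self):
        with pytest.raises(ValueError):
            ExtractorConfig(hidden_units=0)
        with pytest.raises(ValueError):
            ExtractorConfig(pool1_size=-1)

    def test_fingerprint_tracks_config(self):
        assert ExtractorConfig().fingerprint == ExtractorConfig().fingerprint
        assert ExtractorConfig().fingerprint != ExtractorConfig(seed=1).fingerprint


class TestGateEquations:
    def test_scalar_cell_matches_hand_arithmetic(self):
        """A 1-unit cell with hand-set weights follows the gate equations:
        u = s(Wu.[h,x]), r = s(Wr.[h,x]), c = tanh(W.[r*h, x]),
        h' = u*c + (1-u)*h, evaluated step by step with plain floats."""
        cell = _GruCell(np.random.default_rng(0), emb_dim=1, hidden=1)
        w = dict(Wu=0.5, Wr=-0.3, Wc=0.8, Uu=0.2, Ur=0.7, Uc=-0.4,
                 bu=0.1, br=-0.2, bc=0.05)
        for k, v in w.items():
            cell.params[k][...] = v
        xs = [0.9, -1.2, 0.4]
        h = 0.0
        for x in xs:
            u = sigmoid(w["Wu"] * x + w["Uu"] * h + w["bu"])
            r = sigmoid(w["Wr"] * x + w["Ur"] * h + w["br"])
            c = math.tanh(w["Wc"] * x + w["Uc"] * (r * h) + w["bc"])
            h = u * c + (1 - u) * h
        X = np.array(xs).reshape(1, len(xs), 1)
        H, _ = cell.forward(X, cache=False)
        assert H[0, -1, 0] == pytest.approx(h, rel=1e-12)

    def test_gate_activations_in_unit_interval(self):
        cell = _GruCell(np.random.default_rng(1), emb_dim=3, hidden=4)
        X = np.random.default_rng(2).normal(size=(2, 5, 3))
        _, caches = cell.forward(X, cache=True)
        for _, u, r, _ in caches:
            assert np.all((u > 0) & (u < 1)) and np.all((r > 0) & (r < 1))


class TestBuildAndExtract:
    def test_default_gru_emits_1200(self):
        model = build_extractor(ExtractorConfig(seed=0))
        idx = np.random.default_rng(0).integers(0, 6, size=(3, 1200))
        assert model.features(idx).shape == (3, 1200)

    def test_default_bigru_emits_1200(self):
        model = build_extractor(ExtractorConfig(bidirectional=True, seed=0))
        idx = np.random.default_rng(0).integers(0, 6, size=(2, 1200))
        assert model.features(idx).shape == (2, 1200)

    def test_same_seed_identical_parameters(self):
        a = build_extractor(ExtractorConfig(seed=3))
        b = build_extractor(ExtractorConfig(seed=3))
        assert np.array_equal(a.embedding, b.embedding)
        for ca, cb in zip(a.cells, b.cells):
            for k in ca.params:
                assert np.array_equal(ca.params[k], cb.params[k])

    def test_dimension_is_input_independent(self, small_extractor_config):
        model = build_extractor(small_extractor_config)
        rng = np.random.default_rng(4)
        L = small_extractor_config.seq_length
        dims = {extract_deep_features(model, rng.integers(0, 6, size=L)).values.shape
                for _ in range(20)}
        assert dims == {(L,)}

    def test_all_padding_input_is_finite(self, small_extractor_config):
        model = build_extractor(small_extractor_config)
        vec = extract_deep_features(model, np.zeros(60, dtype=int))
        assert np.all(np.isfinite(vec.values))

    def test_length_mismatch_errors(self, small_extractor_config):
        model = build_extractor(small_extractor_config)
        with pytest.raises(ValueError, match="seq_length"):
            model.features(np.zeros((1, 10), dtype=int))

    def test_batch_equals_per_row(self, small_extractor_config):
        model = build_extractor(small_extractor_config)
        idx = np.random.default_rng(5).integers(0, 6, size=(5, 60))
        table = extract_deep_features_batch(model, idx)
        assert table.shape == (5, 60)
        for i in range(5):
            assert np.allclose(table.iloc[i].to_numpy(),
                               extract_deep_features(model, idx[i]).values)

    def test_empty_batch(self, small_extractor_config):
        model = build_extractor(small_extractor_config)
        table = extract_deep_features_batch(model, np.zeros((0, 60), dtype=int))
        assert table.shape == (0, 60)


class TestTraining:
    def test_loss_decreases_on_separable_motif_data(self, small_extractor_config):
        idx, y = make_motif_data(200, 60, seed=7)
        model = build_extractor(small_extractor_config)
        _, history = train_extractor(model, idx, y)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_training_is_deterministic(self, small_extractor_config):
        idx, y = make_motif_data(96, 60, seed=8)
        runs = []
        for _ in range(2):
            model = build_extractor(small_extractor_config)
            _, history = train_extractor(model, idx, y)
            runs.append(history[-1]["train_loss"])
        assert runs[0] == runs[1]

    def test_head_outputs_are_probabilities(self, small_extractor_config):
        idx, y = make_motif_data(64, 60, seed=9)
        model = build_extractor(small_extractor_config)
        train_extractor(model, idx, y)
        probs = model.predict_proba(idx)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_single_class_errors(self, small_extractor_config):
        idx, _ = make_motif_data(64, 60, seed=10)
        model = build_extractor(small_extractor_config)
        with pytest.raises(ValueError, match="single class"):
            train_extractor(model, idx, np.ones(64))

    def test_label_shuffle_gives_chance_accuracy(self, small_extractor_config):
        """Training on label-shuffled balanced data must not beat chance on
        held-out rows (leakage sanity check)."""
        idx, y = make_motif_data(256, 60, seed=11, shuffle_labels=True)
        model = build_extractor(small_extractor_config)
        train_extractor(model, idx[:192], y[:192])
        acc = np.mean((model.predict_proba(idx[192:]) >= 0.5) == (y[192:] == 1))
        assert abs(acc - 0.5) <= 0.12

    def test_linear_probe_on_features_separates_motif_data(self, small_extractor_config):
        from dataclasses import replace

        from sklearn.linear_model import LogisticRegression

        idx, y = make_motif_data(400, 60, seed=12)
        model = build_extractor(replace(small_extractor_config, epochs=20))
        train_extractor(model, idx[:300], y[:300])
        probe = LogisticRegression(max_iter=2000)
        probe.fit(model.features(idx[:300]), y[:300])
        assert probe.score(model.features(idx[300:]), y[300:]) >= 0.9


class TestCheckpoint:
    def test_roundtrip_preserves_features(self, small_extractor_config, tmp_path):
        model = build_extractor(small_extractor_config)
        idx, y = make_motif_data(64, 60, seed=13)
        train_extractor(model, idx, y)
        model.save(tmp_path / "ckpt.npz")
        back = GruExtractor.load(tmp_path / "ckpt.npz")
        assert np.allclose(model.features(idx), back.features(idx))

    def test_fingerprint_mismatch_refused(self, small_extractor_config, tmp_path):
        model = build_extractor(small_extractor_config)
        model.save(tmp_path / "ckpt.npz")
        with pytest.raises(ValueError, match="fingerprint"):
            GruExtractor.load(tmp_path / "ckpt.npz", expected_fingerprint="deadbeef0000")
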