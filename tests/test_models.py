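"""Architecture and training tests: attention-gate contracts, star-operation
algebra against a symbolic oracle, forward-pass invariants, seeded training
determinism and learnability on separable data."""
from __future__ import annotations

import numpy as np
import pytest

from meanbci.core import ConfigError, DataError
from meanbci.model import AttentionClassifier, AttentionClassifierResults, TrainConfig
from meanbci.models import (
    ChannelAttention,
    MappingBlock,
    MeanNetwork,
    RecurrentBaseline,
    SpatialAttention,
    star_term_count,
)
from meanbci.nn import Tensor

from .conftest import make_blob_features
from .oracles import star_monomial_count_symbolic


class TestStarOperation:
    @pytest.mark.parametrize("d,expected", [(1, 3), (2, 6), (4, 15)])
    def test_closed_form(self, d, expected):
        assert star_term_count(d) == expected

    @pytest.mark.parametrize("d", range(1, 7))
    def test_matches_symbolic_expansion(self, d):
        assert star_term_count(d) == star_monomial_count_symbolic(d)

    def test_invalid_dimension(self):
        with pytest.raises(ConfigError):
            star_term_count(0)


class TestChannelAttention:
    def test_zero_input_gives_half_gates(self):
        att = ChannelAttention(15, np.random.default_rng(0))
        att.eval()
        att(Tensor(np.zeros((2, 15, 93))))
        np.testing.assert_allclose(att.last_weights, 0.5, atol=1e-12)

    def test_weights_in_open_unit_interval(self):
        att = ChannelAttention(15, np.random.default_rng(1))
        att(Tensor(np.random.default_rng(2).standard_normal((8, 15, 93)) * 10))
        assert np.all(att.last_weights > 0) and np.all(att.last_weights < 1)

    def test_gating_is_contractive(self):
        att = ChannelAttention(15, np.random.default_rng(3))
        x = np.random.default_rng(4).standard_normal((4, 15, 93))
        out = att(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)


class TestSpatialAttention:
    def test_zero_parameters_halve_input(self):
        att = SpatialAttention(np.random.default_rng(0))
        att.conv.w.data[:] = 0.0
        att.conv.b.data[:] = 0.0
        x = np.random.default_rng(1).standard_normal((3, 15, 93))
        np.testing.assert_allclose(att(Tensor(x)).data, x / 2.0, atol=1e-12)

    def test_locality_of_receptive_field(self):
        """Doubling one cell changes outputs only inside the 7x7 gate
        neighborhood of that cell (plus the cell itself)."""
        att = SpatialAttention(np.random.default_rng(2))
        x = np.random.default_rng(3).standard_normal((1, 15, 93))
        base = att(Tensor(x)).data[0]
        x2 = x.copy()
        ci, cj = 7, 40
        x2[0, ci, cj] *= 2.0
        diff = np.abs(att(Tensor(x2)).data[0] - base) > 1e-12
        ii, jj = np.nonzero(diff)
        assert np.all(np.abs(ii - ci) <= 3)
        assert np.all(np.abs(jj - cj) <= 3)

    def test_gate_contractive(self):
        att = SpatialAttention(np.random.default_rng(4))
        x = np.random.default_rng(5).standard_normal((2, 15, 93))
        assert np.all(np.abs(att(Tensor(x)).data) <= np.abs(x) + 1e-12)


class TestMappingBlock:
    def test_residual_only_is_identity(self):
        block = MappingBlock(np.random.default_rng(0))
        block.w_latent.data = np.array(0.0)
        block.w_orig.data = np.array(1.0)
        x = np.random.default_rng(1).standard_normal((2, 1, 50))
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-12)

    def test_star_fusion_formula(self):
        """Pure-star output equals conv_lin(x) * relu6(conv_nl(x)) computed
        by hand."""
        block = MappingBlock(np.random.default_rng(2))
        block.w_latent.data = np.array(1.0)
        block.w_orig.data = np.array(0.0)
        x = np.random.default_rng(3).standard_normal((1, 1, 30))
        f1 = block.conv_lin(Tensor(x)).data
        f2 = np.clip(block.conv_nl(Tensor(x)).data, 0.0, 6.0)
        np.testing.assert_allclose(block(Tensor(x)).data, f1 * f2, atol=1e-12)

    def test_zero_input_zero_biases_gives_zero(self):
        block = MappingBlock(np.random.default_rng(4))
        out = block(Tensor(np.zeros((1, 1, 20)))).data
        np.testing.assert_allclose(out, 0.0, atol=1e-12)


class TestForward:
    def test_probabilities_sum_to_one(self):
        net = MeanNetwork(15, 93, 2, np.random.default_rng(0))
        net.eval()
        logits = net(
            Tensor(np.random.default_rng(1).standard_normal((5, 15, 93))),
            Tensor(np.random.default_rng(2).standard_normal((5, 2))),
        )
        probs = logits.softmax_probs()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_flattened_width_is_1397(self):
        net = MeanNetwork(15, 93, 2, np.random.default_rng(0))
        assert net.flat_width == 1397

    def test_forward_is_pure_in_eval_mode(self):
        net = MeanNetwork(15, 93, 2, np.random.default_rng(3))
        net.eval()
        freq = Tensor(np.random.default_rng(4).standard_normal((2, 15, 93)))
        scal = Tensor(np.zeros((2, 2)))
        a = net(freq, scal).data
        b = net(freq, scal).data
        np.testing.assert_array_equal(a, b)

    def test_lightweight_parameter_budget(self):
        net = MeanNetwork(15, 93, 2, np.random.default_rng(0))
        assert net.n_parameters() < 10_000

    def test_recurrent_baseline_dimensions(self):
        net = RecurrentBaseline(15, 93, 2, np.random.default_rng(0), cell="lstm")
        assert net.hidden == 128
        assert len(net.layers) == 2


class TestTraining:
    def test_seeded_determinism(self):
        fs = make_blob_features(n_per_class=10, seed=5)
        cfg = TrainConfig(epochs=3, seed=9)
        a = AttentionClassifier(fs, arch="mean", config=cfg).fit()
        b = AttentionClassifier(fs, arch="mean", config=cfg).fit()
        assert a.history == b.history

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loss_decreases_on_separable_data(self, seed):
        fs = make_blob_features(n_per_class=20, separation=4.0, seed=seed)
        res = AttentionClassifier(
            fs, arch="mean", config=TrainConfig(epochs=12, lr=3e-3, seed=seed)
        ).fit()
        assert res.history[-1] < res.history[0]

    def test_single_class_rejected(self):
        fs = make_blob_features(n_per_class=5, seed=0)
        sel = fs.labels == "high"
        with pytest.raises(DataError):
            AttentionClassifier(
                fs.freq_maps[sel], fs.scalars[sel], fs.labels[sel]
            ).fit()

    def test_class_output_permutation_symmetry(self):
        """Permuting the trained output units together with the class order
        leaves predicted labels identical."""
        fs = make_blob_features(n_per_class=8, seed=2)
        res = AttentionClassifier(
            fs, arch="mean", config=TrainConfig(epochs=3, seed=1)
        ).fit()
        before = res.predict(fs)
        perm = [2, 0, 1]
        head = res.network.head
        head.fc2.w.data = head.fc2.w.data[:, perm]
        head.fc2.b.data = head.fc2.b.data[perm]
        res.class_order = tuple(res.class_order[i] for i in perm)
        np.testing.assert_array_equal(res.predict(fs), before)


class TestResultsApi:
    def test_summary_mentions_architecture(self, blob_features):
        res = AttentionClassifier(
            blob_features, arch="mean", config=TrainConfig(epochs=2, seed=0)
        ).fit()
        text = res.summary()
        assert "mean" in text and "parameters" in text

    def test_channel_weights_shape_and_range(self, blob_features):
        res = AttentionClassifier(
            blob_features, arch="mean", config=TrainConfig(epochs=2, seed=0)
        ).fit()
        w = res.extract_channel_weights(blob_features)
        assert list(w.columns) == ["min", "q1", "median", "q3", "max"]
        assert len(w) == 4
        assert (w.to_numpy() > 0).all() and (w.to_numpy() < 1).all()

    def test_missing_normalization_rejected(self, blob_features):
        res = AttentionClassifier(
            blob_features, arch="mean", config=TrainConfig(epochs=1, seed=0)
        ).fit()
        res.norm_mean = None
        with pytest.raises(DataError, match="train or load"):
            res.predict(blob_features)

    def test_save_load_roundtrip(self, blob_features, tmp_path):
        res = AttentionClassifier(
            blob_features, arch="mean", config=TrainConfig(epochs=2, seed=0)
        ).fit()
        path = tmp_path / "model.npz"
        res.save(path)
        loaded = AttentionClassifierResults.load(path)
        np.testing.assert_allclose(
            loaded.predict_proba(blob_features.freq_maps, blob_features.scalars),
            res.predict_proba(blob_features.freq_maps, blob_features.scalars),
            atol=1e-12,
        )
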