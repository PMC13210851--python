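"""Architecture zoo: shapes, parameter counts, training, pretraining."""

import numpy as np
import pytest

from gaitshift.models import (
    ArchitectureSpec,
    PretrainConfig,
    TrainingConfig,
    build_model,
    count_trainable_parameters,
    predict,
    pretrain_encoder,
    train_classifier,
)
from gaitshift.models.architectures import KERNEL, LSTM_HIDDEN, N_FILTERS
from gaitshift.models.layers import BiLSTMLast, Conv1d, LayerNorm, Linear, SelfAttention


def _expected_count(arch: str, C: int = 3) -> int:
    """Independent layer-arithmetic oracle for the parameter counts."""
    F, H, k = N_FILTERS, LSTM_HIDDEN, KERNEL
    conv1 = C * F * k + F
    convN = F * F * k + F
    lstm = lambda in_dim: 2 * (4 * H * (in_dim + H) + 8 * H)
    head = 2 * H * 6 + 6
    attn_block = 4 * (F * F + F) + 2 * F  # Q/K/V/O projections + affine LN
    return {
        "A1": conv1 + F * 6 + 6,
        "A2": 2 * (4 * H * (C + H) + 8 * H) + head,
        "A3": conv1 + 2 * convN + lstm(F) + head,
        "A4": conv1 + convN + lstm(F) + head,
        "A5": conv1 + convN + 2 * attn_block + lstm(F) + head,
    }[arch]


class TestArchitectures:
    @pytest.mark.parametrize("arch,printed", [
        ("A1", 1030), ("A2", 9862), ("A3", 50822), ("A4", 38470),
        ("A5", 72006),
    ])
    def test_parameter_counts_match_layer_arithmetic_and_printed(self, arch, printed):
        model = build_model(arch)
        n = count_trainable_parameters(model)
        assert n == _expected_count(arch) == printed

    @pytest.mark.parametrize("arch", ["A1", "A2", "A3", "A4", "A5"])
    def test_forward_shape_contract(self, arch):
        model = build_model(arch, seed=0)
        x = np.random.default_rng(0).normal(size=(2, 64, 3))
        out = model.forward(x)
        assert out.shape == (2, 6)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="A9"):
            ArchitectureSpec(name="A9")

    def test_a4_attention_contributes_zero_parameters(self):
        model = build_model("A4")
        attn = [l for l in model.layers if isinstance(l, SelfAttention)]
        assert len(attn) == 1 and attn[0].params() == []
        # Whole-model count equals conv + BiLSTM + head exactly.
        rest = sum(p.value.size for l in model.layers
                   if isinstance(l, (Conv1d, BiLSTMLast, Linear))
                   for p in l.params())
        assert count_trainable_parameters(model) == rest

    def test_channel_ablation_removes_192_per_channel(self):
        counts = [count_trainable_parameters(
            build_model(ArchitectureSpec("A5", in_channels=c))) for c in (3, 2, 1)]
        assert counts == [72006, 71814, 71622]
        assert counts[0] - counts[1] == counts[1] - counts[2] == 192

    def test_head_and_first_conv_sizes(self):
        head = Linear(64, 6)
        assert sum(p.value.size for p in head.params()) == 390
        conv = Conv1d(3, 64, 3)
        assert sum(p.value.size for p in conv.params()) == 640


def _toy_two_class(n=120, T=32, seed=0):
    """Linearly separable windows: class 0 negative offset, class 1 positive."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 0.3, size=(n, T, 3))
    y = rng.integers(0, 2, size=n)
    X += np.where(y[:, None, None] == 1, 1.0, -1.0)
    return X, y


class TestTraining:
    def test_single_class_dataset_memorised_quickly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(64, 32, 3))
        y = np.full(64, 2)
        model = build_model("A2", seed=1)
        model, hist = train_classifier(model, (X, y),
                                       TrainingConfig(max_epochs=5, seed=2))
        assert hist[-1]["accuracy"] >= 0.99

    def test_separable_two_class_problem_solved(self):
        X, y = _toy_two_class()
        Xte, yte = _toy_two_class(seed=99)
        model = build_model("A2", seed=3)
        model, _ = train_classifier(model, (X, y),
                                    TrainingConfig(max_epochs=8, seed=4))
        acc = (predict(model, Xte).argmax(1) == yte).mean()
        assert acc >= 0.95

    def test_history_respects_epoch_budget(self):
        X, y = _toy_two_class(n=40)
        model = build_model("A1", seed=0)
        _, hist = train_classifier(model, (X, y),
                                   TrainingConfig(max_epochs=3, seed=0))
        assert len(hist) <= 3

    def test_training_determinism(self):
        X, y = _toy_two_class(n=48)
        h = []
        for _ in range(2):
            model = build_model("A2", seed=7)
            _, hist = train_classifier(model, (X, y),
                                       TrainingConfig(max_epochs=2, seed=8))
            h.append([e["loss"] for e in hist])
        assert h[0] == h[1]

    def test_empty_dataset_rejected(self):
        model = build_model("A1")
        with pytest.raises(ValueError, match="empty"):
            train_classifier(model, (np.empty((0, 16, 3)), np.empty(0, int)),
                             TrainingConfig(max_epochs=1))

    def test_out_of_range_label_rejected(self):
        model = build_model("A1")
        with pytest.raises(ValueError, match="labels"):
            train_classifier(model, (np.zeros((4, 16, 3)), np.array([0, 1, 2, 6])),
                             TrainingConfig(max_epochs=1))


class TestPredict:
    def test_rows_are_probability_vectors(self):
        model = build_model("A1", seed=0)
        probs = predict(model, np.random.default_rng(0).normal(size=(5, 32, 3)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_channel_mismatch_rejected(self):
        model = build_model(ArchitectureSpec("A5", in_channels=3), seed=0)
        with pytest.raises(ValueError, match="x 3"):
            predict(model, np.zeros((2, 32, 2)))


class TestPretraining:
    def test_three_epochs_give_three_loss_entries_and_loss_decreases(self):
        rng = np.random.default_rng(5)
        t = np.arange(64) / 50.0
        X = np.stack([np.column_stack([np.sin(2 * np.pi * 1.8 * t + p)] * 3)
                      for p in rng.uniform(0, 6.28, 96)])
        X += rng.normal(0, 0.1, X.shape)
        model = build_model("A4", seed=6)
        model, hist = pretrain_encoder(model, X, PretrainConfig(epochs=3, seed=7))
        assert len(hist) == 3
        assert hist[-1] < hist[0]

    def test_decoder_mirrors_encoder_shape(self):
        from gaitshift.models.training import _mirrored_decoder
        model = build_model("A3", seed=0)
        convs = [l for l in model.conv_stem if isinstance(l, Conv1d)]
        dec = _mirrored_decoder(convs, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 32, 3))
        z = x
        for l in model.conv_stem:
            z = l.forward(z)
        recon = dec.forward(z)
        assert recon.shape == x.shape

    def test_architecture_without_conv_stem_is_noop_with_warning(self):
        model = build_model("A2", seed=0)
        before = [p.value.copy() for p in model.params()]
        with pytest.warns(UserWarning, match="no conv stem"):
            model, hist = pretrain_encoder(model, np.zeros((8, 32, 3)),
                                           PretrainConfig(epochs=3))
        assert hist == []
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)


class TestGradients:
    @pytest.mark.parametrize("arch", ["A1", "A2", "A3", "A4", "A5"])
    def test_backward_matches_central_differences(self, arch):
        """Analytic gradients agree with numeric differentiation on a tiny
        batch, for a handful of parameters sampled from every layer type."""
        from gaitshift.models.layers import softmax_cross_entropy
        rng = np.random.default_rng(0)
        model = build_model(arch, seed=1)
        X = rng.normal(size=(2, 12, 3))
        y = np.array([1, 4])
        model.zero_grad()
        _, grad = softmax_cross_entropy(model.forward(X), y)
        model.backward(grad)
        params = model.params()
        step = max(len(params) // 5, 1)
        for p in params[::step]:
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for idx in rng.choice(flat.size, size=min(2, flat.size),
                                  replace=False):
                eps, old = 1e-6, flat[idx]
                flat[idx] = old + eps
                lp, _ = softmax_cross_entropy(model.forward(X), y)
                flat[idx] = old - eps
                lm, _ = softmax_cross_entropy(model.forward(X), y)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - gflat[idx]) <= 1e-4 * max(
                    abs(num), abs(gflat[idx]), 1e-3)
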